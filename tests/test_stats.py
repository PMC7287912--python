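import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fcgraph import compare_cohort, radar_normalize, wilcoxon_signed_rank
from _oracles import brute_wilcoxon_two_sided


class TestWilcoxonExact:
    def test_all_positive_n8_probability(self):
        pre = np.zeros(8)
        post = np.arange(1.0, 9.0)
        res = wilcoxon_signed_rank(pre, post)
        assert res.statistic == 36.0
        assert res.method == "exact"
        assert res.pvalue == 2 / 256  # 0.0078125 exactly

    def test_perfectly_symmetric_pair_differences(self):
        res = wilcoxon_signed_rank([0.0, 0.0], [1.0, -1.0])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 11))
        pre = rng.standard_normal(m)
        post = pre + rng.standard_normal(m)  # continuous: no ties, no zeros
        res = wilcoxon_signed_rank(pre, post)
        w_brute, p_brute = brute_wilcoxon_two_sided(pre, post)
        assert res.method == "exact"
        assert res.statistic == pytest.approx(w_brute)
        assert res.pvalue == pytest.approx(p_brute, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_exact(self, seed):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(100 + seed)
        pre = rng.standard_normal(9)
        post = pre + rng.standard_normal(9)
        res = wilcoxon_signed_rank(pre, post)
        ref = scipy_wilcoxon(post, pre, mode="exact")
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_with_ties_enumerates_midranks(self):
        # tied |d|: mid-rank enumeration still sums to a proper distribution
        pre = np.zeros(6)
        post = np.array([1.0, 1.0, -1.0, 2.0, -2.0, 3.0])
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        w, p = brute_wilcoxon_two_sided(pre, post)
        assert res.statistic == pytest.approx(w)
        assert res.pvalue == pytest.approx(p, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_session_swap(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 10))
        pre = rng.standard_normal(m)
        post = pre + rng.standard_normal(m)
        fwd = wilcoxon_signed_rank(pre, post)
        rev = wilcoxon_signed_rank(post, pre)
        assert fwd.statistic + rev.statistic == pytest.approx(m * (m + 1) / 2)
        assert fwd.pvalue == pytest.approx(rev.pvalue, abs=1e-12)


class TestWilcoxonEdgesAndApprox:
    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 1.0 and res.n_used == 0

    def test_zero_differences_dropped(self):
        # pairs with d = 0 do not contribute under the drop-zeros convention
        res_with = wilcoxon_signed_rank([0, 0, 5, 5], [1, -2, 5, 5])
        res_without = wilcoxon_signed_rank([0, 0], [1, -2])
        assert res_with.statistic == res_without.statistic
        assert res_with.pvalue == res_without.pvalue

    def test_approx_matches_scipy_untied(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(5)
        pre = rng.standard_normal(30)
        post = pre + rng.standard_normal(30) + 0.3
        res = wilcoxon_signed_rank(pre, post, mode="approx")
        ref = scipy_wilcoxon(post, pre, mode="approx", correction=False)
        assert res.method == "approx"
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_approx_tie_correction_matches_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        pre = np.zeros(14)
        post = np.array([1, 1, 1, -1, 2, 2, -2, 3, 3, 3, -3, 4, 4, 5], dtype=float)
        res = wilcoxon_signed_rank(pre, post, mode="approx")
        ref = scipy_wilcoxon(post, pre, mode="approx", correction=False)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auto_switches_to_approx_on_large_or_tied(self):
        rng = np.random.default_rng(0)
        pre = rng.standard_normal(20)
        res = wilcoxon_signed_rank(pre, pre + rng.standard_normal(20))
        assert res.method == "approx"  # m = 20 > exact cap
        res2 = wilcoxon_signed_rank([0, 0, 0], [1, 1, -2])
        assert res2.method == "approx"  # tied |d|

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="2 pairs"):
            wilcoxon_signed_rank([1], [2])


def _toy_nodal(values_by_subject, roi="A", metric="degree", density=0.25):
    rows = []
    for subject, (pre, post) in values_by_subject.items():
        rows.append(dict(subject=subject, session="pre", density=density, roi=roi,
                         metric=metric, value=pre))
        rows.append(dict(subject=subject, session="post", density=density, roi=roi,
                         metric=metric, value=post))
    return pd.DataFrame(rows)


class TestCompareCohort:
    def test_identity_cohort_nothing_flagged(self):
        vals = {f"s{i}": (float(i), float(i)) for i in range(8)}
        comp = compare_cohort(_toy_nodal(vals))
        assert (comp["p_value"] == 1.0).all()
        assert not comp["significant"].any()
        assert (comp["direction"] == "none").all()

    def test_consistent_increase_flagged(self):
        vals = {f"s{i}": (float(i), float(i) + 1 + 0.1 * i) for i in range(8)}
        comp = compare_cohort(_toy_nodal(vals))
        row = comp.iloc[0]
        assert row["significant"]
        assert row["direction"] == "increase"
        assert row["p_value"] == pytest.approx(2 / 256)
        assert row["n_pairs"] == 8

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(3)
        vals = {f"s{i}": tuple(rng.standard_normal(2)) for i in range(8)}
        comp1 = compare_cohort(_toy_nodal(vals))
        shuffled = _toy_nodal(dict(reversed(list(vals.items()))))
        comp2 = compare_cohort(shuffled.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(comp1, comp2)

    def test_incomplete_subject_dropped_with_warning(self):
        frame = _toy_nodal({f"s{i}": (1.0 * i, 2.0 * i) for i in range(4)})
        frame = frame[~((frame["subject"] == "s0") & (frame["session"] == "post"))]
        with pytest.warns(UserWarning, match="missing a session"):
            comp = compare_cohort(frame)
        assert comp.iloc[0]["n_pairs"] == 3

    def test_fewer_than_two_pairs_rejected(self):
        frame = _toy_nodal({"s0": (1.0, 2.0), "s1": (1.0, 2.0)})
        frame = frame[~((frame["subject"] == "s1") & (frame["session"] == "post"))]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="complete pre/post pairs"):
                compare_cohort(frame)

    def test_smallworld_rows_appended_per_density(self):
        nodal = _toy_nodal({f"s{i}": (float(i), float(i)) for i in range(4)})
        sweep = pd.DataFrame(
            [
                dict(subject=f"s{i}", session=sess, density=d, s=1.0 + 0.1 * i + off)
                for i in range(4)
                for sess, off in (("pre", 0.0), ("post", -0.2))
                for d in (0.2, 0.25)
            ]
        )
        comp = compare_cohort(nodal, sweep)
        sw = comp[comp["metric"] == "small_worldness"]
        assert len(sw) == 2
        assert set(sw["density"]) == {0.2, 0.25}
        assert (sw["roi"] == "network").all()
        assert (sw["direction"] == "decrease").all()

    def test_density_modes(self):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(4):
            for sess in ("pre", "post"):
                for d in (0.2, 0.25):
                    rows.append(dict(subject=f"s{s}", session=sess, density=d,
                                     roi="A", metric="degree",
                                     value=float(rng.integers(0, 10))))
        nodal = pd.DataFrame(rows)
        ref = compare_cohort(nodal, density_mode="reference", reference_density=0.25)
        per = compare_cohort(nodal, density_mode="per_density")
        agg = compare_cohort(nodal, density_mode="aggregate")
        assert len(ref) == 1 and ref.iloc[0]["density"] == 0.25
        assert len(per) == 2
        assert len(agg) == 1 and agg.iloc[0]["density"] == "mean"

    def test_fdr_correction_adds_adjusted_column(self):
        vals = {f"s{i}": (float(i), float(i) + 1) for i in range(8)}
        comp = compare_cohort(_toy_nodal(vals), correction="fdr_bh")
        assert "p_adjusted" in comp.columns
        assert (comp["p_adjusted"] >= comp["p_value"] - 1e-15).all()


class TestRadarNormalize:
    def _row(self, pre, post, significant=True):
        return pd.DataFrame(
            [dict(roi="A", metric="degree", density=0.25, n_pairs=8, W=36.0,
                  p_value=0.0078, direction="increase", median_pre=pre,
                  median_post=post, significant=significant)]
        )

    def test_ratio_values(self):
        assert radar_normalize(self._row(2.0, 3.0)).iloc[0]["normalized_post"] == 1.5
        assert radar_normalize(self._row(4.0, 3.0)).iloc[0]["normalized_post"] == 0.75
        assert radar_normalize(self._row(5.0, 5.0)).iloc[0]["normalized_post"] == 1.0

    def test_only_significant_rows_kept(self):
        comp = pd.concat([self._row(2, 3), self._row(2, 4, significant=False)])
        assert len(radar_normalize(comp)) == 1
        assert len(radar_normalize(comp, only_significant=False)) == 2

    def test_zero_pre_median_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="pre-median"):
            out = radar_normalize(self._row(0.0, 3.0))
        assert out.empty
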