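import numpy as np
import pytest

from fcgraph import (
    EffectSpec,
    SyntheticCohortConfig,
    apply_effect,
    default_base_connectivity,
    generate_cohort,
    nearest_psd_correlation,
    pearson_matrix,
    write_cohort,
)


class TestConfigValidation:
    def test_defaults_match_study_conditions(self):
        cfg = SyntheticCohortConfig()
        assert cfg.n_subjects == 8
        assert cfg.n_volumes == 150
        assert cfg.tr == 3.0
        assert cfg.roi_set.n == 14

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError, match="n_subjects"):
            SyntheticCohortConfig(n_subjects=1)
        with pytest.raises(ValueError, match="n_volumes"):
            SyntheticCohortConfig(n_volumes=5)
        with pytest.raises(ValueError, match="ar_coefficient"):
            SyntheticCohortConfig(ar_coefficient=1.0)

    def test_rejects_asymmetric_or_nonunit_base(self):
        base = default_base_connectivity()
        bad = base.copy()
        bad[0, 1] = 0.9
        with pytest.raises(ValueError, match="symmetric"):
            SyntheticCohortConfig(base_connectivity=bad)
        bad2 = base.copy()
        bad2[0, 0] = 0.5
        with pytest.raises(ValueError, match="unit diagonal"):
            SyntheticCohortConfig(base_connectivity=bad2)

    def test_rejects_unknown_effect_roi(self):
        with pytest.raises(KeyError, match="NoSuchROI"):
            SyntheticCohortConfig(effects=(EffectSpec(target_roi="NoSuchROI", delta=0.1),))

    def test_default_base_is_psd_correlation(self):
        base = default_base_connectivity()
        assert np.allclose(base, base.T)
        assert np.allclose(np.diag(base), 1.0)
        assert np.linalg.eigvalsh(base).min() >= -1e-8


class TestPsdRepair:
    def test_psd_input_returned_unchanged(self):
        base = default_base_connectivity()
        assert nearest_psd_correlation(base) is base

    def test_indefinite_matrix_repaired(self):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(m).min() < 0
        fixed = nearest_psd_correlation(m)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-8
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.allclose(fixed, fixed.T)


class TestApplyEffect:
    def test_zero_delta_is_identity(self, roi_set):
        base = default_base_connectivity()
        out = apply_effect(base, EffectSpec("mPFC", ("PCC",), 0.0), roi_set)
        assert np.array_equal(out, base)

    def test_only_targeted_entries_change(self, roi_set):
        base = default_base_connectivity()
        i, j = roi_set.index("mPFC"), roi_set.index("PCC")
        out = apply_effect(base, EffectSpec("mPFC", ("PCC",), 0.3), roi_set)
        assert out[i, j] == pytest.approx(base[i, j] + 0.3)
        mask = np.ones_like(base, dtype=bool)
        mask[i, j] = mask[j, i] = False
        assert np.allclose(out[mask], base[mask])

    def test_overflow_clipped_and_repaired(self, roi_set):
        base = default_base_connectivity()
        i, j = roi_set.index("BA1_L"), roi_set.index("BA1_R")  # 0.45 homotopic
        with pytest.warns(UserWarning, match="clipped"):
            out = apply_effect(base, EffectSpec("BA1_L", ("BA1_R",), 0.9), roi_set)
        assert abs(out[i, j]) <= 0.99 + 1e-12
        assert np.linalg.eigvalsh(out).min() >= -1e-8

    def test_all_partners_shorthand(self, roi_set):
        base = default_base_connectivity()
        i = roi_set.index("PCC")
        out = apply_effect(base, EffectSpec("PCC", "ALL", 0.05), roi_set)
        others = [k for k in range(14) if k != i]
        assert np.allclose(out[i, others], base[i, others] + 0.05)


class TestGenerateCohort:
    def test_bit_identical_under_fixed_seed(self):
        cfg = SyntheticCohortConfig(n_subjects=2, n_volumes=40, seed=11)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for a, b in zip(c1.sessions, c2.sessions):
            assert a.subject == b.subject and a.session == b.session
            assert np.array_equal(a.data, b.data)

    def test_shapes_and_pairing(self):
        cohort = generate_cohort(SyntheticCohortConfig(n_subjects=3, n_volumes=50, seed=0))
        assert len(cohort.sessions) == 6
        assert all(s.data.shape == (50, 14) for s in cohort.sessions)
        assert cohort.subjects == ["sub-01", "sub-02", "sub-03"]
        # pre/post of a subject share the jittered covariance when no effects
        assert np.array_equal(
            cohort.covariances[("sub-01", "pre")], cohort.covariances[("sub-01", "post")]
        )

    def test_long_run_correlation_approaches_target(self, roi_set):
        cfg = SyntheticCohortConfig(
            n_subjects=2, n_volumes=50_000, subject_jitter=0.0, ar_coefficient=0.0, seed=3
        )
        cohort = generate_cohort(cfg)
        i, j = roi_set.index("mPFC"), roi_set.index("PCC")
        target = cfg.base_connectivity[i, j]
        r = pearson_matrix(cohort.sessions[0])
        assert r.values[i, j] == pytest.approx(target, abs=0.02)

    def test_empirical_correlation_converges_in_frobenius_norm(self):
        dists = []
        for n_vol in (500, 5_000, 50_000):
            cfg = SyntheticCohortConfig(
                n_subjects=2, n_volumes=n_vol, subject_jitter=0.0, ar_coefficient=0.0, seed=9
            )
            cohort = generate_cohort(cfg)
            emp = np.corrcoef(cohort.sessions[0].data, rowvar=False)
            target = np.asarray(cfg.base_connectivity)
            dists.append(np.linalg.norm(emp - target))
        assert dists[0] > dists[1] > dists[2]

    @pytest.mark.parametrize("ar,expected", [(0.0, 0.0), (0.5, 0.5)])
    def test_lag1_autocorrelation(self, ar, expected):
        cfg = SyntheticCohortConfig(
            n_subjects=2, n_volumes=10_000, subject_jitter=0.0, ar_coefficient=ar, seed=21
        )
        data = generate_cohort(cfg).sessions[0].data
        lag1 = np.mean(
            [np.corrcoef(data[:-1, k], data[1:, k])[0, 1] for k in range(data.shape[1])]
        )
        assert lag1 == pytest.approx(expected, abs=0.05)

    def test_ar_filter_preserves_cross_roi_correlation(self, roi_set):
        cfg = SyntheticCohortConfig(
            n_subjects=2, n_volumes=50_000, subject_jitter=0.0, ar_coefficient=0.6, seed=4
        )
        cohort = generate_cohort(cfg)
        i, j = roi_set.index("LateralParietal_L"), roi_set.index("LateralParietal_R")
        emp = np.corrcoef(cohort.sessions[0].data[:, i], cohort.sessions[0].data[:, j])[0, 1]
        assert emp == pytest.approx(cfg.base_connectivity[i, j], abs=0.03)

    def test_injected_effect_raises_post_correlation_only(self, roi_set):
        effect = EffectSpec("LateralParietal_L", ("BA1_L",), 0.35)
        cfg = SyntheticCohortConfig(
            n_subjects=2, n_volumes=20_000, subject_jitter=0.0, ar_coefficient=0.0,
            effects=(effect,), seed=13,
        )
        cohort = generate_cohort(cfg)
        i, j = roi_set.index("LateralParietal_L"), roi_set.index("BA1_L")
        r_pre = pearson_matrix(cohort.session("sub-01", "pre")).values[i, j]
        r_post = pearson_matrix(cohort.session("sub-01", "post")).values[i, j]
        assert r_post - r_pre == pytest.approx(0.35, abs=0.05)


class TestWriteCohort(object):
    def test_files_and_manifest(self, tmp_path, small_cohort):
        manifest_path = write_cohort(small_cohort, tmp_path)
        import json

        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["subjects"]) == 4
        for entry in manifest["subjects"]:
            for sess in ("pre", "post"):
                assert (tmp_path / entry[sess]).exists()
        assert manifest["config"]["n_subjects"] == 4
        assert manifest["config"]["seed"] == 7
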