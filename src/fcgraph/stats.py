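"""Paired pre/post comparison of network indexes.

Every ROI x metric cell (and small-worldness per density) is compared
across sessions with the Wilcoxon signed-rank test. At the cohort sizes
this design targets (n = 8 pairs) the normal approximation is unreliable,
so exact p-values are computed by enumerating the signed-rank distribution
whenever the sample is small and untied; the approximation (with tie
correction) is the fallback. Zero differences are dropped before ranking
(Wilcoxon's original convention). No multiple-comparison correction is
applied by default — the design reports uncorrected p < alpha per cell —
but Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "compare_cohort",
    "radar_normalize",
]

EXACT_MAX_N = 12


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of a paired signed-rank test.

    ``statistic`` is W = the sum of the ranks of positive differences
    (0 <= W <= m(m+1)/2 with m the number of nonzero differences).
    """

    statistic: float
    pvalue: float
    n_used: int
    method: str

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


@lru_cache(maxsize=256)
def _signed_rank_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Distribution of 2*W over all sign assignments of the given ranks.

    ``counts[s]`` = number of the 2^m subsets of `doubled_ranks` whose sum
    is s. Ranks are doubled so mid-ranks (ties) stay integral.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def _exact_pvalue(w: float, doubled_ranks: tuple[int, ...]) -> float:
    """Two-sided exact p: mass at least as far from the mean as W, both tails."""
    counts = _signed_rank_counts(doubled_ranks)
    total2 = sum(doubled_ranks)
    w2 = int(round(2 * w))
    w2_small = min(w2, total2 - w2)
    lower = counts[: w2_small + 1].sum()
    upper = counts[total2 - w2_small :].sum()
    return min(1.0, float((lower + upper) / counts.sum()))


def _approx_pvalue(w: float, ranks: np.ndarray, correction: bool) -> float:
    """Normal approximation with tie correction (variance from rank values)."""
    m = ranks.size
    mean = m * (m + 1) / 4.0
    var = float(np.sum(ranks**2)) / 4.0  # equals m(m+1)(2m+1)/24 when untied
    if var == 0:
        return 1.0
    d = w - mean
    if correction and d != 0:
        d -= 0.5 * math.copysign(1.0, d)
    z = d / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    *,
    mode: Literal["auto", "exact", "approx"] = "auto",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
    continuity_correction: bool = False,
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test of post vs pre.

    Differences d = post - pre are ranked by absolute value with mid-ranks
    for ties; W is the rank sum of positive differences. With
    ``zero_method="wilcox"`` (default) zero differences are dropped before
    ranking; ``"pratt"`` keeps them in the ranking but excludes their ranks
    from W. ``mode="auto"`` enumerates the exact two-sided p-value when the
    retained sample is small (m <= 12) and untied, otherwise falls back to
    the tie-corrected normal approximation. ``mode="exact"`` forces
    enumeration (valid with ties, the distribution is built from the
    observed mid-ranks); ``mode="approx"`` forces the approximation.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if pre_arr.shape != post_arr.shape or pre_arr.ndim != 1:
        raise ValueError("pre and post must be 1-D sequences of equal length")
    if pre_arr.size < 2:
        raise ValueError(f"need at least 2 pairs, got {pre_arr.size}")
    d = post_arr - pre_arr
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError(f"unknown zero_method {zero_method!r}")
    m = int(np.count_nonzero(d))
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, method="degenerate")
    ranks_all = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        nonzero = d != 0
        ranks = ranks_all[nonzero]
        w = float(ranks_all[d > 0].sum())
        d = d[nonzero]
    else:
        ranks = ranks_all
        w = float(ranks_all[d > 0].sum())
    has_ties = np.unique(ranks).size < ranks.size
    if mode == "auto":
        use_exact = m <= EXACT_MAX_N and not has_ties
    elif mode == "exact":
        if m > 20:
            raise ValueError(f"exact enumeration infeasible for m = {m} (> 20)")
        use_exact = True
    elif mode == "approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if use_exact:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        p = _exact_pvalue(w, doubled)
        method = "exact"
    else:
        p = _approx_pvalue(w, ranks, continuity_correction)
        method = "approx"
    return WilcoxonResult(statistic=w, pvalue=p, n_used=m, method=method)


def _direction(median_diff: float) -> str:
    if median_diff > 0:
        return "increase"
    if median_diff < 0:
        return "decrease"
    return "none"


def _paired_cell(
    pre_vals: np.ndarray, post_vals: np.ndarray, **wilcoxon_kwargs
) -> dict:
    """Test one cell; NaN-bearing pairs (e.g. isolated-node path length) dropped."""
    ok = np.isfinite(pre_vals) & np.isfinite(post_vals)
    pre_vals, post_vals = pre_vals[ok], post_vals[ok]
    n_pairs = int(pre_vals.size)
    if n_pairs < 2:
        return {
            "n_pairs": n_pairs, "W": np.nan, "p_value": np.nan, "direction": "none",
            "median_pre": np.nan, "median_post": np.nan,
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon_signed_rank(pre_vals, post_vals, **wilcoxon_kwargs)
    med_pre = float(np.median(pre_vals))
    med_post = float(np.median(post_vals))
    return {
        "n_pairs": n_pairs,
        "W": res.statistic,
        "p_value": res.pvalue,
        "direction": _direction(float(np.median(post_vals - pre_vals))),
        "median_pre": med_pre,
        "median_post": med_post,
    }


def _complete_subjects(frame: pd.DataFrame) -> list:
    """Subjects with both sessions; others are dropped with a warning."""
    per_subject = frame.groupby("subject")["session"].agg(lambda s: set(s))
    complete = sorted(s for s, sess in per_subject.items() if {"pre", "post"} <= sess)
    incomplete = sorted(set(per_subject.index) - set(complete))
    if incomplete:
        warnings.warn(f"subjects missing a session, excluded: {incomplete}")
    if len(complete) < 2:
        raise ValueError(f"need >= 2 complete pre/post pairs, got {len(complete)}")
    return complete


def compare_cohort(
    nodal: pd.DataFrame,
    sweep: Optional[pd.DataFrame] = None,
    *,
    alpha: float = 0.05,
    density_mode: Literal["reference", "per_density", "aggregate"] = "reference",
    reference_density: float = 0.25,
    correction: Optional[Literal["fdr_bh"]] = None,
    **wilcoxon_kwargs,
) -> pd.DataFrame:
    """Paired pre/post comparison of every ROI x metric cell (and s(k)).

    Parameters
    ----------
    nodal : DataFrame
        Long-format nodal metrics with columns
        ``subject, session, density, roi, metric, value``.
    sweep : DataFrame, optional
        Small-worldness records with columns ``subject, session, density, s``;
        compared per density under ``roi="network"``.
    density_mode : str
        ``"reference"`` — compare nodal metrics at `reference_density` only
        (default; the density singled out for reporting);
        ``"per_density"`` — one row per ROI x metric x density;
        ``"aggregate"`` — mean over the sweep per subject/session first.
    correction : str, optional
        ``"fdr_bh"`` applies Benjamini-Hochberg across all rows (a modern
        option; per-cell uncorrected testing is the default convention here).

    Returns
    -------
    DataFrame with one row per cell: roi, metric, density, n_pairs, W,
    p_value, direction, median_pre, median_post, significant.
    """
    subjects = _complete_subjects(nodal)
    nodal = nodal[nodal["subject"].isin(subjects)]

    if density_mode == "reference":
        sel = nodal[np.isclose(nodal["density"].astype(float), reference_density)]
        if sel.empty:
            raise ValueError(
                f"no nodal rows at reference density {reference_density}; "
                f"available: {sorted(nodal['density'].unique())}"
            )
        cells = sel.assign(density_tag=sel["density"])
    elif density_mode == "per_density":
        cells = nodal.assign(density_tag=nodal["density"])
    elif density_mode == "aggregate":
        agg = (
            nodal.groupby(["subject", "session", "roi", "metric"], as_index=False)["value"]
            .mean()
        )
        cells = agg.assign(density_tag="mean")
    else:
        raise ValueError(f"unknown density_mode {density_mode!r}")

    # one vectorized scatter instead of a pivot per cell (the hot path when
    # this runs inside Monte-Carlo calibration loops)
    key = pd.MultiIndex.from_arrays(
        [cells["roi"], cells["metric"], cells["density_tag"]]
    )
    cell_codes, cell_keys = pd.factorize(key)
    sub_codes = pd.Categorical(cells["subject"], categories=subjects).codes
    sess_codes = (cells["session"].to_numpy() == "post").astype(int)
    values = np.full((len(cell_keys), 2, len(subjects)), np.nan)
    values[cell_codes, sess_codes, sub_codes] = cells["value"].to_numpy(float)
    rows = []
    for idx, (roi, metric, tag) in enumerate(cell_keys):
        cell = _paired_cell(values[idx, 0], values[idx, 1], **wilcoxon_kwargs)
        rows.append({"roi": roi, "metric": metric, "density": tag, **cell})

    if sweep is not None and len(sweep):
        sw = sweep[sweep["subject"].isin(subjects)]
        for density, grp in sw.groupby("density", sort=True):
            wide = grp.pivot_table(index="subject", columns="session", values="s", aggfunc="first")
            wide = wide.reindex(index=subjects, columns=["pre", "post"])
            cell = _paired_cell(
                wide["pre"].to_numpy(float), wide["post"].to_numpy(float), **wilcoxon_kwargs
            )
            rows.append(
                {"roi": "network", "metric": "small_worldness", "density": density, **cell}
            )

    out = pd.DataFrame(rows)
    out = out.sort_values(["metric", "roi", "density"], kind="stable").reset_index(drop=True)
    if correction == "fdr_bh":
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = sps.false_discovery_control(out.loc[mask, "p_value"], method="bh")
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    elif correction is None:
        out["significant"] = out["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def radar_normalize(
    comparison: pd.DataFrame, *, only_significant: bool = True
) -> pd.DataFrame:
    """Post-treatment medians normalized by the pre-treatment median.

    One row per (roi, metric): ``normalized_post = median_post / median_pre``
    (1.0 means no median change; below 1 is a decrease). Restricted to rows
    flagged significant by default, mirroring a radar-chart summary of only
    the indexes that changed. Rows with a zero pre-median are skipped with a
    warning.
    """
    rows = comparison[comparison["significant"]] if only_significant else comparison
    out = []
    for _, row in rows.iterrows():
        if not np.isfinite(row["median_pre"]) or row["median_pre"] == 0:
            warnings.warn(
                f"radar normalization skipped for ({row['roi']}, {row['metric']}): "
                f"pre-median is {row['median_pre']}"
            )
            continue
        out.append(
            {
                "roi": row["roi"],
                "metric": row["metric"],
                "density": row["density"],
                "normalized_post": row["median_post"] / row["median_pre"],
            }
        )
    return pd.DataFrame(out, columns=["roi", "metric", "density", "normalized_post"])
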