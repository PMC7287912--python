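"""Monte-Carlo calibration of the full testing procedure.

These routines validate the end-to-end statistical behavior of the
pipeline on the synthetic cohort: the type-I error of the per-cell paired
Wilcoxon procedure under the no-effect generator, and the power to flag a
known injected connectivity change in the cell it targets. Both run the
real analysis code path (generation -> correlation -> thresholding ->
metrics -> tests); only the density sweep is restricted to the reference
density, which is the comparison the cells use.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import pearson_matrix, threshold_to_density
from .metrics import nodal_metric_table
from .simulate import Cohort, EffectSpec, SyntheticCohortConfig, generate_cohort
from .stats import compare_cohort

__all__ = [
    "cohort_nodal_table",
    "replicate_comparison",
    "type_i_error_rate",
    "power_target_cell",
    "POWER_EFFECT_PARTNERS",
]

#: Partner ROIs of the canonical injected effect: the six bilateral
#: somatosensory ROIs (most headroom below the correlation clip bound).
POWER_EFFECT_PARTNERS = ("BA1_L", "BA1_R", "BA2_L", "BA2_R", "BA3_L", "BA3_R")


def _replicate_seed(master_seed: int, replicate: int) -> int:
    return int(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,)).generate_state(1)[0]
        % (2**31)
    )


def cohort_nodal_table(cohort: Cohort, densities: Sequence[float]) -> pd.DataFrame:
    """Long-format nodal metric table of a cohort over the given densities."""
    rows = []
    for ts in cohort.sessions:
        cm = pearson_matrix(ts)
        for density in densities:
            table = nodal_metric_table(threshold_to_density(cm, density))
            for roi, row in table.iterrows():
                for metric, value in row.items():
                    rows.append(
                        {
                            "subject": ts.subject, "session": ts.session,
                            "density": density, "roi": roi, "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def replicate_comparison(
    seed: int,
    effects: Sequence[EffectSpec] = (),
    *,
    reference_density: float = 0.25,
    alpha: float = 0.05,
    config: Optional[SyntheticCohortConfig] = None,
) -> pd.DataFrame:
    """One synthetic cohort analyzed at the reference density."""
    if config is None:
        config = SyntheticCohortConfig(effects=tuple(effects), seed=seed)
    cohort = generate_cohort(config)
    nodal = cohort_nodal_table(cohort, [reference_density])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compare_cohort(
            nodal, None, alpha=alpha,
            density_mode="reference", reference_density=reference_density,
        )


def type_i_error_rate(
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    reference_density: float = 0.25,
) -> tuple[float, int]:
    """Fraction of (ROI, metric) cells flagged under the no-effect generator.

    Returns ``(rate, n_cells_total)``. Under a calibrated procedure the
    rate should sit near `alpha` (discreteness of the exact signed-rank
    distribution at n = 8 pairs makes it land slightly below).
    """
    flagged = 0
    total = 0
    for rep in range(n_replicates):
        comp = replicate_comparison(
            _replicate_seed(seed, rep), reference_density=reference_density, alpha=alpha
        )
        testable = comp["p_value"].notna()
        flagged += int((comp.loc[testable, "p_value"] < alpha).sum())
        total += int(testable.sum())
    return flagged / total, total


def power_target_cell(
    n_replicates: int = 100,
    seed: int = 0,
    *,
    delta: float = 0.35,
    target_roi: str = "LateralParietal_L",
    partner_rois: Sequence[str] = POWER_EFFECT_PARTNERS,
    subject_jitter: float = 0.05,
    metric: str = "degree",
    expected_direction: str = "increase",
    alpha: float = 0.05,
    reference_density: float = 0.25,
) -> float:
    """Fraction of replicates flagging the targeted cell in the injected direction.

    The canonical effect raises the post-session correlation between the
    target ROI and each partner by `delta`, which should raise the target's
    degree at the reference density.
    """
    effect = EffectSpec(target_roi=target_roi, partner_rois=tuple(partner_rois), delta=delta)
    hits = 0
    for rep in range(n_replicates):
        rep_seed = _replicate_seed(seed, rep)
        config = SyntheticCohortConfig(
            effects=(effect,), subject_jitter=subject_jitter, seed=rep_seed
        )
        comp = replicate_comparison(
            rep_seed, reference_density=reference_density, alpha=alpha, config=config
        )
        cell = comp[(comp["roi"] == target_roi) & (comp["metric"] == metric)]
        if len(cell) == 1:
            row = cell.iloc[0]
            if bool(row["significant"]) and row["direction"] == expected_direction:
                hits += 1
    return hits / n_replicates
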