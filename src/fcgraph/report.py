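"""Figure generation: per-cell pre/post boxplots and the radar summary.

Replaces 3D surface renderings with flat artifacts: one boxplot pair per
significant (ROI, metric) cell and a polar "radar" chart of post/pre
median ratios for the significant indexes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import ResultBundle

logger = logging.getLogger(__name__)

__all__ = ["boxplot_cell", "radar_chart", "write_figures"]


def _cell_values(bundle: ResultBundle, roi: str, metric: str, density) -> pd.DataFrame:
    if roi == "network" and metric == "small_worldness":
        frame = bundle.sweep[np.isclose(bundle.sweep["density"], float(density))]
        return frame.rename(columns={"s": "value"})[["subject", "session", "value"]]
    frame = bundle.nodal
    sel = (
        (frame["roi"] == roi)
        & (frame["metric"] == metric)
        & np.isclose(frame["density"].astype(float), float(density))
    )
    return frame.loc[sel, ["subject", "session", "value"]]


def boxplot_cell(bundle: ResultBundle, roi: str, metric: str, density, ax=None):
    """Pre (left) vs post (right) boxplot of one cell's per-subject values."""
    values = _cell_values(bundle, roi, metric, density)
    pre = values.loc[values["session"] == "pre", "value"].dropna()
    post = values.loc[values["session"] == "post", "value"].dropna()
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.6))
    ax.boxplot([pre, post], tick_labels=["pre", "post"], widths=0.5)
    ax.set_title(f"{roi}\n{metric} @ density {density}", fontsize=9)
    ax.set_ylabel(metric)
    return ax


def radar_chart(radar: pd.DataFrame, ax=None):
    """Polar chart of post/pre median ratios with the unit contour marked."""
    if radar.empty:
        raise ValueError("radar table is empty (no significant cells)")
    labels = [f"{r.metric}\n({r.roi})" for r in radar.itertuples()]
    values = radar["normalized_post"].to_list()
    angles = np.linspace(0, 2 * np.pi, len(values), endpoint=False).tolist()
    closed_vals = values + values[:1]
    closed_angles = angles + angles[:1]
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5), subplot_kw={"projection": "polar"})
    ax.plot(closed_angles, closed_vals, "o-", linewidth=1.5)
    ax.plot(closed_angles, [1.0] * len(closed_angles), "--", color="gray", linewidth=1)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_title("post / pre median index ratio", fontsize=10)
    return ax


def write_figures(bundle: ResultBundle, out_dir: Union[str, Path]) -> list[Path]:
    """Write a boxplot per significant cell and the radar chart as PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sig = bundle.comparison[bundle.comparison["significant"]]
    for row in sig.itertuples():
        fig, ax = plt.subplots(figsize=(3.2, 3.6))
        boxplot_cell(bundle, row.roi, row.metric, row.density, ax=ax)
        fig.tight_layout()
        path = out_dir / f"boxplot_{row.roi}_{row.metric}_{row.density}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if not bundle.radar.empty:
        fig, ax = plt.subplots(figsize=(4.5, 4.5), subplot_kw={"projection": "polar"})
        radar_chart(bundle.radar, ax=ax)
        fig.tight_layout()
        path = out_dir / "radar.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    logger.info("wrote %d figures to %s", len(written), out_dir)
    return written
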