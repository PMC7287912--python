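"""Synthetic paired (pre/post) ROI time-series cohorts.

The generator emulates, at ROI level, a paired resting-state acquisition:
each subject's session is a zero-mean multivariate Gaussian series whose
cross-ROI correlation matrix is a per-subject jittered copy of a target
"base" correlation structure, optionally passed through a first-order
autoregressive (AR(1)) temporal filter re-scaled so the cross-ROI
correlation target is preserved. Treatment effects are injected as signed
increments on chosen correlation entries of the post session, so downstream
detection can be validated against a known ground truth.

Defaults mirror a small longitudinal cohort: 8 subjects, 150 volumes per
session (7 min 30 s at TR = 3 s), the 14-region pain/DMN parcellation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .connectivity import TimeSeriesSession
from .rois import DMN, PAIN, RoiSet, default_roi_set

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "SyntheticCohortConfig",
    "Cohort",
    "default_base_connectivity",
    "nearest_psd_correlation",
    "apply_effect",
    "generate_cohort",
    "write_cohort",
]

PSD_TOL = 1e-8


@dataclass(frozen=True)
class EffectSpec:
    """A connectivity change injected into one session.

    `delta` is added to the correlation between `target_roi` and each
    partner; results are clipped to [-0.99, 0.99] and the matrix is
    repaired to the nearest positive semi-definite correlation if needed.
    """

    target_roi: str
    partner_rois: Union[Sequence[str], Literal["ALL"]] = "ALL"
    delta: float = 0.0
    session: Literal["pre", "post"] = "post"


def default_base_connectivity(roi_set: Optional[RoiSet] = None) -> np.ndarray:
    """Block-structured target correlation matrix for the default parcellation.

    Within-network correlations are moderate (pain 0.25, DMN 0.35),
    homotopic left/right pairs of the same area are stronger (0.45), and
    cross-network correlations are weak (0.05) — the qualitative structure
    of resting-state ROI correlation matrices. PSD-repaired on construction.
    """
    roi_set = roi_set or default_roi_set()
    n = roi_set.n
    base = np.full((n, n), 0.05)
    for i, a in enumerate(roi_set.labels):
        for j, b in enumerate(roi_set.labels):
            if i == j:
                continue
            na, nb = roi_set.network.get(a), roi_set.network.get(b)
            if na == nb == PAIN:
                base[i, j] = 0.25
            elif na == nb == DMN:
                base[i, j] = 0.35
            stem_a, _, hemi_a = a.rpartition("_")
            stem_b, _, hemi_b = b.rpartition("_")
            if stem_a and stem_a == stem_b and {hemi_a, hemi_b} == {"L", "R"}:
                base[i, j] = 0.45
    np.fill_diagonal(base, 1.0)
    return nearest_psd_correlation(base)


def nearest_psd_correlation(m: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Nearest positive semi-definite correlation surrogate.

    Eigenvalues are clipped at `tol` and the result is re-normalized to
    unit diagonal (a congruence transform, so positive semi-definiteness is
    preserved exactly).
    """
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= -tol and np.allclose(np.diag(m), 1.0, atol=1e-12):
        return m
    w = np.clip(w, tol, None)
    repaired = (v * w) @ v.T
    d = np.diag(repaired)
    if np.any(d <= 0):
        raise ValueError("matrix cannot be repaired to a correlation matrix (non-positive diagonal)")
    scale = 1.0 / np.sqrt(d)
    repaired = repaired * scale[:, None] * scale[None, :]
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass
class SyntheticCohortConfig:
    """Conditions of the simulated paired cohort.

    Parameters
    ----------
    n_subjects : int
        Paired subjects (default 8).
    n_volumes : int
        Volumes per session (default 150: 7 min 30 s at TR = 3 s).
    tr : float
        Repetition time in seconds (default 3.0).
    base_connectivity : ndarray, optional
        Target inter-ROI correlation matrix (symmetric, unit diagonal,
        entries in [-1, 1]); defaults to the block structure of
        :func:`default_base_connectivity`.
    subject_jitter : float
        Standard deviation of the per-subject Gaussian perturbation of the
        off-diagonal base correlations; shared between a subject's pre and
        post sessions, which is what makes the paired design meaningful.
    ar_coefficient : float
        Lag-1 autocorrelation of each ROI series, in [0, 1).
    effects : sequence of EffectSpec
        Connectivity changes injected into the designated session.
    seed : int
        Master seed; per-subject/per-session streams are derived from it by
        fixed offsets, so generation is order-independent and bit-reproducible.
    """

    n_subjects: int = 8
    n_volumes: int = 150
    tr: float = 3.0
    roi_set: RoiSet = field(default_factory=default_roi_set)
    base_connectivity: Optional[np.ndarray] = None
    subject_jitter: float = 0.05
    ar_coefficient: float = 0.3
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_volumes < 10:
            raise ValueError("n_volumes must be >= 10")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be non-negative")
        if self.base_connectivity is None:
            self.base_connectivity = default_base_connectivity(self.roi_set)
        base = np.asarray(self.base_connectivity, dtype=float)
        if base.shape != (self.roi_set.n, self.roi_set.n):
            raise ValueError(
                f"base_connectivity shape {base.shape} does not match "
                f"{self.roi_set.n} ROIs"
            )
        if not np.allclose(base, base.T, atol=1e-10):
            raise ValueError("base_connectivity must be symmetric")
        if not np.allclose(np.diag(base), 1.0, atol=1e-10):
            raise ValueError("base_connectivity must have unit diagonal")
        if np.abs(base).max() > 1.0 + 1e-12:
            raise ValueError("base_connectivity entries must lie in [-1, 1]")
        self.base_connectivity = nearest_psd_correlation(base)
        self.effects = tuple(self.effects)
        for eff in self.effects:
            self.roi_set.index(eff.target_roi)  # raises on unknown label
            if eff.partner_rois != "ALL":
                for p in eff.partner_rois:
                    self.roi_set.index(p)


@dataclass
class Cohort:
    """A generated paired cohort: sessions plus their ground-truth covariances."""

    config: SyntheticCohortConfig
    sessions: list[TimeSeriesSession]
    covariances: dict[tuple[str, str], np.ndarray]

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject for s in self.sessions})

    def session(self, subject: str, session: str) -> TimeSeriesSession:
        for s in self.sessions:
            if s.subject == subject and s.session == session:
                return s
        raise KeyError(f"no session {session!r} for subject {subject!r}")


def apply_effect(cov: np.ndarray, effect: EffectSpec, roi_set: RoiSet) -> np.ndarray:
    """Add `effect.delta` to each (target, partner) correlation entry.

    Entries pushed outside [-0.99, 0.99] are clipped with a warning; the
    result is PSD-repaired if the increment breaks positive semi-definiteness.
    Only entries incident to (target, partner) pairs differ from the input
    (up to the PSD repair).
    """
    out = np.asarray(cov, dtype=float).copy()
    ti = roi_set.index(effect.target_roi)
    if effect.partner_rois == "ALL":
        partners = [i for i in range(roi_set.n) if i != ti]
    else:
        partners = [roi_set.index(p) for p in effect.partner_rois]
        if ti in partners:
            raise ValueError(f"target ROI {effect.target_roi!r} cannot be its own partner")
    for pi in partners:
        new = out[ti, pi] + effect.delta
        if abs(new) > 0.99:
            warnings.warn(
                f"effect on ({effect.target_roi}, {roi_set.labels[pi]}) pushes "
                f"correlation to {new:.3f}; clipped to ±0.99"
            )
            new = float(np.clip(new, -0.99, 0.99))
        out[ti, pi] = out[pi, ti] = new
    if np.linalg.eigvalsh(out).min() < -PSD_TOL:
        out = nearest_psd_correlation(out)
    return out


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = corr (eigen-based; tolerates semi-definiteness)."""
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _session_series(
    corr: np.ndarray, n_volumes: int, ar: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1)-filtered Gaussian series with stationary cross-ROI correlation `corr`."""
    n = corr.shape[0]
    factor = _correlation_factor(corr)
    innovations = rng.standard_normal((n_volumes, n)) @ factor.T
    if ar == 0.0:
        return innovations
    x = np.empty_like(innovations)
    scale = np.sqrt(1.0 - ar**2)
    x[0] = innovations[0]  # stationary start: x_0 ~ N(0, corr)
    for t in range(1, n_volumes):
        x[t] = ar * x[t - 1] + scale * innovations[t]
    return x


def _stream(seed: int, subject_idx: int, stream_id: int) -> np.random.Generator:
    """Deterministic per-(subject, purpose) random stream from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_idx, stream_id))
    )


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate pre and post sessions for every subject.

    Each subject's correlation matrix is the base structure plus a
    symmetric Gaussian jitter on the off-diagonals (shared across the
    subject's two sessions), PSD-repaired. Effects modify the designated
    session's matrix only. Bit-identical output for identical config+seed.
    """
    sessions: list[TimeSeriesSession] = []
    covariances: dict[tuple[str, str], np.ndarray] = {}
    n = config.roi_set.n
    iu, ju = np.triu_indices(n, k=1)
    for si in range(config.n_subjects):
        subject = f"sub-{si + 1:02d}"
        subject_corr = np.asarray(config.base_connectivity).copy()
        if config.subject_jitter > 0:
            jitter_rng = _stream(config.seed, si, 0)
            noise = jitter_rng.normal(0.0, config.subject_jitter, size=iu.size)
            subject_corr[iu, ju] += noise
            subject_corr[ju, iu] = subject_corr[iu, ju]
            subject_corr = np.clip(subject_corr, -0.99, 0.99)
            np.fill_diagonal(subject_corr, 1.0)
            subject_corr = nearest_psd_correlation(subject_corr)
        for stream_id, sess in ((1, "pre"), (2, "post")):
            corr = subject_corr
            for eff in config.effects:
                if eff.session == sess:
                    corr = apply_effect(corr, eff, config.roi_set)
            covariances[(subject, sess)] = corr
            data = _session_series(
                corr, config.n_volumes, config.ar_coefficient, _stream(config.seed, si, stream_id)
            )
            sessions.append(
                TimeSeriesSession(
                    subject=subject, session=sess, data=data, tr=config.tr,
                    roi_set=config.roi_set,
                )
            )
    return Cohort(config=config, sessions=sessions, covariances=covariances)


def _config_echo(config: SyntheticCohortConfig) -> dict:
    return {
        "n_subjects": config.n_subjects,
        "n_volumes": config.n_volumes,
        "tr": config.tr,
        "roi_labels": list(config.roi_set.labels),
        "base_connectivity": np.asarray(config.base_connectivity).round(10).tolist(),
        "subject_jitter": config.subject_jitter,
        "ar_coefficient": config.ar_coefficient,
        "effects": [
            {
                "target_roi": e.target_roi,
                "partner_rois": e.partner_rois if e.partner_rois == "ALL" else list(e.partner_rois),
                "delta": e.delta,
                "session": e.session,
            }
            for e in config.effects
        ],
        "seed": config.seed,
    }


def write_cohort(cohort: Cohort, out_dir: Union[str, Path]) -> Path:
    """Write one CSV per subject-session plus a cohort manifest JSON.

    Files are named ``sub-<id>_<pre|post>.csv`` with an ROI-label header
    row and one row per volume. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = cohort.config.roi_set.labels
    manifest: dict = {"seed": cohort.config.seed, "tr": cohort.config.tr, "subjects": []}
    for subject in cohort.subjects:
        entry = {"id": subject}
        for sess in ("pre", "post"):
            ts = cohort.session(subject, sess)
            fname = f"{subject}_{sess}.csv"
            header = ",".join(labels)
            np.savetxt(
                out_dir / fname, ts.data, delimiter=",", header=header, comments="",
                fmt="%.10g",
            )
            entry[sess] = fname
        manifest["subjects"].append(entry)
    manifest["config"] = _config_echo(cohort.config)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %d sessions and manifest to %s", len(cohort.sessions), out_dir)
    return manifest_path
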