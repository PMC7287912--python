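"""Region-of-interest (ROI) sets: labeled network nodes with annotations.

The default parcellation is a 14-region pain / default-mode-network (DMN)
set: bilateral Brodmann areas 1, 2, 3 (primary somatosensory), 13 (insula)
and 32 (anterior cingulate) form the pain network; the medial prefrontal
cortex (mPFC), posterior cingulate cortex (PCC) and bilateral lateral
parietal cortices form the DMN.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

PAIN = "pain"
DMN = "DMN"

__all__ = ["RoiSet", "default_roi_set", "PAIN", "DMN"]


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of labeled ROIs with network and hemisphere annotations.

    Parameters
    ----------
    labels : tuple of str
        Unique ROI labels, in column order of the time-series matrices.
    network : dict
        Maps each label to its network membership (``"pain"`` or ``"DMN"``).
    hemisphere : dict
        Maps each label to ``"L"``, ``"R"`` or ``"midline"``.
    """

    labels: tuple[str, ...]
    network: dict[str, str] = field(default_factory=dict)
    hemisphere: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        for mapping, name in ((self.network, "network"), (self.hemisphere, "hemisphere")):
            unknown = set(mapping) - set(self.labels)
            if unknown:
                raise ValueError(f"{name} annotation for unknown labels: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Position of `label` in the ordered label list."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label {label!r}; known: {list(self.labels)}") from None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "network", "hemisphere"])
            for l in self.labels:
                w.writerow([l, self.network.get(l, ""), self.hemisphere.get(l, "")])

    @classmethod
    def from_csv(cls, path) -> "RoiSet":
        labels, network, hemisphere = [], {}, {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                label = row["label"].strip()
                labels.append(label)
                if row.get("network"):
                    network[label] = row["network"].strip()
                if row.get("hemisphere"):
                    hemisphere[label] = row["hemisphere"].strip()
        return cls(tuple(labels), network, hemisphere)


def default_roi_set() -> RoiSet:
    """The 14-region pain + DMN parcellation used throughout.

    Pain network (10 ROIs): BA1, BA2, BA3, BA13, BA32, each bilateral.
    DMN (4 ROIs): mPFC, PCC, left and right lateral parietal cortex.
    """
    pain_areas = ["BA1", "BA2", "BA3", "BA13", "BA32"]
    labels: list[str] = []
    network: dict[str, str] = {}
    hemisphere: dict[str, str] = {}
    for area in pain_areas:
        for hemi in ("L", "R"):
            label = f"{area}_{hemi}"
            labels.append(label)
            network[label] = PAIN
            hemisphere[label] = hemi
    for label, hemi in (
        ("mPFC", "midline"),
        ("PCC", "midline"),
        ("LateralParietal_L", "L"),
        ("LateralParietal_R", "R"),
    ):
        labels.append(label)
        network[label] = DMN
        hemisphere[label] = hemi
    return RoiSet(tuple(labels), network, hemisphere)
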