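"""Landmark configurations.

A study configuration is 8 fixed anatomical landmarks (S1..S8) plus 65
curve semilandmarks on 8 curves (C1..C8), 73 points in all:

    S1-S2 tip of the talon (dorsal / ventral edge); S3 talon midpoint
    height; S4 ventral end of the inner curvature; S5 tip of the flexor
    tubercle; S6 tip of the extensor tubercle; S7-S8 ventral foramina;
    C1 distal outer curvature; C2 inner curvature; C3 proximal outer
    curvature; C4 ventral curvature; C5-C6 talon maximum width;
    C7-C8 lateral borders of the articular facet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIXED = "fixed"
SEMILANDMARK = "semilandmark"

#: number of semilandmarks per curve in the default 73-point scheme
DEFAULT_CURVE_COUNTS = {"C1": 10, "C2": 10, "C3": 9, "C4": 8,
                        "C5": 7, "C6": 7, "C7": 7, "C8": 7}


@dataclass
class LandmarkSet:
    """One specimen's named, ordered 3D landmarks (mm)."""

    specimen_id: str
    points: np.ndarray                       # (n, 3)
    labels: list[str]                        # unique, e.g. S1, C1_03
    kind: list[str] = field(default_factory=list)   # fixed | semilandmark
    curve_id: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if np.isnan(self.points).any():
            raise ValueError(f"{self.specimen_id}: NaN coordinates")
        n = len(self.points)
        if not self.kind:
            self.kind = [FIXED if lb.startswith("S") else SEMILANDMARK
                         for lb in self.labels]
        if not self.curve_id:
            self.curve_id = [lb.split("_")[0] if k == SEMILANDMARK else None
                             for lb, k in zip(self.labels, self.kind)]
        if not (len(self.labels) == len(self.kind) == len(self.curve_id) == n):
            raise ValueError("labels/kind/curve_id length mismatch")
        if len(set(self.labels)) != n:
            raise ValueError(f"{self.specimen_id}: duplicate labels")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: list[str]) -> "LandmarkSet":
        idx = [self.index_of(lb) for lb in labels]
        return LandmarkSet(self.specimen_id, self.points[idx],
                           [self.labels[i] for i in idx],
                           [self.kind[i] for i in idx],
                           [self.curve_id[i] for i in idx])

    def fixed_mask(self) -> np.ndarray:
        return np.array([k == FIXED for k in self.kind])

    def semilandmark_mask(self) -> np.ndarray:
        return ~self.fixed_mask()


def default_labels(curve_counts: dict[str, int] | None = None) -> tuple[list[str], list[str], list[str | None]]:
    """Labels/kind/curve for the standard 8 + 65 scheme, in study order."""
    counts = dict(curve_counts or DEFAULT_CURVE_COUNTS)
    labels = [f"S{i}" for i in range(1, 9)]
    kind = [FIXED] * 8
    curve: list[str | None] = [None] * 8
    for c, m in counts.items():
        for j in range(m):
            labels.append(f"{c}_{j:02d}")
            kind.append(SEMILANDMARK)
            curve.append(c)
    return labels, kind, curve


def stack(sets: list[LandmarkSet]) -> np.ndarray:
    """Specimens x points x 3 array; raises on inconsistent point counts."""
    n0 = sets[0].n_points
    for s in sets:
        if s.n_points != n0:
            raise ValueError(
                f"inconsistent point count: specimen '{s.specimen_id}' has "
                f"{s.n_points}, expected {n0}")
    return np.stack([s.points for s in sets])
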