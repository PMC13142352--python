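"""Ligand interaction geometry: centres, pairwise distances, density maxima.

Tracks ligand geometric centres relative to the per-frame pore centre and
builds the ring–ring / oxygen–ion distance distributions used to characterise
π-stacking between ligand phenyl rings, contacts with pore-lining aromatics,
and carbonyl-oxygen coordination of the nearest selectivity-filter K+ ion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import cylinder_center
from .model import Trajectory


@dataclass
class CenterSeries:
    """Per-frame 3D position of a group's geometric centre, relative to the pore centre (Å)."""

    label: str
    positions: np.ndarray  # (n_frames, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")

    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class DistancePairSeries:
    """Per-frame distance between two (possibly centre-reduced) groups (Å)."""

    pair_label: str
    distances: np.ndarray
    pairing_rule: str  # "all-pairs" | "nearest"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class Density2D:
    """2D histogram of paired distance samples with its local maxima."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    maxima: list[tuple[float, float, int]]  # (x centre, y centre, count), count-descending

    def to_csv(self, path: str | Path) -> None:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        df = pd.DataFrame(self.counts, index=pd.Index(xc, name="x_A"), columns=yc)
        df.to_csv(path, float_format="%.6f")


def geometric_center_series(
    traj: Trajectory, group: np.ndarray, refs: np.ndarray, label: str = "center"
) -> CenterSeries:
    """Unweighted mean of the group's coordinates, relative to the pore centre.

    The pore centre is the centroid of the four reference Cα atoms of the same
    frame, so a ligand sitting exactly at the pore centre reads (0, 0, 0).
    """
    group = np.asarray(group)
    if group.size == 0:
        raise ValueError("geometric_center_series: empty atom group")
    centers = traj.coordinates[:, group, :].mean(axis=1)
    pore = np.stack([cylinder_center(traj.coordinates[f], refs) for f in range(traj.n_frames)])
    return CenterSeries(label=label, positions=centers - pore)


def _group_centers(traj: Trajectory, groups: list[np.ndarray]) -> np.ndarray:
    """Reduce each group to its per-frame geometric centre: (n_groups, n_frames, 3)."""
    out = np.empty((len(groups), traj.n_frames, 3))
    for i, g in enumerate(groups):
        g = np.asarray(g)
        if g.size == 0:
            raise ValueError("pairwise_distance_series: empty atom group")
        out[i] = traj.coordinates[:, g, :].mean(axis=1)
    return out


def pairwise_distance_series(
    traj: Trajectory,
    groups_a: list[np.ndarray],
    groups_b: list[np.ndarray],
    rule: str = "all-pairs",
    labels_a: list[str] | None = None,
    labels_b: list[str] | None = None,
) -> list[DistancePairSeries]:
    """Per-frame distances between group centres.

    Each group (a phenyl ring, a pair of carbonyl oxygens, a single ion…) is
    first reduced to its geometric centre.  With ``rule="all-pairs"`` one
    series per (a, b) pair is emitted — when ``groups_a is groups_b`` only the
    C(n, 2) unordered pairs are produced.  With ``rule="nearest"`` a single
    series holds the per-frame minimum over all pairs.
    """
    if not groups_a or not groups_b:
        raise ValueError("pairwise_distance_series: empty group list")
    if rule not in {"all-pairs", "nearest"}:
        raise ValueError(f"unknown pairing rule {rule!r}")
    labels_a = labels_a or [f"a{i}" for i in range(len(groups_a))]
    labels_b = labels_b or [f"b{i}" for i in range(len(groups_b))]

    ca = _group_centers(traj, groups_a)
    same = groups_a is groups_b
    cb = ca if same else _group_centers(traj, groups_b)
    if same:
        pairs = list(combinations(range(len(groups_a)), 2))
        pair_ab = [(i, j) for i, j in pairs]
        labels = [f"{labels_a[i]}-{labels_a[j]}" for i, j in pairs]
    else:
        pair_ab = list(product(range(len(groups_a)), range(len(groups_b))))
        labels = [f"{labels_a[i]}-{labels_b[j]}" for i, j in pair_ab]
    if not pair_ab:
        raise ValueError("no group pairs to compare")

    dists = np.stack([np.linalg.norm(ca[i] - cb[j], axis=1) for i, j in pair_ab])
    if rule == "nearest":
        return [
            DistancePairSeries(
                pair_label="nearest", distances=dists.min(axis=0), pairing_rule="nearest"
            )
        ]
    return [
        DistancePairSeries(pair_label=lab, distances=dists[k], pairing_rule="all-pairs")
        for k, lab in enumerate(labels)
    ]


def density2d_maxima(
    xs: np.ndarray,
    ys: np.ndarray,
    bin_width: float = 0.25,
    min_fraction: float = 0.01,
) -> Density2D:
    """2D histogram with its major local maxima.

    A bin is a maximum when its count is ≥ each of its 8 neighbours and holds
    at least ``min_fraction`` of all points.  Maxima whose bin indices differ
    by less than 2 in both axes are merged, keeping the higher count (avoids
    double-reporting plateaus).  Maxima are returned count-descending as
    (x bin centre, y bin centre, count).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 2:
        raise ValueError("need at least 2 paired samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    def edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        return np.arange(lo, hi + bin_width / 2, bin_width)

    x_edges, y_edges = edges(xs), edges(ys)
    counts, x_edges, y_edges = np.histogram2d(xs, ys, bins=[x_edges, y_edges])

    total = counts.sum()
    threshold = min_fraction * total
    padded = np.pad(counts, 1, constant_values=-1)
    candidates: list[tuple[int, int, int]] = []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c < threshold or c <= 0:
                continue
            window = padded[i : i + 3, j : j + 3]
            if c >= window.max():
                candidates.append((i, j, int(c)))

    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept: list[tuple[int, int, int]] = []
    for i, j, c in candidates:
        if any(abs(i - ki) < 2 and abs(j - kj) < 2 for ki, kj, _ in kept):
            continue
        kept.append((i, j, c))

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    maxima = [(float(xc[i]), float(yc[j]), c) for i, j, c in kept]
    return Density2D(x_edges=x_edges, y_edges=y_edges, counts=counts, maxima=maxima)
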