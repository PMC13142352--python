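"""Per-frame pore hydration, grid-based cavity volume and water density.

All three metrics live inside a z-aligned analysis cylinder that is
re-centred every frame on the centroid of the four pore-lining reference Cα
atoms, so the region tracks the pore as the protein breathes.  Boundary
conventions are exact and stated: a point at xy-distance equal to the radius
(or |Δz| equal to half the height) is *inside* the cylinder; a grid point at
distance exactly ``vdw + buffer`` from a protein atom is *occluded*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import SelectionSet, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class CylinderSpec:
    """The z-aligned analysis cylinder, dynamically centred each frame.

    ``fixed`` mode uses the configured radius (default 10 Å with 12 Å height,
    spanning the central cavity); ``adaptive`` mode instead takes the mean
    xy-distance of the four reference Cα atoms from their centroid, so the
    radius breathes with the pore.
    """

    radius_mode: str = "fixed"
    radius: float = 10.0
    height: float = 12.0

    def __post_init__(self) -> None:
        if self.radius_mode not in {"fixed", "adaptive"}:
            raise ValueError(f"radius_mode must be 'fixed' or 'adaptive', got {self.radius_mode!r}")
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cylinder radius and height must be positive")

    def effective_radius(self, frame: np.ndarray, refs: np.ndarray) -> float:
        if self.radius_mode == "fixed":
            return self.radius
        center = cylinder_center(frame, refs)
        d = np.linalg.norm(frame[refs][:, :2] - center[:2], axis=1)
        return float(d.mean())


@dataclass
class GridSpec:
    """Lattice used for cavity-volume estimation.

    ``spacing`` is the lattice constant (grid cell volume = spacing³);
    ``probe_buffer`` is added to every protein atom's van der Waals radius
    when deciding occlusion.
    """

    spacing: float = 2.0
    probe_buffer: float = 1.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.probe_buffer < 0:
            raise ValueError("probe_buffer must be non-negative")


@dataclass
class FrameSeries:
    """A per-frame scalar metric with its time base."""

    metric_name: str
    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have equal length")

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_ns": self.frame_times,
                "value": self.values,
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path, metric_name: str | None = None) -> "FrameSeries":
        df = pd.read_csv(path)
        return cls(
            metric_name=metric_name or Path(path).stem,
            values=df["value"].to_numpy(),
            frame_times=df["time_ns"].to_numpy(),
        )


def cylinder_center(frame: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the four reference Cα positions for one frame."""
    refs = np.asarray(refs)
    if refs.size != 4:
        raise ValueError(f"expected 4 reference atom indices, got {refs.size}")
    return frame[refs].mean(axis=0)


def _inside_cylinder(points: np.ndarray, center: np.ndarray, radius: float, height: float) -> np.ndarray:
    d = points - center
    r_xy = np.hypot(d[:, 0], d[:, 1])
    return (r_xy <= radius) & (np.abs(d[:, 2]) <= height / 2.0)


def count_pore_waters(traj: Trajectory, sel: SelectionSet, cyl: CylinderSpec) -> FrameSeries:
    """Number of water molecules (by oxygen position) inside the cylinder, per frame.

    A water whose oxygen lies exactly on the cylinder boundary is counted.
    An empty water selection yields an all-zero series with a warning rather
    than an error, so dry systems pass through the pipeline.
    """
    waters = np.asarray(sel.water_oxygens)
    counts = np.zeros(traj.n_frames)
    if waters.size == 0:
        logger.warning("count_pore_waters: empty water selection; returning zeros")
        return FrameSeries("pore_water_count", counts, traj.times)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        center = cylinder_center(frame, sel.pore_reference_ca)
        radius = cyl.effective_radius(frame, sel.pore_reference_ca)
        counts[f] = int(_inside_cylinder(frame[waters], center, radius, cyl.height).sum())
    return FrameSeries("pore_water_count", counts, traj.times)


def _lattice_offsets(radius: float, height: float, spacing: float) -> np.ndarray:
    """Cell-centred lattice points (offsets from the cylinder centre).

    The lattice is anchored at the per-frame centre so the grid translates
    rigidly with the pore; points sit at cell centres (odd multiples of
    spacing/2), so each point represents a disjoint spacing³ cell and the
    empty-cylinder volume converges to πr²h as spacing → 0.
    """
    if spacing > 2 * radius or spacing > height:
        raise ValueError(
            f"degenerate grid: spacing {spacing} Å exceeds cylinder dimensions "
            f"(diameter {2 * radius} Å, height {height} Å)"
        )
    nr = int(np.ceil(radius / spacing))
    nz = int(np.ceil((height / 2.0) / spacing))
    ax = (np.arange(-nr, nr) + 0.5) * spacing
    az = (np.arange(-nz, nz) + 0.5) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, az, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = (np.hypot(pts[:, 0], pts[:, 1]) <= radius) & (np.abs(pts[:, 2]) <= height / 2.0)
    return pts[inside]


def cavity_volume(
    traj: Trajectory,
    sel: SelectionSet,
    cyl: CylinderSpec,
    grid: GridSpec | None = None,
) -> FrameSeries:
    """Grid-based accessible cavity volume inside the cylinder, per frame (Å³).

    Lattice points within ``vdw_radius + probe_buffer`` of any protein atom are
    excluded (waters, ions, lipids and ligands do not occlude); the remaining
    points are multiplied by the grid cell volume.  The neighbour search uses a
    k-d tree with a query radius of ``max(vdw) + buffer`` followed by an exact
    per-atom distance check, so results are identical to the all-pairs test.
    """
    grid = grid or GridSpec()
    protein = np.asarray(sel.protein_atoms)
    radii = traj.topology.vdw_radii[protein] if protein.size else np.empty(0)
    cutoffs = radii + grid.probe_buffer
    max_cut = float(cutoffs.max()) if protein.size else 0.0
    cell = grid.spacing**3

    volumes = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        center = cylinder_center(frame, sel.pore_reference_ca)
        radius = cyl.effective_radius(frame, sel.pore_reference_ca)
        pts = center + _lattice_offsets(radius, cyl.height, grid.spacing)
        if protein.size:
            tree = cKDTree(frame[protein])
            neighbours = tree.query_ball_point(pts, r=max_cut)
            free = np.ones(len(pts), dtype=bool)
            for i, nb in enumerate(neighbours):
                if not nb:
                    continue
                d = np.linalg.norm(frame[protein[nb]] - pts[i], axis=1)
                if np.any(d <= cutoffs[nb]):
                    free[i] = False
            n_free = int(free.sum())
        else:
            n_free = len(pts)
        volumes[f] = n_free * cell
    return FrameSeries("cavity_volume_A3", volumes, traj.times)


def water_density(counts: FrameSeries, volumes: FrameSeries) -> FrameSeries:
    """Water density = molecules per Å³ of cavity volume, per frame.

    Frames with zero volume are undefined (NaN), not zero, and are excluded
    from downstream window summaries.
    """
    if len(counts) != len(volumes) or not np.allclose(counts.frame_times, volumes.frame_times):
        raise ValueError("count and volume series must share frames and times")
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(volumes.values > 0, counts.values / volumes.values, np.nan)
    n_undef = int(np.isnan(dens).sum())
    if n_undef:
        logger.warning("water_density: %d frame(s) with zero volume flagged undefined", n_undef)
    return FrameSeries("water_density_A-3", dens, counts.frame_times)
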