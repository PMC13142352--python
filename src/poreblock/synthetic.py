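"""Synthetic channel-pore trajectories with planted ground truth.

The generator emulates the analysed features of a tetrameric K+ channel pore
region — four pore-lining reference Cα atoms, pore-facing aromatic rings, a
cylindrical hydrated cavity, a selectivity-filter column of K+ ions, 0/1/2/4
rigid two-ring ligand copies and a dummy membrane annulus — without any
physical dynamics.  Every analysable quantity is planted by construction and
returned as :class:`GroundTruth`, so the analysis stages can be tested for
exact recovery.

Key construction guarantees:

* inside-waters are placed with a margin of one grid spacing (2 Å) from the
  cylinder wall and their per-frame jitter is clipped, so the planted
  inside-count is exact for every frame under the fixed-geometry cylinder;
* the applied field acts as a deterministic axial drift on the filter ions
  (clipped noise keeps z monotone), scaled by ``(1 - n_ligand_copies/4)`` so
  four ligand copies block permeation entirely;
* identical seed ⇒ bit-identical coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import (
    Atom,
    Topology,
    Trajectory,
    vdw_radius_for,
    write_dcd,
    write_multi_model_pdb,
    write_topology_pdb,
)

#: jitter is clipped per-coordinate to this fraction of the placement margin,
#: so radial displacement (√2 · clip) and axial displacement stay below the
#: margin and planted inside/outside classifications can never flip.
_JITTER_CLIP_FRACTION = 0.6


class CapacityError(ValueError):
    """More inside-waters requested than the cylinder can hold at 2.8 Å exclusion."""


@dataclass
class SyntheticPoreConfig:
    """Geometry, occupancy and dynamics of one synthetic condition.

    Defaults mirror the simulated control system: a 10 Å × 12 Å pore cylinder
    inside a membrane spanning ±20 Å, 43 inside-waters (the control-condition
    mean occupancy), four K+ ions stacked above the pore in the selectivity
    filter, no ligand and no field.  ``field_strength`` of 10 mV/nm across the
    4 nm membrane corresponds to a 40 mV membrane potential and switches on
    the ion drift.
    """

    n_frames: int = 500
    frame_dt: float = 0.1  # ns
    pore_radius: float = 10.0  # Å
    pore_height: float = 12.0  # Å
    membrane_half_span: float = 20.0  # Å
    n_waters_inside: int = 43
    water_count_sd: float = 0.0  # per-frame occupancy fluctuation (waters exchange with outside)
    n_waters_outside: int = 40
    n_filter_ions: int = 4
    n_ligand_copies: int = 0
    field_strength: float = 0.0  # mV/nm; 0 = off
    ion_drift_per_frame: float = 0.5  # Å per frame when the field is on
    positional_noise_sd: float = 0.3  # Å
    wall_margin: float = 2.0  # Å; one default grid spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pore_radius <= 0 or self.pore_height <= 0:
            raise ValueError("pore_radius and pore_height must be positive")
        for attr in ("n_waters_inside", "n_waters_outside", "n_filter_ions", "n_ligand_copies"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.n_ligand_copies not in {0, 1, 2, 4}:
            raise ValueError("n_ligand_copies must be one of {0, 1, 2, 4}")


@dataclass
class PlantedEvent:
    """A planted complete pore traversal of one filter ion."""

    ion_id: int
    start_frame: int
    end_frame: int
    direction: str  # "inward" | "outward"


@dataclass
class GroundTruth:
    """What the generator planted, for exact-recovery tests."""

    inside_counts: np.ndarray  # per-frame planted inside-water count
    events: list[PlantedEvent]
    ligand_offsets: np.ndarray  # (n_copies, 3) centre offsets from the pore centre

    def to_json(self, path: str | Path) -> None:
        data = {
            "inside_counts": [int(c) for c in self.inside_counts],
            "events": [asdict(e) for e in self.events],
            "ligand_offsets": np.asarray(self.ligand_offsets).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            inside_counts=np.array(data["inside_counts"]),
            events=[PlantedEvent(**e) for e in data["events"]],
            ligand_offsets=np.array(data["ligand_offsets"]),
        )


def field_to_potential(field_strength: float, membrane_thickness: float = 4.0) -> float:
    """Convert a uniform transmembrane field to a membrane potential.

    Parameters are ``field_strength`` in mV/nm and ``membrane_thickness`` in
    nm; the potential (mV) is their product, e.g. 10 mV/nm across a 4 nm
    membrane is 40 mV.
    """
    if membrane_thickness <= 0:
        raise ValueError(f"membrane thickness must be positive, got {membrane_thickness}")
    return field_strength * membrane_thickness


# rigid ligand template: two phenyl hexagons (ring plane xy, C–C 1.39 Å)
# 5 Å apart along x, bridged by two carbonyl-style oxygens.
def _ligand_template() -> tuple[np.ndarray, list[str]]:
    ang = np.arange(6) * np.pi / 3.0
    hexagon = np.column_stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)])
    ring_a = hexagon + np.array([-2.5, 0.0, 0.0])
    ring_b = hexagon + np.array([2.5, 0.0, 0.0])
    oxy = np.array([[-0.8, 0.0, 1.2], [0.8, 0.0, 1.2]])
    coords = np.vstack([ring_a, ring_b, oxy])
    names = [f"C{i}" for i in range(1, 7)] + [f"C{i}" for i in range(11, 17)] + ["O1", "O2"]
    return coords, names


def _ligand_center_offsets(n_copies: int) -> np.ndarray:
    if n_copies == 0:
        return np.zeros((0, 3))
    if n_copies == 1:
        return np.array([[0.0, 0.0, 0.0]])
    if n_copies == 2:
        return np.array([[0.0, 0.0, 2.0], [0.0, 0.0, -2.0]])
    return np.array(
        [[2.0, 0.0, 3.0], [-2.0, 0.0, 3.0], [2.0, 0.0, -3.0], [-2.0, 0.0, -3.0]]
    )


def _drift_scale(n_ligand_copies: int) -> float:
    # ion mobility shrinks with pore occupancy; four copies block completely
    return max(0.0, 1.0 - n_ligand_copies / 4.0)


def generate_pore_trajectory(
    config: SyntheticPoreConfig,
) -> tuple[Topology, Trajectory, GroundTruth]:
    """Build a synthetic pore system and its planted ground truth.

    The four reference Cα atoms (TYR 318, chains A–D) sit at the corners of a
    square of side ``pore_radius`` centred on the pore axis at z = 0; the
    per-frame pore centre is their (noisy) centroid, and all pore contents are
    generated relative to that centroid so planted counts are exact under the
    dynamically centred analysis cylinder.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    margin = cfg.wall_margin
    clip = _JITTER_CLIP_FRACTION * margin

    # capacity guard: hard-sphere packing at the 2.8 Å water–water exclusion
    place_r = cfg.pore_radius - margin
    place_h = cfg.pore_height - 2 * margin
    if place_r <= 0 or place_h <= 0:
        raise ValueError("pore too small for the wall margin")
    capacity = int(np.pi * place_r**2 * place_h / 2.8**3)
    if cfg.n_waters_inside > capacity:
        raise CapacityError(
            f"{cfg.n_waters_inside} inside-waters exceed cylinder capacity "
            f"{capacity} at 2.8 Å exclusion"
        )
    # exchangeable pool: when occupancy fluctuates, extra waters park outside
    n_pool = cfg.n_waters_inside
    if cfg.water_count_sd > 0:
        n_pool = min(capacity, cfg.n_waters_inside + int(np.ceil(4 * cfg.water_count_sd)))
    inside_counts_per_frame = np.full(cfg.n_frames, cfg.n_waters_inside, dtype=int)
    if cfg.water_count_sd > 0:
        inside_counts_per_frame = np.clip(
            np.rint(rng.normal(cfg.n_waters_inside, cfg.water_count_sd, cfg.n_frames)),
            0, n_pool,
        ).astype(int)

    atoms: list[Atom] = []
    base: list[np.ndarray] = []
    groups: dict[str, list[int]] = {
        "refs": [], "inside": [], "outside": [], "ions": [], "ligand": [], "static": []
    }

    def add(name, element, resname, resnum, chain, pos, group):
        idx = len(atoms)
        atoms.append(
            Atom(
                index=idx, name=name, element=element, residue_name=resname,
                residue_number=resnum, subunit_id=chain,
                vdw_radius=vdw_radius_for(element),
            )
        )
        base.append(np.asarray(pos, dtype=float))
        groups[group].append(idx)

    half = cfg.pore_radius / 2.0
    chains = ["A", "B", "C", "D"]
    corners = np.array([[half, half, 0], [-half, half, 0], [-half, -half, 0], [half, -half, 0]])
    for chain, corner in zip(chains, corners):
        add("CA", "C", "TYR", 318, chain, corner, "refs")

    # pore-facing aromatic rings (PHE 315), one per subunit on the wall
    ring_local = np.column_stack(
        [1.39 * np.cos(np.arange(6) * np.pi / 3.0), np.zeros(6), 1.39 * np.sin(np.arange(6) * np.pi / 3.0)]
    )
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for k, chain in enumerate(chains):
        theta = np.pi / 4 + k * np.pi / 2
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        v = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ring_center = u * cfg.pore_radius + np.array([0.0, 0.0, -2.0])
        ring = ring_center + ring_local[:, 0:1] * v + ring_local[:, 2:3] * np.array([0, 0, 1.0])
        for nm, pos in zip(ring_names, ring):
            add(nm, "C", "PHE", 315, chain, pos, "static")

    # protein shell: Cα beads outside the cylinder so they never occlude it
    shell_r = cfg.pore_radius + 5.0
    for iz, z in enumerate(np.linspace(-cfg.pore_height / 2, cfg.pore_height / 2, 4)):
        for ja, ang in enumerate(np.linspace(0, 2 * np.pi, 12, endpoint=False)):
            chain = chains[ja % 4]
            add("CA", "C", "ALA", 400 + iz, chain,
                [shell_r * np.cos(ang), shell_r * np.sin(ang), z], "static")

    # static membrane annulus (dummy atoms marking the lipid region)
    mem_r = cfg.pore_radius + 10.0
    for iz, z in enumerate((-cfg.membrane_half_span, cfg.membrane_half_span)):
        for ja, ang in enumerate(np.linspace(0, 2 * np.pi, 8, endpoint=False)):
            add("C1", "C", "MEM", 900 + iz, "M",
                [mem_r * np.cos(ang), mem_r * np.sin(ang), z], "static")

    # ligand copies
    lig_template, lig_names = _ligand_template()
    lig_offsets = _ligand_center_offsets(cfg.n_ligand_copies)
    for ci, offset in enumerate(lig_offsets):
        for nm, pos in zip(lig_names, lig_template + offset):
            add(nm, "O" if nm.startswith("O") else "C", "LIG", ci + 1, "L", pos, "ligand")

    # filter ions: stacked on the axis above the membrane top
    ion_z0 = np.array(
        [cfg.membrane_half_span + 1.0 + 3.0 * i for i in range(cfg.n_filter_ions)]
    )
    for i, z0 in enumerate(ion_z0):
        add("K", "K", "POT", i + 1, "I", [0.0, 0.0, z0], "ions")

    # pool waters: a base position strictly inside the margin-shrunk cylinder
    # plus a parking position strictly outside (used when occupancy fluctuates)
    r = place_r * np.sqrt(rng.uniform(size=n_pool))
    th = rng.uniform(0, 2 * np.pi, size=n_pool)
    z = rng.uniform(-place_h / 2, place_h / 2, size=n_pool)
    for i in range(n_pool):
        add("O", "O", "HOH", i + 1, "W", [r[i] * np.cos(th[i]), r[i] * np.sin(th[i]), z[i]], "inside")
    rp = rng.uniform(cfg.pore_radius + margin + 1.0, cfg.pore_radius + margin + 6.0, size=n_pool)
    thp = rng.uniform(0, 2 * np.pi, size=n_pool)
    zp = rng.uniform(-cfg.pore_height / 2, cfg.pore_height / 2, size=n_pool)
    park_base = np.column_stack([rp * np.cos(thp), rp * np.sin(thp), zp])

    # outside-waters: strictly outside by >= margin + clip headroom
    for i in range(cfg.n_waters_outside):
        if rng.uniform() < 0.5:  # radially outside
            ro = rng.uniform(cfg.pore_radius + margin + 1.0, cfg.pore_radius + margin + 6.0)
            tho = rng.uniform(0, 2 * np.pi)
            zo = rng.uniform(-cfg.pore_height / 2, cfg.pore_height / 2)
        else:  # axially outside
            ro = rng.uniform(0, cfg.pore_radius)
            tho = rng.uniform(0, 2 * np.pi)
            zo = rng.choice([-1.0, 1.0]) * rng.uniform(
                cfg.pore_height / 2 + margin + 1.0, cfg.pore_height / 2 + margin + 6.0
            )
        add("O", "O", "HOH", n_pool + i + 1, "W",
            [ro * np.cos(tho), ro * np.sin(tho), zo], "outside")

    base_arr = np.stack(base)
    n_atoms = len(atoms)
    topology = Topology(atoms=atoms)

    refs = np.array(groups["refs"])
    pore_content = np.array(groups["inside"] + groups["outside"] + groups["ligand"], dtype=int)
    ions = np.array(groups["ions"], dtype=int)

    # ion axial path (relative to the pore centre): deterministic drift when
    # the field is on, clipped noise keeps the path strictly monotone
    drift = cfg.ion_drift_per_frame * _drift_scale(cfg.n_ligand_copies) if cfg.field_strength > 0 else 0.0
    frames_idx = np.arange(cfg.n_frames)
    ion_z = np.empty((cfg.n_filter_ions, cfg.n_frames))
    z_noise_clip = min(0.4 * drift, clip) if drift > 0 else clip
    for i in range(cfg.n_filter_ions):
        noise = np.clip(rng.normal(0, cfg.positional_noise_sd, cfg.n_frames), -z_noise_clip, z_noise_clip)
        ion_z[i] = ion_z0[i] - drift * frames_idx + noise
    ion_xy = np.clip(
        rng.normal(0, cfg.positional_noise_sd, (cfg.n_filter_ions, cfg.n_frames, 2)), -clip, clip
    )

    coords = np.empty((cfg.n_frames, n_atoms, 3))
    for f in range(cfg.n_frames):
        frame = base_arr.copy()
        frame[refs] += rng.normal(0, cfg.positional_noise_sd, (4, 3))
        centroid = frame[refs].mean(axis=0)
        jitter = np.clip(
            rng.normal(0, cfg.positional_noise_sd, (pore_content.size, 3)), -clip, clip
        )
        frame[pore_content] = centroid + base_arr[pore_content] + jitter
        # park the pool waters beyond this frame's occupancy outside the cylinder
        n_f = inside_counts_per_frame[f]
        pool = np.array(groups["inside"], dtype=int)
        if n_f < pool.size:
            parked = pool[n_f:]
            park_jitter = np.clip(
                rng.normal(0, cfg.positional_noise_sd, (parked.size, 3)), -clip, clip
            )
            frame[parked] = centroid + park_base[n_f:] + park_jitter
        for i, ion in enumerate(ions):
            frame[ion] = centroid + np.array([ion_xy[i, f, 0], ion_xy[i, f, 1], ion_z[i, f]])
        static = np.array(groups["static"], dtype=int)
        frame[static] += np.clip(
            rng.normal(0, cfg.positional_noise_sd, (static.size, 3)), -clip, clip
        )
        coords[f] = frame

    span = 2 * (cfg.pore_radius + 15.0)
    box = np.tile([span, span, 2 * (cfg.membrane_half_span + 20.0)], (cfg.n_frames, 1))
    times = frames_idx * cfg.frame_dt
    if cfg.n_frames == 1:
        times = np.array([0.0])
    traj = Trajectory(topology=topology, coordinates=coords, box=box, times=times)

    # planted ground truth
    inside_counts = inside_counts_per_frame
    events = _scan_planted_events(
        ion_z, z_top=cfg.membrane_half_span, z_bottom=-cfg.membrane_half_span
    )
    gt = GroundTruth(inside_counts=inside_counts, events=events, ligand_offsets=lig_offsets)
    return topology, traj, gt


def _scan_planted_events(ion_z: np.ndarray, z_top: float, z_bottom: float) -> list[PlantedEvent]:
    """Threshold scan over the generated (monotone) axial paths."""
    events: list[PlantedEvent] = []
    for i in range(ion_z.shape[0]):
        z = ion_z[i]
        above = np.flatnonzero(z >= z_top)
        below = np.flatnonzero(z <= z_bottom)
        if above.size and below.size and below[-1] > above[0]:
            start = int(above[above < below[0]][-1]) if np.any(above < below[0]) else int(above[0])
            events.append(
                PlantedEvent(ion_id=i, start_frame=start, end_frame=int(below[0]), direction="inward")
            )
    return events


def write_system(
    topology: Topology,
    traj: Trajectory,
    gt: GroundTruth,
    out_dir: str | Path,
    *,
    label: str = "system",
    trajectory_format: str = "dcd",
) -> dict[str, Path]:
    """Write topology (PDB), frames (DCD or multi-model PDB) and ground truth (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    top_path = out / f"{label}_topology.pdb"
    write_topology_pdb(traj, top_path)
    if trajectory_format == "dcd":
        traj_path = out / f"{label}_trajectory.dcd"
        write_dcd(traj, traj_path)
    elif trajectory_format == "pdb":
        traj_path = out / f"{label}_trajectory.pdb"
        write_multi_model_pdb(traj, traj_path)
    else:
        raise ValueError(f"unknown trajectory format {trajectory_format!r}")
    gt_path = out / f"{label}_ground_truth.json"
    gt.to_json(gt_path)
    return {"topology": top_path, "trajectory": traj_path, "ground_truth": gt_path}
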