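"""Domain types, structure/trajectory readers and role-based atom selection.

Coordinates are in Å throughout the package, times in ns, and the membrane
normal is the global z axis.  Topologies are read from PDB; coordinates from
DCD, XTC or multi-model PDB.  Waters are represented by their oxygen atom for
all counting purposes (one molecule ↔ one point).  Periodic images are not
unwrapped: analyses assume the pore region does not cross the box boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)


class TopologyFormatError(ValueError):
    """The structure file could not be parsed."""


class AtomCountMismatchError(ValueError):
    """Coordinate file atom count differs from the topology."""


class SelectionError(ValueError):
    """A role-based selection did not resolve as required."""


#: Bondi van der Waals radii (Å).  The default of 1.50 Å is applied to
#: elements outside this table, with a logged warning.
BONDI_VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "H": 1.20,
    "S": 1.80,
    "P": 1.80,
    "K": 2.75,
}
DEFAULT_VDW_RADIUS = 1.50

_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "CA", "ZN", "FE", "BR", "MN", "CU"}


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer the chemical element from a PDB atom name.

    Ion residues are disambiguated first (a potassium ion named ``K`` in
    residue ``POT``/``K`` must not become carbon); otherwise the leading
    alphabetic characters of the name are matched against known two-letter
    elements, falling back to the first letter.
    """
    name = atom_name.strip().upper()
    res = residue_name.strip().upper()
    if res in {"POT", "K", "K+"} or name in {"K", "K+", "POT"}:
        return "K"
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return ""
    if stripped[:2] in _TWO_LETTER_ELEMENTS and res not in {"TIP3", "HOH", "WAT", "SOL"}:
        # CA in an amino acid is an alpha carbon, not calcium: only accept the
        # two-letter reading when the atom is the whole residue (monoatomic ion).
        if stripped == res or stripped[:2] != "CA":
            return stripped[:2].capitalize()
    return stripped[0]


def vdw_radius_for(element: str) -> float:
    el = element.strip().capitalize()
    if el in BONDI_VDW_RADII:
        return BONDI_VDW_RADII[el]
    logger.warning("unknown element %r: using default vdW radius %.2f Å", element, DEFAULT_VDW_RADIUS)
    return DEFAULT_VDW_RADIUS


@dataclass(frozen=True)
class Atom:
    """A single atom with role-relevant identity and a van der Waals radius."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    subunit_id: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0, got {self.vdw_radius}")


@dataclass
class Topology:
    """An ordered list of atoms; indices are 0-based and unique."""

    atoms: list[Atom]
    source_path: str | None = None

    def __post_init__(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be 0..n_atoms-1 in order")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # cached column arrays for vectorised selection
    def _column(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms])

    @property
    def names(self) -> np.ndarray:
        return self._column("name")

    @property
    def residue_names(self) -> np.ndarray:
        return self._column("residue_name")

    @property
    def residue_numbers(self) -> np.ndarray:
        return self._column("residue_number")

    @property
    def subunit_ids(self) -> np.ndarray:
        return self._column("subunit_id")

    @property
    def elements(self) -> np.ndarray:
        return self._column("element")

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """Ordered frames of Å coordinates with per-frame box and time.

    ``coordinates`` has shape (n_frames, n_atoms, 3); ``box`` holds the
    orthorhombic box edge lengths (n_frames, 3); ``times`` is in ns and
    strictly increasing.
    """

    topology: Topology
    coordinates: np.ndarray
    box: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        nf, na, three = self.coordinates.shape
        if three != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if na != self.topology.n_atoms:
            raise AtomCountMismatchError(
                f"coordinates have {na} atoms but topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.box.shape != (nf, 3) or np.any(self.box <= 0):
            raise ValueError("box must be (n_frames, 3) with positive dimensions")
        if self.times.shape != (nf,) or (nf > 1 and np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be strictly increasing, one per frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class LigandCopy:
    """Atom-index groups of one ligand copy: two phenyl rings and two carbonyl oxygens."""

    ring_a: np.ndarray
    ring_b: np.ndarray
    carbonyl_oxygens: np.ndarray


@dataclass
class SelectionSet:
    """Resolved role-based atom index groups shared by all analysis stages."""

    pore_reference_ca: np.ndarray  # exactly 4, one per subunit
    water_oxygens: np.ndarray
    potassium_ions: np.ndarray
    ligand_copies: list[LigandCopy]
    phe_ring_atoms: dict[str, np.ndarray]  # subunit_id -> 6 ring atom indices
    protein_atoms: np.ndarray  # everything that is not water/ion/lipid/ligand


@dataclass
class SelectionConfig:
    """Which residue names/numbers play which role.

    Defaults follow the human Slo1 numbering: the pore-lining reference residue
    is Tyr318 (its four Cα atoms define the per-frame pore centre) and the
    pore-facing aromatic is Phe315.  Both are configurable because channel
    constructs differ in numbering.
    """

    reference_residue_name: str = "TYR"
    reference_residue_number: int = 318
    aromatic_residue_name: str = "PHE"
    aromatic_residue_number: int = 315
    water_residue_names: frozenset[str] = frozenset({"HOH", "TIP3", "WAT", "SOL"})
    ion_names: frozenset[str] = frozenset({"K", "POT", "K+"})
    ligand_residue_names: frozenset[str] = frozenset({"LIG", "DBM"})
    lipid_residue_names: frozenset[str] = frozenset({"POPC", "POPE", "POPS", "MEM"})
    ligand_ring_a_names: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6")
    ligand_ring_b_names: tuple[str, ...] = ("C11", "C12", "C13", "C14", "C15", "C16")
    aromatic_ring_atom_names: tuple[str, ...] = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

    def __post_init__(self) -> None:
        for attr in ("water_residue_names", "ion_names", "ligand_residue_names"):
            value = getattr(self, attr)
            setattr(self, attr, frozenset(value))
            if not getattr(self, attr):
                raise ValueError(f"{attr} must be non-empty")
        self.lipid_residue_names = frozenset(self.lipid_residue_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def load_topology(path: str | Path, config: SelectionConfig | None = None) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    The element is taken from the file when present, otherwise inferred from
    the atom name; every atom receives a Bondi van der Waals radius (default
    1.50 Å for elements outside the table, with a logged warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise reader failures
        raise TopologyFormatError(f"could not parse {path} as PDB: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise TopologyFormatError(f"{path} contains no atoms")

    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        chains = u.atoms.chainIDs
    except Exception:  # noqa: BLE001
        chains = u.atoms.segids
    try:
        file_elements = [str(e) for e in u.atoms.elements]
    except Exception:  # noqa: BLE001
        file_elements = [""] * u.atoms.n_atoms

    atoms = []
    for i in range(u.atoms.n_atoms):
        el = file_elements[i].strip().capitalize()
        if not el:
            el = infer_element(str(names[i]), str(resnames[i]))
        atoms.append(
            Atom(
                index=i,
                name=str(names[i]).strip(),
                element=el,
                residue_name=str(resnames[i]).strip(),
                residue_number=int(resids[i]),
                subunit_id=str(chains[i]).strip(),
                vdw_radius=vdw_radius_for(el),
            )
        )
    return Topology(atoms=atoms, source_path=str(path))


def _coordinate_atom_count(path: Path) -> int:
    mda = _import_mda()
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".dcd":
            from MDAnalysis.coordinates.DCD import DCDReader

            with DCDReader(str(path)) as reader:
                return reader.n_atoms
        if suffix == ".xtc":
            from MDAnalysis.coordinates.XTC import XTCReader

            with XTCReader(str(path)) as reader:
                return reader.n_atoms
        return mda.Universe(str(path)).atoms.n_atoms


def load_trajectory(
    topology: Topology,
    paths: str | Path | Sequence[str | Path],
    *,
    default_dt_ns: float = 0.1,
) -> Trajectory:
    """Read coordinate files (DCD, XTC or multi-model PDB) against a topology.

    Frames are kept in file order.  Times come from the file metadata when it
    carries meaningful values, otherwise they are synthesised at
    ``default_dt_ns`` per frame.  A coordinate/topology atom-count mismatch is
    reported explicitly with both counts.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        n = _coordinate_atom_count(p)
        if n != topology.n_atoms:
            raise AtomCountMismatchError(
                f"{p} has {n} atoms but topology has {topology.n_atoms}"
            )
    if topology.source_path is None:
        raise ValueError("topology has no source file; cannot attach coordinates")
    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(topology.source_path, *[str(p) for p in paths])
        coords, boxes, times_ps = [], [], []
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is None or np.any(np.asarray(dims[:3]) <= 0):
                span = ts.positions.max(axis=0) - ts.positions.min(axis=0)
                boxes.append(span + 20.0)
            else:
                boxes.append(np.asarray(dims[:3], dtype=float))
            times_ps.append(float(getattr(ts, "time", 0.0)))

    times = np.asarray(times_ps) / 1000.0  # ps -> ns
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords)) * default_dt_ns
    elif len(times) == 1:
        times = np.array([0.0])
    return Trajectory(
        topology=topology,
        coordinates=np.stack(coords),
        box=np.stack(boxes),
        times=times,
    )


def write_multi_model_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write every frame as a MODEL record in one PDB file (Å, 3 decimals)."""
    _write_with_mda(traj, Path(path), multiframe=True)


def write_dcd(traj: Trajectory, path: str | Path) -> None:
    """Write coordinates as a CHARMM-style DCD file."""
    _write_with_mda(traj, Path(path), multiframe=True)


def write_topology_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write the first frame only, as a single-model PDB topology file."""
    first = Trajectory(
        topology=traj.topology,
        coordinates=traj.coordinates[:1],
        box=traj.box[:1],
        times=traj.times[:1],
    )
    _write_with_mda(first, Path(path), multiframe=False)


def _write_with_mda(traj: Trajectory, path: Path, *, multiframe: bool) -> None:
    mda = _import_mda()
    top = traj.topology
    n = top.n_atoms
    resid_keys: list[tuple] = []
    atom_res_idx = np.empty(n, dtype=int)
    for i, a in enumerate(top.atoms):
        key = (a.subunit_id, a.residue_number, a.residue_name)
        if not resid_keys or resid_keys[-1] != key:
            resid_keys.append(key)
        atom_res_idx[i] = len(resid_keys) - 1
    n_res = len(resid_keys)
    seg_ids = sorted({k[0] for k in resid_keys})
    seg_index = {s: j for j, s in enumerate(seg_ids)}
    res_seg = np.array([seg_index[k[0]] for k in resid_keys])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n_res, n_segments=len(seg_ids),
            atom_resindex=atom_res_idx, residue_segindex=res_seg,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in top.atoms])
        u.add_TopologyAttr("elements", [a.element for a in top.atoms])
        u.add_TopologyAttr("resnames", [k[2] for k in resid_keys])
        u.add_TopologyAttr("resids", [k[1] for k in resid_keys])
        u.add_TopologyAttr("chainIDs", [a.subunit_id[:1] or "A" for a in top.atoms])
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))

        with mda.Writer(str(path), n_atoms=n, multiframe=multiframe) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f]
                u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
                u.trajectory.ts.frame = f
                u.trajectory.ts.time = traj.times[f] * 1000.0
                w.write(u.atoms)


def build_selections(topology: Topology, config: SelectionConfig | None = None) -> SelectionSet:
    """Resolve role-based atom groups from residue identity.

    Exactly four reference Cα atoms (one per subunit) are required — they
    define the pore centre every frame; anything else is a
    :class:`SelectionError` reporting the per-subunit counts.  Waters are
    reduced to their oxygen atoms; ligand copies are split into two phenyl
    rings and two carbonyl oxygens by atom name.
    """
    config = config or SelectionConfig()
    names = topology.names
    resnames = topology.residue_names
    resnums = topology.residue_numbers
    subunits = topology.subunit_ids
    elements = topology.elements

    ref_mask = (
        (resnames == config.reference_residue_name)
        & (resnums == config.reference_residue_number)
        & (names == "CA")
    )
    ref_idx = np.flatnonzero(ref_mask)
    per_subunit: dict[str, int] = {}
    for i in ref_idx:
        per_subunit[subunits[i]] = per_subunit.get(subunits[i], 0) + 1
    if len(ref_idx) != 4 or len(per_subunit) != 4 or any(v != 1 for v in per_subunit.values()):
        raise SelectionError(
            f"expected 4 reference Cα atoms ({config.reference_residue_name} "
            f"{config.reference_residue_number}), one per subunit; found "
            f"{len(ref_idx)} reference atoms (per subunit: {dict(sorted(per_subunit.items()))})"
        )

    water_mask = np.isin(resnames, list(config.water_residue_names)) & (elements == "O")
    water_oxygens = np.flatnonzero(water_mask)
    if water_oxygens.size == 0:
        logger.warning("no water oxygens found in topology")

    ion_mask = np.isin(names, list(config.ion_names)) | np.isin(resnames, list(config.ion_names))
    ion_mask &= elements == "K"
    potassium = np.flatnonzero(ion_mask)

    lig_mask = np.isin(resnames, list(config.ligand_residue_names))
    ligand_copies: list[LigandCopy] = []
    lig_idx = np.flatnonzero(lig_mask)
    if lig_idx.size:
        seen: dict[tuple, list[int]] = {}
        for i in lig_idx:
            seen.setdefault((subunits[i], resnums[i]), []).append(int(i))
        for key in sorted(seen):
            members = np.array(seen[key])
            mnames = names[members]
            ring_a = members[np.isin(mnames, config.ligand_ring_a_names)]
            ring_b = members[np.isin(mnames, config.ligand_ring_b_names)]
            oxy = members[elements[members] == "O"]
            if oxy.size != 2:
                raise SelectionError(
                    f"ligand copy {key} has {oxy.size} oxygen atoms; expected exactly 2 carbonyl oxygens"
                )
            ligand_copies.append(LigandCopy(ring_a=ring_a, ring_b=ring_b, carbonyl_oxygens=oxy))

    phe_rings: dict[str, np.ndarray] = {}
    phe_mask = (
        (resnames == config.aromatic_residue_name)
        & (resnums == config.aromatic_residue_number)
        & np.isin(names, config.aromatic_ring_atom_names)
    )
    for i in np.flatnonzero(phe_mask):
        phe_rings.setdefault(subunits[i], [])
        phe_rings[subunits[i]].append(int(i))
    phe_rings = {k: np.array(sorted(v)) for k, v in sorted(phe_rings.items())}

    nonprotein = water_mask | ion_mask | lig_mask | np.isin(resnames, list(config.lipid_residue_names))
    protein_atoms = np.flatnonzero(~nonprotein)

    return SelectionSet(
        pore_reference_ca=ref_idx,
        water_oxygens=water_oxygens,
        potassium_ions=potassium,
        ligand_copies=ligand_copies,
        phe_ring_atoms=phe_rings,
        protein_atoms=protein_atoms,
    )
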