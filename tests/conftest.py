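"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from poreblock import (
    Atom,
    CylinderSpec,
    SelectionSet,
    SyntheticPoreConfig,
    Topology,
    Trajectory,
    build_selections,
    generate_pore_trajectory,
)


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    x: float,
    y: float,
    z: float,
    element: str = "",
) -> str:
    return (
        f"ATOM  {serial:>5} {name:<4} {resname:<4}{chain}{resid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


def make_channel_pdb(
    tmp_path,
    *,
    chains=("A", "B", "C", "D"),
    n_waters: int = 0,
    water_resname: str = "HOH",
    filename: str = "channel.pdb",
):
    """A minimal 4-subunit channel PDB: TYR 318 CA per chain + optional waters."""
    lines = ["CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1"]
    serial = 1
    corners = [(5, 5), (-5, 5), (-5, -5), (5, -5)]
    for chain, (x, y) in zip(chains, corners):
        lines.append(pdb_atom_line(serial, "CA", "TYR", chain, 318, x, y, 0.0, "C"))
        serial += 1
    rng = np.random.default_rng(42)
    for i in range(n_waters):
        x, y, z = rng.uniform(-3, 3, 3)
        lines.append(pdb_atom_line(serial, "OH2", water_resname, "W", i + 1, x, y, z, "O"))
        serial += 1
        lines.append(pdb_atom_line(serial, "H1", water_resname, "W", i + 1, x + 0.8, y, z, "H"))
        serial += 1
    lines.append("END")
    path = tmp_path / filename
    path.write_text("\n".join(lines) + "\n")
    return path


def bare_topology(positions: np.ndarray, *, element: str = "C", resname: str = "ALA") -> Topology:
    """A topology of identical dummy atoms at the given positions."""
    atoms = [
        Atom(
            index=i, name="CA", element=element, residue_name=resname,
            residue_number=i + 1, subunit_id="A", vdw_radius=1.70,
        )
        for i in range(len(positions))
    ]
    return Topology(atoms=atoms)


def single_frame_trajectory(positions: np.ndarray, topology: Topology | None = None) -> Trajectory:
    positions = np.asarray(positions, dtype=float)
    top = topology or bare_topology(positions)
    return Trajectory(
        topology=top,
        coordinates=positions[None, :, :],
        box=np.array([[100.0, 100.0, 100.0]]),
        times=np.array([0.0]),
    )


def reference_square(half: float = 5.0) -> np.ndarray:
    """Four reference positions at (±half, ±half, 0)."""
    return np.array([[half, half, 0.0], [-half, half, 0.0], [-half, -half, 0.0], [half, -half, 0.0]])


def selection_for(
    n_atoms: int,
    *,
    refs=(0, 1, 2, 3),
    waters=(),
    ions=(),
    protein=(),
) -> SelectionSet:
    return SelectionSet(
        pore_reference_ca=np.array(refs),
        water_oxygens=np.array(waters, dtype=int),
        potassium_ions=np.array(ions, dtype=int),
        ligand_copies=[],
        phe_ring_atoms={},
        protein_atoms=np.array(protein, dtype=int),
    )


@pytest.fixture(scope="session")
def synthetic_system():
    """A 100-frame synthetic pore with 30 planted inside-waters (seed 7)."""
    cfg = SyntheticPoreConfig(n_frames=100, n_waters_inside=30, seed=7)
    topology, traj, gt = generate_pore_trajectory(cfg)
    return topology, traj, gt, build_selections(topology)


@pytest.fixture(scope="session")
def drifting_system():
    """A field-on system whose four filter ions drift through the pore."""
    cfg = SyntheticPoreConfig(n_frames=150, field_strength=10.0, seed=3)
    topology, traj, gt = generate_pore_trajectory(cfg)
    return topology, traj, gt, build_selections(topology)
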