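"""Cylinder hydration counting, grid cavity volume, water density."""

import numpy as np
import pytest

from poreblock import (
    Atom,
    CylinderSpec,
    FrameSeries,
    GridSpec,
    Topology,
    cavity_volume,
    count_pore_waters,
    cylinder_center,
    water_density,
)

from conftest import bare_topology, reference_square, selection_for, single_frame_trajectory


def brute_force_count(points, center, radius, height):
    """Independent oracle: per-point in-cylinder test."""
    n = 0
    for p in points:
        dx, dy, dz = p - center
        if np.hypot(dx, dy) <= radius and abs(dz) <= height / 2:
            n += 1
    return n


def brute_force_volume(center, radius, height, spacing, atom_positions, cutoffs):
    """Independent oracle: exhaustive enumeration of the cell-centred lattice
    with all-pairs occlusion checks."""
    nr = int(np.ceil(radius / spacing))
    nz = int(np.ceil((height / 2) / spacing))
    count = 0
    for i in range(-nr, nr):
        for j in range(-nr, nr):
            for k in range(-nz, nz):
                p = center + spacing * (np.array([i, j, k]) + 0.5)
                d = p - center
                if np.hypot(d[0], d[1]) > radius or abs(d[2]) > height / 2:
                    continue
                occluded = any(
                    np.linalg.norm(p - a) <= c for a, c in zip(atom_positions, cutoffs)
                )
                if not occluded:
                    count += 1
    return count * spacing**3


class TestCylinderCenter:
    @pytest.mark.parametrize(
        "refs,expected",
        [
            (reference_square(5.0), (0.0, 0.0, 0.0)),
            (np.tile([[1.0, 2.0, 3.0]], (4, 1)), (1.0, 2.0, 3.0)),
            (np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 4.0]]), (1.0, 1.0, 1.0)),
        ],
    )
    def test_centroid_arithmetic(self, refs, expected):
        traj = single_frame_trajectory(np.asarray(refs, dtype=float))
        assert np.allclose(cylinder_center(traj.coordinates[0], np.arange(4)), expected)


class TestCountPoreWaters:
    def test_counts_only_waters_within_radius(self):
        refs = reference_square()
        center_waters = np.zeros((5, 3))
        far_waters = np.array([[15.0, 0, 0], [0, 15.0, 0], [-15.0, 0, 0]])
        pos = np.vstack([refs, center_waters, far_waters])
        traj = single_frame_trajectory(pos)
        sel = selection_for(len(pos), waters=range(4, 12))
        series = count_pore_waters(traj, sel, CylinderSpec())
        assert series.values[0] == 5

    def test_boundary_water_is_counted(self):
        pos = np.vstack([reference_square(), [[10.0, 0.0, 0.0]], [[0.0, 0.0, 6.0]]])
        traj = single_frame_trajectory(pos)
        sel = selection_for(len(pos), waters=(4, 5))
        series = count_pore_waters(traj, sel, CylinderSpec(radius=10.0, height=12.0))
        assert series.values[0] == 2  # both exactly on the boundary

    def test_matches_brute_force_on_uniform_scatter(self):
        rng = np.random.default_rng(11)
        waters = rng.uniform(-14, 14, size=(200, 3))
        pos = np.vstack([reference_square(), waters])
        traj = single_frame_trajectory(pos)
        sel = selection_for(len(pos), waters=range(4, 204))
        cyl = CylinderSpec()
        series = count_pore_waters(traj, sel, cyl)
        center = cylinder_center(traj.coordinates[0], np.arange(4))
        assert series.values[0] == brute_force_count(waters, center, cyl.radius, cyl.height)

    def test_empty_water_selection_returns_zeros(self):
        traj = single_frame_trajectory(reference_square())
        sel = selection_for(4)
        series = count_pore_waters(traj, sel, CylinderSpec())
        assert np.all(series.values == 0)

    def test_adaptive_radius_uses_mean_reference_distance(self):
        refs = reference_square(5.0)  # corners at xy-distance sqrt(50) ~ 7.07
        water_in = [[7.0, 0, 0]]
        water_out = [[8.0, 0, 0]]  # inside fixed 10 A radius, outside adaptive
        pos = np.vstack([refs, water_in, water_out])
        traj = single_frame_trajectory(pos)
        sel = selection_for(len(pos), waters=(4, 5))
        fixed = count_pore_waters(traj, sel, CylinderSpec(radius_mode="fixed"))
        adaptive = count_pore_waters(traj, sel, CylinderSpec(radius_mode="adaptive"))
        assert fixed.values[0] == 2
        assert adaptive.values[0] == 1

    def test_translation_invariance(self, synthetic_system):
        _, traj, _, sel = synthetic_system
        cyl = CylinderSpec()
        base = count_pore_waters(traj, sel, cyl).values
        shifted = traj.coordinates + np.array([13.0, -7.0, 4.0])
        traj2 = type(traj)(topology=traj.topology, coordinates=shifted, box=traj.box, times=traj.times)
        moved = count_pore_waters(traj2, sel, cyl).values
        assert np.array_equal(base, moved)


class TestCavityVolume:
    def test_empty_cylinder_matches_lattice_oracle(self):
        traj = single_frame_trajectory(reference_square())
        sel = selection_for(4)  # no protein atoms occlude
        cyl, grid = CylinderSpec(), GridSpec(spacing=2.0)
        series = cavity_volume(traj, sel, cyl, grid)
        center = cylinder_center(traj.coordinates[0], np.arange(4))
        expected = brute_force_volume(center, cyl.radius, cyl.height, grid.spacing, [], [])
        assert series.values[0] == expected

    def test_occluded_volume_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        protein = rng.uniform(-8, 8, size=(20, 3))
        pos = np.vstack([reference_square(), protein])
        traj = single_frame_trajectory(pos)
        sel = selection_for(len(pos), protein=range(4, 24))
        cyl, grid = CylinderSpec(), GridSpec()
        series = cavity_volume(traj, sel, cyl, grid)
        center = cylinder_center(traj.coordinates[0], np.arange(4))
        cutoffs = [1.70 + grid.probe_buffer] * 20
        expected = brute_force_volume(center, cyl.radius, cyl.height, grid.spacing, protein, cutoffs)
        assert series.values[0] == expected

    def test_giant_atom_fully_occludes(self):
        pos = np.vstack([reference_square(), [[0.0, 0.0, 0.0]]])
        atoms = bare_topology(pos).atoms
        giant = Atom(index=4, name="XX", element="C", residue_name="ALA",
                     residue_number=5, subunit_id="A", vdw_radius=50.0)
        top = Topology(atoms=atoms[:4] + [giant])
        traj = single_frame_trajectory(pos, topology=top)
        sel = selection_for(5, protein=(4,))
        series = cavity_volume(traj, sel, CylinderSpec(), GridSpec())
        assert series.values[0] == 0.0

    def test_adding_an_atom_never_increases_volume(self):
        rng = np.random.default_rng(9)
        protein = rng.uniform(-9, 9, size=(10, 3))
        pos = np.vstack([reference_square(), protein])
        traj = single_frame_trajectory(pos)
        cyl, grid = CylinderSpec(), GridSpec()
        for k in range(1, 11):
            fewer = cavity_volume(traj, selection_for(len(pos), protein=range(4, 3 + k)), cyl, grid)
            more = cavity_volume(traj, selection_for(len(pos), protein=range(4, 4 + k)), cyl, grid)
            assert more.values[0] <= fewer.values[0]

    def test_analytic_limit_at_fine_spacing(self):
        """With no occluders the grid volume converges to pi r^2 h: within 2%
        of 3769.9 A^3 for r=10, h=12 at 0.5 A spacing."""
        traj = single_frame_trajectory(reference_square())
        sel = selection_for(4)
        analytic = np.pi * 10.0**2 * 12.0
        v = cavity_volume(traj, sel, CylinderSpec(), GridSpec(spacing=0.5)).values[0]
        assert abs(v - analytic) / analytic < 0.02

    def test_degenerate_spacing_rejected(self):
        traj = single_frame_trajectory(reference_square())
        with pytest.raises(ValueError, match="degenerate"):
            cavity_volume(traj, selection_for(4), CylinderSpec(), GridSpec(spacing=30.0))

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        protein = rng.uniform(-8, 8, size=(15, 3))
        pos = np.vstack([reference_square(), protein])
        sel = selection_for(len(pos), protein=range(4, 19))
        cyl, grid = CylinderSpec(), GridSpec()
        v0 = cavity_volume(single_frame_trajectory(pos), sel, cyl, grid).values[0]
        v1 = cavity_volume(single_frame_trajectory(pos + [3.0, -11.0, 6.0]), sel, cyl, grid).values[0]
        assert v0 == v1

    def test_volume_is_multiple_of_cell_volume(self, synthetic_system):
        _, traj, _, sel = synthetic_system
        grid = GridSpec(spacing=2.0)
        sub = type(traj)(topology=traj.topology, coordinates=traj.coordinates[:5],
                         box=traj.box[:5], times=traj.times[:5])
        series = cavity_volume(sub, sel, CylinderSpec(), grid)
        assert np.allclose(series.values % grid.spacing**3, 0.0)


class TestWaterDensity:
    def test_simple_ratio(self):
        t = np.arange(3.0)
        c = FrameSeries("c", [20.0, 0.0, 10.0], t)
        v = FrameSeries("v", [1000.0, 500.0, 0.0], t)
        d = water_density(c, v)
        assert d.values[0] == pytest.approx(0.02)
        assert d.values[1] == 0.0
        assert np.isnan(d.values[2])  # zero volume: undefined, not zero

    def test_length_mismatch_rejected(self):
        c = FrameSeries("c", [1.0, 2.0], np.arange(2.0))
        v = FrameSeries("v", [1.0], np.arange(1.0))
        with pytest.raises(ValueError):
            water_density(c, v)


class TestFrameSeriesCsv:
    def test_round_trip(self, tmp_path):
        s = FrameSeries("m", np.array([1.5, 2.5, 3.5]), np.array([0.0, 0.1, 0.2]))
        path = tmp_path / "series.csv"
        s.to_csv(path)
        back = FrameSeries.from_csv(path, "m")
        assert np.allclose(back.values, s.values)
        assert np.allclose(back.frame_times, s.frame_times)
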