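import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ifsim import conformation as cf
from ifsim import dynamics as dyn
from ifsim import geometry as geo


class TestEndToEnd:
    def test_straight_dimer(self, dimer):
        assert cf.end_to_end_length(dimer) == pytest.approx(50.0)

    def test_hairpin_geometry(self, dimer):
        pos = dimer.positions.copy()
        # fold into two antiparallel arms 2 nm apart; path ends meet
        n = dimer.n_beads
        half = n // 2
        pos[:] = 0.0
        pos[:half, 0] = np.arange(half)
        pos[half:, 0] = np.arange(n - half)[::-1]
        pos[half:, 1] = 2.0
        assert cf.end_to_end_length(dimer, pos) == pytest.approx(2.0, abs=1e-9)

    def test_straight_tetramer(self, tetramer):
        assert cf.end_to_end_length(tetramer) == pytest.approx(75.0, abs=1.0)

    def test_too_few_beads(self, dimer):
        with pytest.raises(ValueError):
            cf.end_to_end_length(dimer, dimer.positions[:1])

    def test_bounded_by_contour(self, free_coil_trajs):
        tr = free_coil_trajs[0]
        limit = tr.model.contour_length_per_dimer + 2 * tr.model.radii[0]
        for pos in tr.positions:
            assert cf.end_to_end_length(tr.model, pos) <= limit


class TestKabsch:
    def test_identical_sets_zero(self):
        a = np.random.default_rng(0).normal(size=(20, 3))
        assert cf.kabsch_rmsd(a, a) < 1e-12

    def test_rigid_motion_zero(self):
        a = np.random.default_rng(1).normal(size=(20, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        assert cf.kabsch_rmsd(a, a @ rot.T + np.array([1, -2, 3])) < 1e-9

    def test_mismatched_counts_raise(self):
        with pytest.raises(ValueError):
            cf.kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_against_rotation_grid_oracle(self):
        """Brute-force minimisation over a dense rotation grid agrees with
        the closed-form Kabsch solution for a 3-bead displacement."""
        a = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        b = a.copy()
        b[2] += np.array([0.4, -0.2, 0.3])
        mats = Rotation.random(200_000, random_state=11).as_matrix()
        aa = a - a.mean(0)
        bb = b - b.mean(0)
        rotated = np.einsum("nij,kj->nki", mats, bb)
        msd = np.mean(np.sum((rotated - aa) ** 2, axis=2), axis=1)
        best = float(np.sqrt(msd.min()))
        ours = cf.kabsch_rmsd(a, b)
        assert ours <= best + 1e-9
        assert best - ours < 0.01

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        a, b, c = rng.normal(size=(3, 12, 3))
        rab, rba = cf.kabsch_rmsd(a, b), cf.kabsch_rmsd(b, a)
        assert rab == pytest.approx(rba, abs=1e-9)
        assert cf.kabsch_rmsd(a, c) <= rab + cf.kabsch_rmsd(b, c) + 1e-9


class TestProjectionArea:
    def test_single_bead_disk(self):
        area = cf.projection_area(np.zeros((1, 3)), radii=[1.0], grid_resolution=0.05)
        assert area == pytest.approx(math.pi, rel=0.01)

    def test_straight_rod_stadium(self, dimer):
        # 50-nm rod of 1-nm beads: ~ 50 x 2 rectangle + end caps
        area = cf.projection_area(dimer.positions, dimer.radii, 0.1)
        assert area == pytest.approx(50 * 2 + math.pi, rel=0.05)

    def test_rigid_rotation_invariance(self, tetramer):
        rng = np.random.default_rng(4)
        pos = tetramer.positions + 0.5 * rng.standard_normal(
            tetramer.positions.shape
        )
        a0 = cf.projection_area(pos, tetramer.radii, 0.2)
        rot = Rotation.random(random_state=5).as_matrix()
        a1 = cf.projection_area(pos @ rot.T + 7.0, tetramer.radii, 0.2)
        assert a1 == pytest.approx(a0, rel=0.02)

    def test_grid_resolution_guard(self, dimer):
        with pytest.raises(ValueError):
            cf.projection_area(dimer.positions, dimer.radii, 2.0)


class TestSASA:
    def test_single_bead_sphere(self):
        s = cf.cg_sasa(np.zeros((1, 3)), radii=[1.0])
        assert s == pytest.approx(4 * math.pi, rel=0.01)

    def test_two_distant_beads_add(self):
        pos = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        s = cf.cg_sasa(pos, radii=[1.0, 1.0])
        assert s == pytest.approx(8 * math.pi, rel=0.01)

    def test_coincident_beads_count_once(self):
        pos = np.zeros((2, 3))
        s = cf.cg_sasa(pos, radii=[1.0, 1.0])
        assert s == pytest.approx(4 * math.pi, rel=0.01)

    def test_probe_radius_inflates(self, dimer):
        s0 = cf.cg_sasa(dimer.positions, dimer.radii, probe_radius=0.0,
                        n_sphere_points=240)
        s1 = cf.cg_sasa(dimer.positions, dimer.radii, probe_radius=0.5,
                        n_sphere_points=240)
        assert s1 > s0

    def test_rigid_motion_invariance(self, dimer):
        rot = Rotation.random(random_state=6).as_matrix()
        s0 = cf.cg_sasa(dimer.positions, dimer.radii)
        s1 = cf.cg_sasa(dimer.positions @ rot.T - 3.0, dimer.radii)
        assert s1 == pytest.approx(s0, rel=0.02)


class TestWLCAngle:
    def test_coiled_coil_segment_is_about_70_degrees(self):
        # arccos(1/e) for a segment as long as its persistence length
        assert cf.wlc_mean_tangent_angle(25.0, 25.0) == pytest.approx(68.42, abs=0.01)

    def test_limits(self):
        assert cf.wlc_mean_tangent_angle(0.0, 25.0) == 0.0
        assert cf.wlc_mean_tangent_angle(1e6, 25.0) == pytest.approx(90.0, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(1.01, 2.0)
    )
    def test_monotonicity(self, L, Lp, factor):
        from hypothesis import assume

        assume(L * factor / Lp < 20.0)  # below floating-point saturation
        base = cf.wlc_mean_tangent_angle(L, Lp)
        assert cf.wlc_mean_tangent_angle(L * factor, Lp) > base
        assert cf.wlc_mean_tangent_angle(L, Lp * factor) < base


def _synthetic_traj(frames, model):
    cfg = dyn.SimulationConfig(n_steps=1, record_every=1)
    return dyn.Trajectory(
        np.arange(len(frames), dtype=float), np.asarray(frames), [], cfg, model
    )


class TestPersistenceEstimate:
    def test_rigid_chain_returns_infinite_flag(self):
        chain = geo.build_chain(20.0, 1.0)
        tr = _synthetic_traj([chain.positions] * 60, chain)
        assert cf.estimate_persistence_length(tr) == math.inf

    def test_freely_jointed_chain_is_nearly_uncorrelated(self):
        chain = geo.build_chain(25.0, 1.0)
        rng = np.random.default_rng(9)
        frames = []
        for _ in range(200):
            steps = rng.standard_normal((25, 3))
            steps /= np.linalg.norm(steps, axis=1)[:, None]
            frames.append(np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]))
        tr = _synthetic_traj(frames, chain)
        assert cf.estimate_persistence_length(tr) < 1.5

    def test_recovers_programmed_persistence_length(self, free_coil_trajs):
        pooled = _synthetic_traj(
            np.concatenate([t.positions for t in free_coil_trajs]),
            free_coil_trajs[0].model,
        )
        lp = cf.estimate_persistence_length(pooled)
        assert lp == pytest.approx(25.0, rel=0.10)

    def test_too_few_frames_raise(self, dimer):
        tr = _synthetic_traj([dimer.positions] * 10, dimer)
        with pytest.raises(ValueError):
            cf.estimate_persistence_length(tr)

    def test_hinges_are_not_crossed(self, dimer):
        # a dimer folded sharply at the linker still reports stiff coils
        pos = dimer.positions.copy()
        rot = Rotation.from_euler("z", 150, degrees=True).as_matrix()
        pos[24:] = (pos[24:] - pos[23]) @ rot.T + pos[23]
        tr = _synthetic_traj([pos] * 60, dimer)
        assert cf.estimate_persistence_length(tr) == math.inf


class TestDiskDiameter:
    @pytest.mark.parametrize(
        "area,expected",
        [(math.pi, 2.0), (587.0, 27.3), (246.0, 17.7)],
    )
    def test_equivalent_disk_diameter(self, area, expected):
        assert cf.equivalent_disk_diameter(area) == pytest.approx(expected, abs=0.05)

    def test_negative_area_raises(self):
        with pytest.raises(ValueError):
            cf.equivalent_disk_diameter(-1.0)
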