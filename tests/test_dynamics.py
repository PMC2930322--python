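import numpy as np
import pytest

from ifsim import dynamics as dyn
from ifsim import energetics as en
from ifsim import geometry as geo
from ifsim.conformation import radius_of_gyration
from ifsim.units import KT_300K


class TestIntegrator:
    def test_fixed_seed_is_bitwise_reproducible(self, dimer, ff):
        cfg = dyn.SimulationConfig(
            timestep=2e-3, n_steps=5000, seed=7, record_every=500,
            record_energies=False,
        )
        a = dyn.run_simulation(dimer, None, ff, cfg)
        b = dyn.run_simulation(dimer, None, ff, cfg)
        assert np.array_equal(a.positions, b.positions)

    def test_first_frame_is_initial_model(self, dimer, ff):
        cfg = dyn.SimulationConfig(
            timestep=2e-3, n_steps=2000, seed=1, record_every=1000,
            record_energies=False,
        )
        tr = dyn.run_simulation(dimer, None, ff, cfg)
        assert np.array_equal(tr.positions[0], dimer.positions)
        assert tr.n_frames == 3  # initial + n_steps / record_every

    def test_zero_temperature_descends_energy(self, ff):
        """T -> 0 overdamped dynamics is gradient descent: total energy
        never increases between recorded frames."""
        chain = geo.build_chain(20.0, 1.0)
        rng = np.random.default_rng(0)
        bent = chain.copy()
        bent.positions = bent.positions + 0.3 * rng.standard_normal((21, 3))
        cfg = dyn.SimulationConfig(
            timestep=1e-3, temperature=0.0, n_steps=20_000, seed=1,
            record_every=1000,
        )
        tr = dyn.run_simulation(bent, None, ff, cfg)
        totals = [bd.total for bd in tr.energies]
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))
        assert totals[-1] < totals[0]

    def test_straight_chain_stays_straight_at_zero_temperature(self, dimer, ff):
        cfg = dyn.SimulationConfig(
            timestep=1e-3, temperature=0.0, n_steps=5000, seed=1,
            record_every=5000, record_energies=False,
        )
        tr = dyn.run_simulation(dimer, None, ff, cfg)
        assert np.allclose(tr.positions[-1], dimer.positions, atol=1e-9)

    def test_timestep_overflow_reports_step(self, dimer, ff):
        bad = dimer.copy()
        bad.positions[10] = bad.positions[11] + 1e-4  # huge bond strain
        cfg = dyn.SimulationConfig(
            timestep=0.5, n_steps=1000, seed=1, record_every=100,
            record_energies=False,
        )
        with pytest.raises(dyn.TimestepOverflowError) as err:
            dyn.run_simulation(bad, None, ff, cfg)
        assert err.value.step >= 0

    def test_kernel_forces_match_reference(self, tetramer, ff, calibrated_small_lattice):
        """One T=0 step of the fast kernel equals mobility x the numpy
        reference forces, with every term active (bonds, angles,
        crosslinks, non-bonded, adhesion, wall, pull)."""
        lat = geo.lattice_for_model(tetramer, margin=10.0)
        lat = en.replace_lattice_lj(lat, calibrated_small_lattice.lj)
        model = tetramer.copy().placed_above_plane(0.6)
        rng = np.random.default_rng(1)
        model.positions = model.positions + 0.05 * rng.standard_normal(
            model.positions.shape
        )
        model.positions[0, 2] = 5.5  # engage the pull term
        cfg = dyn.SimulationConfig(
            timestep=1e-6, temperature=0.0, n_steps=1, seed=1, record_every=1,
            environment="substrate", record_energies=False,
            max_step_displacement=1e9,  # diagnostic step, no guard
        )
        tr = dyn.run_simulation(model, lat, ff, cfg)
        step = tr.positions[-1] - model.positions
        pull = en.PullSpec(
            cfg.pull_force_per_bead(model.residues_per_bead), cfg.pull_z_threshold
        )
        _, f = en.energy_and_forces(model, lat, ff, pull)
        assert np.allclose(step, f * cfg.timestep, rtol=1e-6, atol=1e-12)


class TestDepositionPull:
    def test_force_only_above_threshold(self, dimer):
        cfg = dyn.SimulationConfig()
        pos = np.array([[0, 0, 6.0], [0, 0, 4.0], [0, 0, 5.0]])
        f = dyn.apply_deposition_pull(pos, cfg, dimer.residues_per_bead)
        expected = 0.0012 * dimer.residues_per_bead * 10.0
        assert f[0, 2] == pytest.approx(-expected)
        assert np.all(f[1:] == 0.0)

    def test_no_pull_energy_when_all_low(self, dimer, ff):
        pull = en.PullSpec(0.2, 5.0)
        bd = en.total_energy(dimer, None, ff, pull=pull)
        assert bd.external_pull == 0.0


class TestEnvironmentModes:
    def test_solution_mode_is_identity(self, dimer, ff):
        m2, ff2 = dyn.apply_environment_mode(dimer, ff, "solution")
        assert m2 is dimer and ff2 is ff

    def test_unknown_mode_raises(self, dimer, ff):
        with pytest.raises(ValueError):
            dyn.apply_environment_mode(dimer, ff, "substrate+molybdate")

    def test_glutaraldehyde_on_straight_chain_adds_nothing(self, dimer, ff):
        m2, _ = dyn.apply_environment_mode(
            dimer, ff, "solution+glutaraldehyde"
        )
        assert len(m2.topology.crosslinks) == len(dimer.topology.crosslinks)

    def test_glutaraldehyde_fixes_a_hairpin(self, dimer, ff):
        folded = dimer.copy()
        # fold the chain back on itself at the linker
        pos = folded.positions.copy()
        pos[26:, 0] = 2 * pos[25, 0] - pos[26:, 0]
        pos[26:, 1] = 1.2
        folded.positions = pos
        m2, _ = dyn.apply_environment_mode(folded, ff, "solution+glutaraldehyde")
        assert len(m2.topology.crosslinks) > 0

    def test_calcium_mode_sets_attraction(self, dimer, ff):
        _, ff2 = dyn.apply_environment_mode(
            dimer, ff, "substrate+calcium", ca_eps=0.9
        )
        assert ff2.ca_eps == 0.9
        assert ff.ca_eps == 0.0  # original untouched

    def test_calcium_compacts_relative_to_salt_only(self, ff):
        """Paired-seed comparison: with a strong calcium-bridging
        attraction the equilibrium radius of gyration is smaller than in
        the plain (NaCl screened, repulsive-only) solution."""
        chain = geo.build_chain(25.0, 1.0, charge=-1.0)
        ff_base = en.ForceFieldParams(
            bend_k_coil=en.bending_constant_from_persistence_length(10.0, 1.0)
        )
        rg = {"solution": [], "solution+calcium": []}
        for seed in (1, 2, 3):
            for env in rg:
                cfg = dyn.SimulationConfig(
                    timestep=2e-3, n_steps=120_000, seed=seed,
                    record_every=4000, environment=env, record_energies=False,
                )
                _, ffe = dyn.apply_environment_mode(chain, ff_base, env, ca_eps=1.5)
                tr = dyn.run_simulation(chain, None, ffe, cfg)
                rg[env].append(
                    np.mean([radius_of_gyration(p) for p in tr.positions[-8:]])
                )
        assert np.mean(rg["solution+calcium"]) < np.mean(rg["solution"])


class TestConvergence:
    @staticmethod
    def _traj_from_frames(frames, model):
        cfg = dyn.SimulationConfig(n_steps=1, record_every=1)
        return dyn.Trajectory(
            np.arange(len(frames), dtype=float), np.asarray(frames), [], cfg, model
        )

    def test_static_trajectory_converges_with_zero_rmsd(self, dimer):
        tr = self._traj_from_frames([dimer.positions] * 20, dimer)
        converged, series = dyn.check_convergence(tr)
        assert converged
        assert np.allclose(series, 0.0)

    def test_drifting_chain_not_converged(self, dimer):
        rng = np.random.default_rng(0)
        frames = []
        pos = dimer.positions.copy()
        for k in range(30):
            pos = pos + rng.standard_normal(pos.shape) * 0.5
            frames.append(pos.copy())
        tr = self._traj_from_frames(frames, dimer)
        converged, _ = dyn.check_convergence(tr, window=20)
        assert not converged

    def test_window_longer_than_trajectory_raises(self, dimer):
        tr = self._traj_from_frames([dimer.positions] * 5, dimer)
        with pytest.raises(ValueError):
            dyn.check_convergence(tr, window=10)


class TestEquipartition:
    def test_bending_energy_per_coil_joint(self, free_coil_trajs):
        """Each bending joint has two transverse degrees of freedom, so
        its mean bending energy at equilibrium is ~kB T (within 15%)."""
        ffp = en.ForceFieldParams(
            bend_k_coil=en.bending_constant_from_persistence_length(25.0, 1.0)
        )
        vals = []
        for tr in free_coil_trajs:
            for pos in tr.positions[::5]:
                bd = en.total_energy(tr.model, None, ffp, positions=pos)
                vals.append(bd.bending / len(tr.model.topology.angles))
        assert np.mean(vals) == pytest.approx(KT_300K, rel=0.15)
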