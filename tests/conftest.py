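import numpy as np
import pytest

from ifsim import energetics as en
from ifsim import geometry as geo
from ifsim import dynamics as dyn
from ifsim import pipeline as pl


@pytest.fixture
def dimer():
    return geo.build_dimer()


@pytest.fixture
def tetramer():
    return geo.build_tetramer()


@pytest.fixture
def ff():
    return en.ForceFieldParams()


@pytest.fixture(scope="session")
def small_lattice():
    return geo.build_substrate(0.98, 30.0, 30.0)


@pytest.fixture(scope="session")
def calibrated_small_lattice(small_lattice):
    return en.calibrated_lattice(small_lattice, geo.DEFAULT_RESIDUES_PER_BEAD)


@pytest.fixture(scope="session")
def free_coil_trajs():
    """Three equilibrated runs of a free 25-nm coil with bend_k mapped
    from a 25-nm persistence length; first 30 frames discarded."""
    ffp = en.ForceFieldParams(
        bend_k_coil=en.bending_constant_from_persistence_length(25.0, 1.0, 300.0)
    )
    coil = geo.build_chain(25.0, 1.0)
    out = []
    for seed in (1, 2, 3):
        cfg = dyn.SimulationConfig(
            timestep=2e-3, n_steps=400_000, seed=seed, record_every=4000,
            record_energies=False,
        )
        tr = dyn.run_simulation(coil, None, ffp, cfg)
        out.append(
            dyn.Trajectory(tr.times[30:], tr.positions[30:], [], tr.config, tr.model)
        )
    return out


DEPOSITION_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def deposition_trajs():
    """Deposition runs (extended start at z = 3 nm over the calibrated
    lattice) for both subunits, five seeds each."""
    return {
        kind: [
            pl.deposit_subunit(kind, seed, n_steps=300_000)
            for seed in DEPOSITION_SEEDS
        ]
        for kind in ("dimer", "tetramer")
    }


@pytest.fixture(scope="session")
def solution_trajs():
    """Matched-seed solution equilibrations for both subunits."""
    return {
        kind: [
            pl.solution_subunit(kind, seed, n_steps=600_000)
            for seed in DEPOSITION_SEEDS
        ]
        for kind in ("dimer", "tetramer")
    }


def trailing_lee(traj, frac=0.25):
    from ifsim.conformation import end_to_end_length

    k = max(int(traj.n_frames * frac), 1)
    return float(
        np.mean([end_to_end_length(traj.model, p) for p in traj.positions[-k:]])
    )
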