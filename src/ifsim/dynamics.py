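"""Overdamped Langevin sampling of subunit conformations.

The chain beads follow the position-Langevin (Brownian dynamics) update

    x(t+dt) = x(t) + F/gamma * dt + sqrt(2 kB T dt / gamma) * N(0,1)

with deterministic forces from the CG force field (plus substrate adhesion
and the deposition pull) and thermal noise satisfying
fluctuation-dissipation at the target temperature.  Substrate beads are
immobile.  Time is in reduced units of gamma * nm^2 / (kcal/mol); with the
default gamma = 1 a free bead diffuses its own 1-nm radius in ~0.8 time
units.  Identical seeds give bitwise-identical trajectories.

Deposition protocol: the subunit starts extended with its lowest bead 3 nm
above the lattice (beyond the non-bonded cutoff, so initially
non-interacting) and a constant downward force acts on every bead more
than 5 nm above the substrate, scaled per bead as
0.0012 kcal/mol/Angstrom per residue x residues_per_bead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import kt
from .geometry import (
    SubunitModel,
    SubstrateLattice,
    ChainTopology,
    JOINT_HINGE,
    LINKER,
)
from .energetics import (
    ForceFieldParams,
    PullSpec,
    EnergyBreakdown,
    energy_and_forces,
    nonbonded_pairs,
)
from .units import COULOMB_KCAL_NM

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "run_simulation",
    "apply_deposition_pull",
    "apply_environment_mode",
    "check_convergence",
    "ENVIRONMENTS",
]

ENVIRONMENTS = (
    "solution",
    "substrate",
    "substrate+calcium",
    "substrate+glutaraldehyde",
    "solution+calcium",
    "solution+glutaraldehyde",
)


@dataclass
class SimulationConfig:
    """Parameters of one Langevin run.

    ``timestep`` is in reduced time units; 2e-4 is stable against the
    calibrated adhesion well (the stiffest interaction), while
    substrate-free runs are stable up to ~2e-3.  The pull force is stated
    per residue (kcal/mol/Angstrom) and scaled by residues_per_bead.
    """

    timestep: float = 2e-4
    friction: float = 1.0
    temperature: float = 300.0
    n_steps: int = 100_000
    seed: int = 0
    record_every: int = 1000
    pull_force_per_residue: float = 0.0012  # kcal/mol/A per residue
    pull_z_threshold: float = 5.0  # nm
    environment: str = "solution"
    record_energies: bool = True
    max_step_displacement: float = 0.5  # nm, instability guard

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")

    def pull_force_per_bead(self, residues_per_bead: float) -> float:
        """Per-bead pull force in kcal/mol/nm (10 A per nm)."""
        return self.pull_force_per_residue * residues_per_bead * 10.0


@dataclass
class Trajectory:
    """Recorded frames of one run: times, positions, energy breakdowns."""

    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, N, 3)
    energies: list  # list[EnergyBreakdown] or []
    config: SimulationConfig
    model: SubunitModel

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def final_model(self) -> SubunitModel:
        out = self.model.copy()
        out.positions = self.positions[-1].copy()
        return out


class TimestepOverflowError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(
            f"force overflow at step {step}: displacement exceeded the "
            "stability guard; reduce the timestep"
        )
        self.step = step


@njit(cache=True)
def _run_block(  # noqa: C901 - single hot loop by design
    pos,
    n_steps,
    dt,
    kT,
    gamma,
    noise,
    bond_i,
    bond_j,
    bond_rest,
    bond_k,
    ang_i,
    ang_j,
    ang_k,
    ang_stiff,
    pair_i,
    pair_j,
    pair_A,
    pair_ca,
    ex_eps,
    ex_sigma,
    debye,
    cutoff,
    ca_eps,
    ca_range,
    has_lattice,
    lat_x0,
    lat_y0,
    lat_a,
    lat_h,
    lat_ncols,
    lat_nrows,
    lat_eps,
    lat_sigma,
    wall_k,
    wall_z,
    f_pull,
    z_thr,
    max_disp,
):
    n = pos.shape[0]
    mob = dt / gamma
    amp = math.sqrt(2.0 * kT * dt / gamma)
    forces = np.zeros((n, 3))
    x6c = (lat_sigma / cutoff) ** 6
    e_shift = lat_eps * (x6c * x6c - 2.0 * x6c)
    for step in range(n_steps):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        # bonds and crosslinks
        for b in range(bond_i.shape[0]):
            i = bond_i[b]
            j = bond_j[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-12:
                r = 1e-12
            fmag = -bond_k[b] * (r - bond_rest[b]) / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
        # bending: E = k (1 + cos theta)
        for a in range(ang_i.shape[0]):
            ks = ang_stiff[a]
            if ks == 0.0:
                continue
            i = ang_i[a]
            j = ang_j[a]
            k2 = ang_k[a]
            ux = pos[i, 0] - pos[j, 0]
            uy = pos[i, 1] - pos[j, 1]
            uz = pos[i, 2] - pos[j, 2]
            vx = pos[k2, 0] - pos[j, 0]
            vy = pos[k2, 1] - pos[j, 1]
            vz = pos[k2, 2] - pos[j, 2]
            nu = math.sqrt(ux * ux + uy * uy + uz * uz)
            nv = math.sqrt(vx * vx + vy * vy + vz * vz)
            inv = 1.0 / (nu * nv)
            c = (ux * vx + uy * vy + uz * vz) * inv
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            gux = vx * inv - ux * c / (nu * nu)
            guy = vy * inv - uy * c / (nu * nu)
            guz = vz * inv - uz * c / (nu * nu)
            gvx = ux * inv - vx * c / (nv * nv)
            gvy = uy * inv - vy * c / (nv * nv)
            gvz = uz * inv - vz * c / (nv * nv)
            forces[i, 0] -= ks * gux
            forces[i, 1] -= ks * guy
            forces[i, 2] -= ks * guz
            forces[k2, 0] -= ks * gvx
            forces[k2, 1] -= ks * gvy
            forces[k2, 2] -= ks * gvz
            forces[j, 0] += ks * (gux + gvx)
            forces[j, 1] += ks * (guy + gvy)
            forces[j, 2] += ks * (guz + gvz)
        # non-bonded chain pairs
        for p in range(pair_i.shape[0]):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff * cutoff:
                continue
            r = math.sqrt(r2)
            if r < 1e-12:
                r = 1e-12
            dEdr = 0.0
            if r < ex_sigma:
                x6 = (ex_sigma / r) ** 6
                dEdr += ex_eps * 12.0 * (-x6 * x6 + x6) / r
            A = pair_A[p]
            if A != 0.0:
                ex = math.exp(-r / debye)
                dEdr += -A * ex * (1.0 / (r * debye) + 1.0 / r2)
            if ca_eps > 0.0 and pair_ca[p]:
                u = (r - ex_sigma) / ca_range
                dEdr += ca_eps * math.exp(-u * u) * 2.0 * u / ca_range
            fmag = -dEdr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
        # substrate adhesion, wall, pull
        if has_lattice:
            for i in range(n):
                z = pos[i, 2]
                if z < cutoff:
                    x = pos[i, 0]
                    y = pos[i, 1]
                    j_lo = int(math.floor((y - lat_y0 - cutoff) / lat_h))
                    j_hi = int(math.ceil((y - lat_y0 + cutoff) / lat_h))
                    if j_lo < 0:
                        j_lo = 0
                    if j_hi > lat_nrows - 1:
                        j_hi = lat_nrows - 1
                    for jj in range(j_lo, j_hi + 1):
                        yj = lat_y0 + jj * lat_h
                        offs = 0.5 * lat_a if (jj % 2) == 1 else 0.0
                        i_lo = int(math.floor((x - lat_x0 - offs - cutoff) / lat_a))
                        i_hi = int(math.ceil((x - lat_x0 - offs + cutoff) / lat_a))
                        if i_lo < 0:
                            i_lo = 0
                        if i_hi > lat_ncols - 1:
                            i_hi = lat_ncols - 1
                        for ii in range(i_lo, i_hi + 1):
                            xi = lat_x0 + ii * lat_a + offs
                            dx = x - xi
                            dy = y - yj
                            r2 = dx * dx + dy * dy + z * z
                            if r2 >= cutoff * cutoff:
                                continue
                            r = math.sqrt(r2)
                            if r < 1e-12:
                                r = 1e-12
                            x6 = (lat_sigma / r) ** 6
                            dEdr = lat_eps * 12.0 * (-x6 * x6 + x6) / r
                            fmag = -dEdr / r
                            forces[i, 0] += fmag * dx
                            forces[i, 1] += fmag * dy
                            forces[i, 2] += fmag * z
                if z < wall_z:
                    forces[i, 2] += wall_k * (wall_z - z)
                if f_pull > 0.0 and z > z_thr:
                    forces[i, 2] -= f_pull
        # integrate
        bad = False
        for i in range(n):
            ddx = forces[i, 0] * mob + amp * noise[step, i, 0]
            ddy = forces[i, 1] * mob + amp * noise[step, i, 1]
            ddz = forces[i, 2] * mob + amp * noise[step, i, 2]
            if (
                abs(ddx) > max_disp
                or abs(ddy) > max_disp
                or abs(ddz) > max_disp
                or ddx != ddx
                or ddy != ddy
                or ddz != ddz
            ):
                bad = True
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
        if bad:
            return step
    return -1


def _prepare_arrays(model: SubunitModel, ff: ForceFieldParams):
    t = model.topology
    bond_i = np.concatenate([t.bonds[:, 0], t.crosslinks[:, 0]]).astype(np.int64)
    bond_j = np.concatenate([t.bonds[:, 1], t.crosslinks[:, 1]]).astype(np.int64)
    bond_rest = np.concatenate([t.bond_rest, t.crosslink_rest]).astype(float)
    bond_k = np.concatenate(
        [
            np.full(len(t.bonds), ff.bond_k),
            np.full(len(t.crosslinks), ff.crosslink_k),
        ]
    )
    ang = t.angles.astype(np.int64)
    ang_stiff = np.where(
        t.angle_class == JOINT_HINGE, ff.bend_k_hinge, ff.bend_k_coil
    ).astype(float)
    pi, pj = nonbonded_pairs(model)
    pair_A = (
        COULOMB_KCAL_NM
        / ff.dielectric
        * model.charges[pi]
        * model.charges[pj]
    )
    pair_ca = (
        (model.segment_labels[pi] != LINKER) & (model.segment_labels[pj] != LINKER)
    ).astype(np.bool_)
    return (
        bond_i,
        bond_j,
        bond_rest,
        bond_k,
        ang[:, 0].copy(),
        ang[:, 1].copy(),
        ang[:, 2].copy(),
        ang_stiff,
        pi.astype(np.int64),
        pj.astype(np.int64),
        pair_A.astype(float),
        pair_ca,
    )


def apply_deposition_pull(
    positions: np.ndarray,
    config: SimulationConfig,
    residues_per_bead: float,
) -> np.ndarray:
    """Per-bead external force of the deposition protocol.

    (0, 0, -f) on beads higher than the 5-nm threshold, zero otherwise.
    """
    f = config.pull_force_per_bead(residues_per_bead)
    out = np.zeros_like(positions)
    out[positions[:, 2] > config.pull_z_threshold, 2] = -f
    return out


def apply_environment_mode(
    model: SubunitModel,
    ff: ForceFieldParams,
    mode: str,
    ca_eps: float = 0.8,
    capture_radius: float = 1.5,
    crosslink_rest: float | None = None,
) -> tuple:
    """Return (model, ff) adjusted for the chemical environment.

    ``calcium`` switches on a short-range attraction (depth ``ca_eps``,
    range ff.ca_range) between coil beads, emulating divalent-ion
    bridging.  ``glutaraldehyde`` converts every non-bonded bead pair
    currently closer than ``capture_radius`` into a permanent harmonic
    crosslink, once, at invocation (chemical fixation of the instantaneous
    conformation).  Plain solution/substrate modes return the inputs
    unchanged.
    """
    if mode not in ENVIRONMENTS:
        raise ValueError(f"unknown environment {mode!r}")
    base = mode.split("+")
    if len(base) == 1:
        return model, ff
    chem = base[1]
    if chem == "calcium":
        return model, replace(ff, ca_eps=ca_eps)
    # glutaraldehyde
    pi, pj = nonbonded_pairs(model)
    d = np.linalg.norm(model.positions[pi] - model.positions[pj], axis=1)
    hit = d < capture_radius
    if not np.any(hit):
        return model, ff
    new = model.copy()
    rest = d[hit] if crosslink_rest is None else np.full(hit.sum(), crosslink_rest)
    t = new.topology
    t.crosslinks = np.vstack([t.crosslinks, np.column_stack([pi[hit], pj[hit]])])
    t.crosslink_rest = np.concatenate([t.crosslink_rest, rest])
    return new, ff


def run_simulation(
    model: SubunitModel,
    lattice: SubstrateLattice | None,
    ff: ForceFieldParams,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate the model and record frames every ``record_every`` steps.

    The first frame is the initial configuration.  Lattice beads are
    immobile; the deposition pull is active only in substrate
    environments.  Raises TimestepOverflowError if any per-step
    displacement exceeds the stability guard.
    """
    substrate_env = config.environment.startswith("substrate")
    if substrate_env and lattice is None:
        raise ValueError("substrate environment requires a lattice")
    if not substrate_env:
        lattice = None

    model, ff = apply_environment_mode(model, ff, config.environment)
    arrays = _prepare_arrays(model, ff)
    pos = model.positions.astype(float).copy()
    n = pos.shape[0]

    if lattice is not None:
        lat_args = (
            True,
            float(lattice.origin[0]),
            float(lattice.origin[1]),
            float(lattice.spacing),
            float(lattice.spacing * np.sqrt(3.0) / 2.0),
            int(lattice.n_cols),
            int(lattice.n_rows),
            float(lattice.lj.well_depth),
            float(lattice.lj.r_min),
        )
        f_pull = config.pull_force_per_bead(model.residues_per_bead)
    else:
        lat_args = (False, 0.0, 0.0, 1.0, 1.0, 0, 0, 0.0, 1.0)
        f_pull = 0.0

    rng = np.random.default_rng(config.seed)
    kT = kt(config.temperature)

    n_rec = config.n_steps // config.record_every
    times = np.empty(n_rec + 1)
    frames = np.empty((n_rec + 1, n, 3))
    times[0] = 0.0
    frames[0] = pos
    energies = []
    pull = (
        PullSpec(f_pull, config.pull_z_threshold) if f_pull > 0 else None
    )
    if config.record_energies:
        bd, _ = energy_and_forces(model, lattice, ff, pull, positions=pos)
        energies.append(bd)

    done = 0
    frame = 1
    while done < config.n_steps:
        block = min(config.record_every, config.n_steps - done)
        if config.temperature > 0:
            noise = rng.standard_normal((block, n, 3))
        else:
            noise = np.zeros((block, n, 3))
        status = _run_block(
            pos,
            block,
            config.timestep,
            kT,
            config.friction,
            noise,
            *arrays,
            ff.excluded_eps,
            ff.excluded_sigma,
            ff.debye_length,
            ff.cutoff,
            ff.ca_eps,
            ff.ca_range,
            *lat_args,
            ff.wall_k,
            ff.wall_z,
            f_pull,
            config.pull_z_threshold,
            config.max_step_displacement,
        )
        if status >= 0:
            raise TimestepOverflowError(done + status)
        done += block
        if block == config.record_every:
            times[frame] = done * config.timestep
            frames[frame] = pos
            if config.record_energies:
                bd, _ = energy_and_forces(
                    model, lattice, ff, pull, positions=pos
                )
                energies.append(bd)
            frame += 1

    return Trajectory(
        times=times[:frame],
        positions=frames[:frame],
        energies=energies,
        config=config,
        model=model,
    )


def check_convergence(
    traj: Trajectory,
    reference_frame: int = -1,
    window: int | None = None,
    slope_tol: float = 0.5,
    fluct_tol: float = 1.0,
) -> tuple:
    """Convergence test on the RMSD-to-reference series.

    Computes the Kabsch RMSD of every frame to the reference frame and
    examines the trailing ``window`` frames (default: last quarter):
    converged iff the total linear drift across the window and the
    standard deviation are both below their tolerances (nm).

    Returns (converged, rmsd_series).
    """
    from .conformation import kabsch_rmsd

    nf = traj.n_frames
    if window is None:
        window = max(nf // 4, 2)
    if window > nf:
        raise ValueError("window longer than the trajectory")
    ref = traj.positions[reference_frame]
    series = np.array([kabsch_rmsd(p, ref) for p in traj.positions])
    tail = series[-window:]
    x = np.arange(window, dtype=float)
    slope = np.polyfit(x, tail, 1)[0] if window > 1 else 0.0
    drift = abs(slope) * window
    fluct = float(np.std(tail))
    return bool(drift < slope_tol and fluct < fluct_tol), series
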