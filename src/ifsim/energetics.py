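"""Energy model: CG chain force field plus Lennard-Jones substrate adhesion.

The total energy decomposes into chain terms (bonds, bending, excluded
volume, screened electrostatics, crosslinks), the bead-lattice adhesion
term, and the external deposition pull.  The adhesion model follows the
coarse-grained-substrate construction: every chain bead interacts with
every lattice bead within a cutoff through a Lennard-Jones pair potential

    E(r) = eps * [ (sigma/r)^12 - 2 (sigma/r)^6 ]

written so that ``sigma`` is the distance of zero force (the location of
the minimum) and ``eps`` the well depth.  The per-bead well depth is
calibrated so that the minimum over height of the lattice-summed energy of
a single probe bead equals a target adhesion energy; the target is taken
as residues_per_bead x 1.48 kcal/mol, the per-amino-acid adhesion well of
a silica surface (itself bracketed by the 50-60 mJ/m^2 adhesion energy
density times a 0.28 nm^2 residue footprint, i.e. 2.01-2.42 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .units import AVOGADRO, COULOMB_KCAL_NM, JOULES_PER_KCAL, KB_KCAL_PER_MOL_K
from .geometry import SubunitModel, SubstrateLattice, JOINT_HINGE, LINKER

__all__ = [
    "LJParams",
    "ForceFieldParams",
    "EnergyBreakdown",
    "PullSpec",
    "lj_pair_energy",
    "substrate_adhesion_energy",
    "gamma_to_per_residue_energy",
    "calibrate_bead_well_depth",
    "calibrated_lattice",
    "bending_constant_from_persistence_length",
    "total_energy",
    "energy_and_forces",
    "nonbonded_pairs",
    "PER_RESIDUE_WELL_KCAL",
]

#: Adhesion energy well of one amino acid on the silica surface, kcal/mol.
#: Treated as a universal per-residue constant of the substrate model.
PER_RESIDUE_WELL_KCAL = 1.48


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones pair parameters: positive well depth and the distance
    of zero force (potential minimum)."""

    well_depth: float  # kcal/mol, > 0
    r_min: float  # nm, > 0

    def __post_init__(self):
        if self.well_depth <= 0:
            raise ValueError("well_depth must be positive")
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")


@dataclass
class ForceFieldParams:
    """CG chain force-field parameters (implicit solvent).

    bond_k : harmonic bond stiffness, kcal/mol/nm^2.
    bend_k_coil / bend_k_hinge : bending stiffness of COIL and HINGE
        joints, kcal/mol (potential k(1 + cos theta), harmonic in the
        deviation from straight for small angles); the coil value maps to a
        25-nm persistence length via Lp*kB*T/b.
    excluded_eps / excluded_sigma : purely repulsive (WCA-truncated)
        excluded volume between non-bonded chain beads, contact at the
        bead diameter.
    dielectric / debye_length : screened Yukawa electrostatics between
        charged beads (NaCl assembly conditions, ~0.8 nm screening).
    ca_eps / ca_range : calcium-bridging attraction between coil beads
        (zero in the default solution/substrate environments).
    cutoff : non-bonded cutoff, < the 3-nm initial drop height so the
        deposition start is non-interacting.
    wall_k / wall_z : one-sided harmonic keeping beads out of the bulk
        substrate below the top lattice layer (active only with a lattice).
    """

    bond_k: float = 100.0
    bend_k_coil: float = 14.904
    bend_k_hinge: float = 0.0
    excluded_eps: float = 0.3
    excluded_sigma: float = 2.0
    dielectric: float = 80.0
    debye_length: float = 0.8
    cutoff: float = 2.5
    crosslink_k: float = 10.0
    ca_eps: float = 0.0
    ca_range: float = 1.5
    wall_k: float = 200.0
    wall_z: float = 0.25

    def __post_init__(self):
        for name in ("bond_k", "bend_k_coil", "bend_k_hinge", "crosslink_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PullSpec:
    """Constant downward deposition force on beads above a height threshold."""

    force_per_bead: float  # kcal/mol/nm, >= 0
    z_threshold: float = 5.0  # nm


@dataclass
class EnergyBreakdown:
    bonded: float = 0.0
    bending: float = 0.0
    excluded: float = 0.0
    electrostatic: float = 0.0
    adhesion: float = 0.0
    external_pull: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.bonded
            + self.bending
            + self.excluded
            + self.electrostatic
            + self.adhesion
            + self.external_pull
        )

    def as_dict(self) -> dict:
        return {
            "bonded": self.bonded,
            "bending": self.bending,
            "excluded": self.excluded,
            "electrostatic": self.electrostatic,
            "adhesion": self.adhesion,
            "external_pull": self.external_pull,
            "total": self.total,
        }


def lj_pair_energy(r, lj: LJParams):
    """LJ pair energy eps[(sigma/r)^12 - 2(sigma/r)^6]; minimum -eps at r_min.

    Accepts scalars or arrays; r must be positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    x6 = (lj.r_min / r) ** 6
    out = lj.well_depth * (x6 * x6 - 2.0 * x6)
    return float(out) if out.ndim == 0 else out


def gamma_to_per_residue_energy(gamma: float, area: float) -> float:
    """Convert an adhesion energy density (mJ/m^2) times a per-residue
    contact area (nm^2) into kcal/mol.

    gamma_to_per_residue_energy(50, 0.28) = 2.01 and (60, 0.28) = 2.42,
    bracketing the per-residue silica adhesion well.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if area <= 0:
        raise ValueError("area must be positive")
    joules = gamma * 1e-3 * area * 1e-18  # J per residue
    return joules * AVOGADRO / JOULES_PER_KCAL


def bending_constant_from_persistence_length(
    Lp: float, bond_length: float, temperature: float = 300.0
) -> float:
    """Bending constant k = Lp * kB * T / b mapping a worm-like-chain
    persistence length onto the discrete-joint stiffness."""
    if Lp < 0:
        raise ValueError("persistence length must be non-negative")
    if bond_length <= 0:
        raise ValueError("bond length must be positive")
    return Lp * KB_KCAL_PER_MOL_K * temperature / bond_length


def substrate_adhesion_energy(
    model_or_positions, lattice: SubstrateLattice, cutoff: float = 2.5
) -> float:
    """Sum of LJ pair energies over (chain bead, lattice bead) pairs within
    the cutoff.  Additive over chain beads; zero when every pair is beyond
    the cutoff.  Raises if the model leaves the lattice xy extent."""
    if hasattr(model_or_positions, "positions"):
        positions = model_or_positions.positions
    else:
        positions = np.atleast_2d(np.asarray(model_or_positions, dtype=float))
    lj = lattice.lj
    if lj is None:
        raise ValueError("lattice has no LJ parameters assigned")
    x0, y0 = lattice.origin
    w, d = lattice.extent
    xy = positions[:, :2]
    if (
        xy[:, 0].min() < x0 - 1e-9
        or xy[:, 0].max() > x0 + w + 1e-9
        or xy[:, 1].min() < y0 - 1e-9
        or xy[:, 1].max() > y0 + d + 1e-9
    ):
        raise ValueError("model lies outside the lattice extent")
    tree = cKDTree(lattice.positions)
    total = 0.0
    for p in positions:
        idx = tree.query_ball_point(p, cutoff)
        if idx:
            r = np.linalg.norm(lattice.positions[idx] - p, axis=1)
            total += float(np.sum(lj_pair_energy(r, lj)))
    return total


def _lattice_center_site(lattice: SubstrateLattice) -> np.ndarray:
    """xy of the lattice bead nearest the lattice centroid."""
    centroid = lattice.positions[:, :2].mean(axis=0)
    i = int(np.argmin(np.sum((lattice.positions[:, :2] - centroid) ** 2, axis=1)))
    return lattice.positions[i, :2].copy()


def single_bead_well(
    lattice: SubstrateLattice,
    cutoff: float = 2.5,
    xy=None,
    z_bounds=(0.05, 2.5),
) -> tuple:
    """Depth and location of the lattice-summed LJ well for one probe bead.

    Returns (well_depth, z_min) where well_depth > 0 is the magnitude of
    the energy minimum over height z at a fixed lateral position.  When
    ``xy`` is not given the deepest of the three high-symmetry sites
    (on-top, bridge, hollow) around the lattice centre is used -- the site
    an adsorbed bead actually occupies.
    """
    if xy is None:
        a = lattice.spacing
        centre = _lattice_center_site(lattice)
        candidates = [
            centre,
            centre + np.array([a / 2.0, 0.0]),
            centre + np.array([a / 2.0, a / (2.0 * np.sqrt(3.0))]),
        ]
    else:
        candidates = [np.asarray(xy, dtype=float)]

    best = (0.0, float(z_bounds[1]))
    for site in candidates:
        def e_of_z(z, site=site):
            p = np.array([[site[0], site[1], z]])
            return substrate_adhesion_energy(p, lattice, cutoff=cutoff)

        zs = np.linspace(z_bounds[0], z_bounds[1], 200)
        es = np.array([e_of_z(z) for z in zs])
        k = int(np.argmin(es))
        lo = zs[max(k - 1, 0)]
        hi = zs[min(k + 1, len(zs) - 1)]
        res = minimize_scalar(e_of_z, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if -float(res.fun) > best[0]:
            best = (-float(res.fun), float(res.x))
    return best


def calibrate_bead_well_depth(
    target_well: float,
    pair_r_min: float,
    lattice: SubstrateLattice,
    cutoff: float = 2.5,
) -> float:
    """Per-pair LJ well depth reproducing a target single-bead adhesion well.

    Scans the height of a probe bead above the lattice with unit pair
    depth, measures the summed well, and scales: the LJ sum is linear in
    eps, so eps = target / well(eps=1) exactly, and doubling the target
    doubles eps.
    """
    if target_well <= 0:
        raise ValueError("target_well must be positive")
    probe = replace_lattice_lj(lattice, LJParams(1.0, pair_r_min))
    well_unit, _ = single_bead_well(probe, cutoff=cutoff)
    return target_well / well_unit


def replace_lattice_lj(lattice: SubstrateLattice, lj: LJParams) -> SubstrateLattice:
    out = SubstrateLattice(
        positions=lattice.positions,
        spacing=lattice.spacing,
        lj=lj,
        extent=lattice.extent,
        origin=lattice.origin,
        n_cols=lattice.n_cols,
        n_rows=lattice.n_rows,
    )
    return out


def calibrated_lattice(
    lattice: SubstrateLattice,
    residues_per_bead: float,
    pair_r_min: float = 1.0,
    per_residue_well: float = PER_RESIDUE_WELL_KCAL,
    cutoff: float = 2.5,
) -> SubstrateLattice:
    """Assign calibrated LJ parameters: the single-bead well equals
    residues_per_bead x the per-residue adhesion well."""
    target = residues_per_bead * per_residue_well
    eps = calibrate_bead_well_depth(target, pair_r_min, lattice, cutoff=cutoff)
    return replace_lattice_lj(lattice, LJParams(eps, pair_r_min))


def nonbonded_pairs(model: SubunitModel):
    """Index arrays (i, j) of chain-bead pairs subject to non-bonded terms.

    Excludes directly bonded pairs, angle partners (1-3) and crosslinked
    pairs, whose geometry is governed by the bonded terms.
    """
    n = model.n_beads
    excl = np.zeros((n, n), dtype=bool)
    t = model.topology
    for b in t.bonds:
        excl[b[0], b[1]] = excl[b[1], b[0]] = True
    for a in t.angles:
        excl[a[0], a[2]] = excl[a[2], a[0]] = True
    for c in t.crosslinks:
        excl[c[0], c[1]] = excl[c[1], c[0]] = True
    iu, ju = np.triu_indices(n, k=1)
    keep = ~excl[iu, ju]
    return iu[keep], ju[keep]


def _pair_energy_forces(positions, i, j, ff, charges, coil_pair, shift=True):
    """Non-bonded chain-chain energies and forces (excluded volume,
    electrostatics, calcium attraction), truncated at the cutoff."""
    d = positions[i] - positions[j]
    r = np.linalg.norm(d, axis=1)
    r = np.maximum(r, 1e-12)
    within = r < ff.cutoff
    e_ex = np.zeros_like(r)
    e_el = np.zeros_like(r)
    dEdr = np.zeros_like(r)

    # WCA-style repulsion: LJ (min at sigma) + eps, zero beyond sigma.
    rep = within & (r < ff.excluded_sigma)
    if np.any(rep):
        x6 = (ff.excluded_sigma / r[rep]) ** 6
        e_ex[rep] = ff.excluded_eps * (x6 * x6 - 2.0 * x6) + ff.excluded_eps
        dEdr[rep] += ff.excluded_eps * 12.0 * (-x6 * x6 + x6) / r[rep]

    # Screened Coulomb.
    qq = charges[i] * charges[j]
    el = within & (qq != 0)
    if np.any(el):
        A = COULOMB_KCAL_NM / ff.dielectric * qq[el]
        ex = np.exp(-r[el] / ff.debye_length)
        e_el[el] = A * ex / r[el]
        if shift:
            e_el[el] -= (
                A * np.exp(-ff.cutoff / ff.debye_length) / ff.cutoff
            )
        dEdr[el] += -A * ex * (1.0 / (r[el] * ff.debye_length) + 1.0 / r[el] ** 2)

    # Calcium-bridging attraction between coil beads.
    if ff.ca_eps > 0:
        ca = within & coil_pair
        if np.any(ca):
            u = (r[ca] - ff.excluded_sigma) / ff.ca_range
            g = np.exp(-u * u)
            e_el[ca] += -ff.ca_eps * g
            dEdr[ca] += ff.ca_eps * g * 2.0 * u / ff.ca_range

    f = np.zeros_like(positions)
    fij = (-dEdr / r)[:, None] * d
    np.add.at(f, i, fij)
    np.add.at(f, j, -fij)
    return float(e_ex.sum()), float(e_el.sum()), f


def _angle_energy_forces(positions, angles, ks):
    """Bending energy k(1 + cos theta) per joint (zero when straight)."""
    if len(angles) == 0:
        return 0.0, np.zeros_like(positions)
    i, j, k = angles[:, 0], angles[:, 1], angles[:, 2]
    u = positions[i] - positions[j]
    v = positions[k] - positions[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.sum(u * v, axis=1) / (nu * nv)
    c = np.clip(c, -1.0, 1.0)
    e = float(np.sum(ks * (1.0 + c)))
    # dE/dcos = ks ; grad of cos w.r.t. positions
    inv = 1.0 / (nu * nv)
    gu = (v * inv[:, None]) - u * (c / nu**2)[:, None]
    gv = (u * inv[:, None]) - v * (c / nv**2)[:, None]
    f = np.zeros_like(positions)
    np.add.at(f, i, -ks[:, None] * gu)
    np.add.at(f, k, -ks[:, None] * gv)
    np.add.at(f, j, ks[:, None] * (gu + gv))
    return e, f


def energy_and_forces(
    model: SubunitModel,
    lattice: SubstrateLattice | None,
    ff: ForceFieldParams,
    pull: PullSpec | None = None,
    positions: np.ndarray | None = None,
) -> tuple:
    """Reference (pure numpy) energy breakdown and forces.

    Used for recorded-frame energetics, for testing the fast integrator
    kernel against an independent implementation, and for small systems.
    """
    pos = model.positions if positions is None else positions
    if pos.shape[0] != model.n_beads:
        raise ValueError("position array does not match the model bead count")
    t = model.topology
    f = np.zeros_like(pos)
    bd = EnergyBreakdown()

    # Bonds + crosslinks.
    for pairs, rests, k in (
        (t.bonds, t.bond_rest, ff.bond_k),
        (t.crosslinks, t.crosslink_rest, ff.crosslink_k),
    ):
        if len(pairs) == 0:
            continue
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-12)
        bd.bonded += float(np.sum(0.5 * k * (r - rests) ** 2))
        fij = (-k * (r - rests) / r)[:, None] * d
        np.add.at(f, pairs[:, 0], fij)
        np.add.at(f, pairs[:, 1], -fij)

    # Bending.
    ks = np.where(t.angle_class == JOINT_HINGE, ff.bend_k_hinge, ff.bend_k_coil)
    e_bend, f_bend = _angle_energy_forces(pos, t.angles, ks)
    bd.bending += e_bend
    f += f_bend

    # Non-bonded chain-chain.
    i, j = nonbonded_pairs(model)
    if len(i):
        coil_pair = (model.segment_labels[i] != LINKER) & (
            model.segment_labels[j] != LINKER
        )
        e_ex, e_el, f_nb = _pair_energy_forces(
            pos, i, j, ff, model.charges, coil_pair
        )
        bd.excluded += e_ex
        bd.electrostatic += e_el
        f += f_nb

    # Substrate adhesion + impenetrability wall.
    if lattice is not None:
        lj = lattice.lj
        if lj is None:
            raise ValueError("lattice has no LJ parameters assigned")
        tree = cKDTree(lattice.positions)
        x6c = (lj.r_min / ff.cutoff) ** 6
        e_shift = lj.well_depth * (x6c * x6c - 2.0 * x6c)
        for bi, p in enumerate(pos):
            idx = tree.query_ball_point(p, ff.cutoff)
            if idx:
                d = p - lattice.positions[idx]
                r = np.linalg.norm(d, axis=1)
                r = np.maximum(r, 1e-12)
                x6 = (lj.r_min / r) ** 6
                bd.adhesion += float(
                    np.sum(lj.well_depth * (x6 * x6 - 2.0 * x6) - e_shift)
                )
                dEdr = lj.well_depth * 12.0 * (-x6 * x6 + x6) / r
                f[bi] += np.sum((-dEdr / r)[:, None] * d, axis=0)
        below = pos[:, 2] < ff.wall_z
        if np.any(below):
            dz = ff.wall_z - pos[below, 2]
            bd.excluded += float(np.sum(0.5 * ff.wall_k * dz**2))
            f[below, 2] += ff.wall_k * dz

    # Deposition pull.
    if pull is not None and pull.force_per_bead > 0:
        above = pos[:, 2] > pull.z_threshold
        bd.external_pull += float(
            np.sum(pull.force_per_bead * (pos[above, 2] - pull.z_threshold))
        )
        f[above, 2] -= pull.force_per_bead

    return bd, f


def total_energy(
    model: SubunitModel,
    lattice: SubstrateLattice | None,
    ff: ForceFieldParams,
    pull: PullSpec | None = None,
    positions: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Energy breakdown of a configuration; adhesion is zero without a
    lattice and the total is the exact sum of the components."""
    bd, _ = energy_and_forces(model, lattice, ff, pull, positions)
    return bd
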