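"""Coarse-grained bead-chain models of IF subunits and the adhesive substrate.

An intermediate-filament (IF) dimer is represented as a single bead-spring
path: two stiff coiled-coil segments (~22 and ~25 nm) joined by a short
flexible linker (the L12 hinge), 50 nm of contour in total.  A tetramer is
two antiparallel dimers, half-staggered along the axis, held together by
soft harmonic crosslinks in the overlap region; built straight it spans
~75 nm.  The substrate is a rigid plane of adhesion beads on a hexagonal
lattice (0.98 nm spacing) at z = 0.

Conventions: the substrate plane is z = 0 and "vertical distance" means the
+z coordinate; all lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Bead",
    "ChainTopology",
    "SubunitModel",
    "SubstrateLattice",
    "build_dimer",
    "build_chain",
    "build_tetramer",
    "build_substrate",
    "lattice_for_model",
    "DEFAULT_DIMER_PRESET",
]

COIL1 = "COIL1"
LINKER = "LINKER"
COIL2 = "COIL2"

JOINT_COIL = "COIL"
JOINT_HINGE = "HINGE"

#: Default dimer preset: 22 + 3 + 25 nm = 50 nm of contour at 1 bead/nm.
DEFAULT_DIMER_PRESET = dict(
    bond_length=1.0,
    coil1_length=22.0,
    linker_length=3.0,
    coil2_length=25.0,
)

#: Residues represented by one 1-nm bead: a vimentin dimer has 2 x ~466
#: residues over 50 nm of contour, ~18 residues per nm.  Overridable.
DEFAULT_RESIDUES_PER_BEAD = 18.0


@dataclass(frozen=True)
class Bead:
    """View of a single coarse-grained bead."""

    position: np.ndarray
    radius: float
    residues_per_bead: float
    charge: float
    segment_label: str


@dataclass
class ChainTopology:
    """Bonded topology of one or two bead paths.

    ``bonds``/``angles`` are index arrays into the owning model's bead list;
    ``angle_class`` marks each bending joint as a stiff COIL joint or a
    flexible HINGE joint (the L12 linker).  ``crosslinks`` are the soft
    inter-dimer contacts of the tetramer (and any chemical crosslinks added
    by the glutaraldehyde environment mode).
    """

    bonds: np.ndarray  # (M, 2) int
    bond_rest: np.ndarray  # (M,) nm
    angles: np.ndarray  # (K, 3) int, (i, j, k) centred on j
    angle_class: np.ndarray  # (K,) str, JOINT_COIL or JOINT_HINGE
    crosslinks: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )
    crosslink_rest: np.ndarray = field(default_factory=lambda: np.empty(0))

    def copy(self) -> "ChainTopology":
        return ChainTopology(
            self.bonds.copy(),
            self.bond_rest.copy(),
            self.angles.copy(),
            self.angle_class.copy(),
            self.crosslinks.copy(),
            self.crosslink_rest.copy(),
        )

    def validate(self, n_beads: int) -> None:
        if self.bonds.size and self.bonds.max() >= n_beads:
            raise ValueError("bond index out of range")
        if np.any(self.bond_rest <= 0):
            raise ValueError("bond rest lengths must be positive")
        if self.crosslink_rest.size and np.any(self.crosslink_rest <= 0):
            raise ValueError("crosslink rest lengths must be positive")


@dataclass
class SubunitModel:
    """A coarse-grained IF subunit (dimer, tetramer, or generic chain)."""

    positions: np.ndarray  # (N, 3) nm
    radii: np.ndarray  # (N,) nm
    charges: np.ndarray  # (N,) e
    segment_labels: np.ndarray  # (N,) str
    chain_id: np.ndarray  # (N,) int, 0 or 1
    topology: ChainTopology
    kind: str  # "dimer" | "tetramer" | "chain"
    contour_length_per_dimer: float
    residues_per_bead: float = DEFAULT_RESIDUES_PER_BEAD

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def termini(self) -> np.ndarray:
        """Indices of the terminal beads of each bead path."""
        idx = []
        for cid in np.unique(self.chain_id):
            members = np.flatnonzero(self.chain_id == cid)
            idx.extend([members[0], members[-1]])
        return np.asarray(idx, dtype=np.int64)

    def bead(self, i: int) -> Bead:
        return Bead(
            position=self.positions[i].copy(),
            radius=float(self.radii[i]),
            residues_per_bead=self.residues_per_bead,
            charge=float(self.charges[i]),
            segment_label=str(self.segment_labels[i]),
        )

    def copy(self) -> "SubunitModel":
        return SubunitModel(
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            charges=self.charges.copy(),
            segment_labels=self.segment_labels.copy(),
            chain_id=self.chain_id.copy(),
            topology=self.topology.copy(),
            kind=self.kind,
            contour_length_per_dimer=self.contour_length_per_dimer,
            residues_per_bead=self.residues_per_bead,
        )

    def translated(self, shift) -> "SubunitModel":
        out = self.copy()
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def placed_above_plane(self, z_min: float) -> "SubunitModel":
        """Translate so the lowest bead sits at height ``z_min``."""
        dz = z_min - self.positions[:, 2].min()
        return self.translated((0.0, 0.0, dz))


@dataclass
class SubstrateLattice:
    """Rigid hexagonal plane of adhesion beads at z = 0.

    ``lj`` carries the per-pair Lennard-Jones parameters between one chain
    bead and one lattice bead (set by `energetics.calibrate_bead_well_depth`).
    """

    positions: np.ndarray  # (M, 3) nm, z = 0
    spacing: float  # nm
    lj: "object"  # energetics.LJParams; kept loose to avoid an import cycle
    extent: tuple  # (width, depth) nm
    origin: tuple = (0.0, 0.0)  # (x0, y0) of the lattice corner
    n_cols: int = 0
    n_rows: int = 0

    @property
    def number_density(self) -> float:
        """Ideal areal density 2 / (sqrt(3) spacing^2), beads per nm^2."""
        return 2.0 / (np.sqrt(3.0) * self.spacing**2)


def _segment_chain(n_beads: int, bond_length: float, coil1: float, linker: float):
    """Per-bead segment labels and per-joint stiffness classes."""
    s = np.arange(n_beads) * bond_length
    labels = np.where(
        s < coil1 - 1e-9,
        COIL1,
        np.where(s <= coil1 + linker + 1e-9, LINKER, COIL2),
    ).astype(object)
    return np.asarray(labels, dtype="U6")


def build_chain(
    length: float,
    bond_length: float = 1.0,
    radius: float = 1.0,
    charge: float = 0.0,
    label: str = COIL1,
    residues_per_bead: float = DEFAULT_RESIDUES_PER_BEAD,
) -> SubunitModel:
    """Build a straight homogeneous bead chain (all joints COIL class).

    Useful for free-coil reference simulations (e.g. persistence-length
    recovery of a single coiled-coil segment).
    """
    if length <= 0 or bond_length <= 0:
        raise ValueError("length and bond_length must be positive")
    n_bonds = int(round(length / bond_length))
    if n_bonds < 1:
        raise ValueError("chain must contain at least one bond")
    n = n_bonds + 1
    positions = np.zeros((n, 3))
    positions[:, 0] = np.arange(n) * bond_length
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    angles = np.column_stack(
        [np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)]
    ).astype(np.int64)
    topo = ChainTopology(
        bonds=bonds,
        bond_rest=np.full(n - 1, bond_length),
        angles=angles,
        angle_class=np.full(n - 2, JOINT_COIL, dtype="U5"),
    )
    return SubunitModel(
        positions=positions,
        radii=np.full(n, radius),
        charges=np.full(n, charge),
        segment_labels=np.full(n, label, dtype="U6"),
        chain_id=np.zeros(n, dtype=np.int64),
        topology=topo,
        kind="chain",
        contour_length_per_dimer=n_bonds * bond_length,
        residues_per_bead=residues_per_bead,
    )


def build_dimer(
    bond_length: float = 1.0,
    coil1_length: float = 22.0,
    linker_length: float = 3.0,
    coil2_length: float = 25.0,
    radius: float = 1.0,
    coil_charge: float = -1.0,
    residues_per_bead: float = DEFAULT_RESIDUES_PER_BEAD,
) -> SubunitModel:
    """Build a straight CG dimer along +x starting at the origin.

    The default preset 22 + 3 + 25 nm reproduces the 50-nm coiled-coil
    dimer with a 3-nm flexible linker.  Bending joints whose centre bead
    lies inside the linker (junctions included) are classed HINGE; all
    others COIL.  Coil beads carry a uniform negative charge (coiled-coil
    segments are negatively charged at assembly pH), linker beads none.
    """
    for name, val in [
        ("bond_length", bond_length),
        ("coil1_length", coil1_length),
        ("linker_length", linker_length),
        ("coil2_length", coil2_length),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if bond_length > min(coil1_length, linker_length, coil2_length):
        raise ValueError("bond_length must not exceed any segment length")

    total = coil1_length + linker_length + coil2_length
    n_bonds = int(round(total / bond_length))
    n = n_bonds + 1
    positions = np.zeros((n, 3))
    positions[:, 0] = np.arange(n) * bond_length

    labels = _segment_chain(n, bond_length, coil1_length, linker_length)
    charges = np.where(labels == LINKER, 0.0, coil_charge)

    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    angles = np.column_stack(
        [np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)]
    ).astype(np.int64)
    angle_class = np.where(labels[angles[:, 1]] == LINKER, JOINT_HINGE, JOINT_COIL)

    topo = ChainTopology(
        bonds=bonds,
        bond_rest=np.full(n - 1, bond_length),
        angles=angles,
        angle_class=angle_class.astype("U5"),
    )
    topo.validate(n)
    return SubunitModel(
        positions=positions,
        radii=np.full(n, radius),
        charges=charges,
        segment_labels=labels,
        chain_id=np.zeros(n, dtype=np.int64),
        topology=topo,
        kind="dimer",
        contour_length_per_dimer=n_bonds * bond_length,
        residues_per_bead=residues_per_bead,
    )


def build_tetramer(
    dimer_template: SubunitModel | None = None,
    stagger: float = 25.0,
    lateral_gap: float = 2.0,
    crosslink_every: int = 1,
) -> SubunitModel:
    """Assemble two antiparallel, half-staggered dimers into a tetramer.

    The second dimer is reflected along x (antiparallel axis) and offset
    axially by ``stagger`` and laterally by ``lateral_gap``; built straight
    from 50-nm dimers with the default 25-nm stagger the rod spans ~75 nm.
    Facing beads in the axial overlap are joined by soft harmonic
    crosslinks with rest length ``lateral_gap`` (the inter-dimer cohesion
    of the A11-type overlap; the chemistry itself is not modelled).
    """
    if dimer_template is None:
        dimer_template = build_dimer()
    dimer = dimer_template
    L = dimer.contour_length_per_dimer
    if stagger >= L:
        raise ValueError(f"stagger {stagger} leaves no overlap with a {L} nm dimer")
    if lateral_gap <= 0:
        raise ValueError("lateral_gap must be positive")

    a = dimer.positions
    n = dimer.n_beads
    # Antiparallel copy: reflect along x about the template span, then shift.
    b = a.copy()
    b[:, 0] = stagger + (a[:, 0].max() + a[:, 0].min()) - a[:, 0]
    b[:, 1] = a[:, 1] + lateral_gap

    positions = np.vstack([a, b])
    radii = np.concatenate([dimer.radii, dimer.radii])
    charges = np.concatenate([dimer.charges, dimer.charges])
    labels = np.concatenate([dimer.segment_labels, dimer.segment_labels])
    chain_id = np.concatenate(
        [np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)]
    )

    t = dimer.topology
    bonds = np.vstack([t.bonds, t.bonds + n])
    bond_rest = np.concatenate([t.bond_rest, t.bond_rest])
    angles = np.vstack([t.angles, t.angles + n])
    angle_class = np.concatenate([t.angle_class, t.angle_class])

    # Crosslinks between facing beads in the overlap region.
    bond_length = float(np.median(t.bond_rest))
    xa, xb = a[:, 0], b[:, 0]
    lo, hi = max(xa.min(), xb.min()), min(xa.max(), xb.max())
    pairs, rests = [], []
    for i in np.flatnonzero((xa >= lo - 1e-9) & (xa <= hi + 1e-9))[::crosslink_every]:
        j = int(np.argmin(np.abs(xb - xa[i])))
        if abs(xb[j] - xa[i]) <= bond_length / 2 + 1e-9:
            pairs.append((i, j + n))
            rests.append(lateral_gap)
    crosslinks = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    crosslink_rest = np.asarray(rests, dtype=float)

    topo = ChainTopology(
        bonds=bonds,
        bond_rest=bond_rest,
        angles=angles,
        angle_class=angle_class,
        crosslinks=crosslinks,
        crosslink_rest=crosslink_rest,
    )
    topo.validate(2 * n)
    return SubunitModel(
        positions=positions,
        radii=radii,
        charges=charges,
        segment_labels=labels,
        chain_id=chain_id,
        topology=topo,
        kind="tetramer",
        contour_length_per_dimer=L,
        residues_per_bead=dimer.residues_per_bead,
    )


def build_substrate(
    spacing: float = 0.98,
    width: float = 60.0,
    depth: float = 20.0,
    lj=None,
    origin: tuple = (0.0, 0.0),
) -> SubstrateLattice:
    """Build a hexagonal lattice of substrate beads at z = 0.

    Rows are spaced by spacing*sqrt(3)/2 in y with alternate rows offset by
    spacing/2 in x, so every interior bead has six neighbours at exactly
    ``spacing``.  Generation is deterministic for fixed arguments.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if width < spacing or depth < spacing:
        raise ValueError("extent smaller than one lattice cell")
    row_h = spacing * np.sqrt(3.0) / 2.0
    n_cols = int(np.floor(width / spacing)) + 1
    n_rows = int(np.floor(depth / row_h)) + 1
    jj, ii = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    x = origin[0] + ii * spacing + (jj % 2) * (spacing / 2.0)
    y = origin[1] + jj * row_h
    pos = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
    return SubstrateLattice(
        positions=pos,
        spacing=spacing,
        lj=lj,
        extent=(width, depth),
        origin=(float(origin[0]), float(origin[1])),
        n_cols=n_cols,
        n_rows=n_rows,
    )


def lattice_for_model(
    model: SubunitModel,
    spacing: float = 0.98,
    lj=None,
    margin: float = 10.0,
) -> SubstrateLattice:
    """Build a substrate sized to the model's xy bounding box plus margin.

    The margin must exceed the non-bonded cutoff plus the lateral room the
    subunit may explore; 10 nm is ample for deposition runs, where adsorbed
    subunits barely translate.
    """
    xy = model.positions[:, :2]
    lo = xy.min(axis=0) - margin
    hi = xy.max(axis=0) + margin
    return build_substrate(
        spacing=spacing,
        width=float(hi[0] - lo[0]),
        depth=float(hi[1] - lo[1]),
        lj=lj,
        origin=(float(lo[0]), float(lo[1])),
    )
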