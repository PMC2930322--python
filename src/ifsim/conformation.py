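"""Conformational observables of CG subunits.

End-to-end length, Kabsch RMSD, principal-axis projection area, a
coarse-grained solvent-accessible surface area, worm-like-chain tangent
analytics, and a tangent-correlation persistence-length estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import SubunitModel, JOINT_HINGE

__all__ = [
    "ConformationMetrics",
    "end_to_end_length",
    "kabsch_rmsd",
    "projection_area",
    "cg_sasa",
    "wlc_mean_tangent_angle",
    "estimate_persistence_length",
    "equivalent_disk_diameter",
    "radius_of_gyration",
    "metrics_for_frame",
]


@dataclass
class ConformationMetrics:
    end_to_end: float  # nm
    projection_area: float  # nm^2
    sasa: float  # nm^2
    rmsd_to_reference: float = 0.0  # nm
    persistence_length_estimate: float = float("nan")  # nm


def _positions_of(model_or_positions) -> np.ndarray:
    if hasattr(model_or_positions, "positions"):
        return model_or_positions.positions
    return np.asarray(model_or_positions, dtype=float)


def end_to_end_length(model: SubunitModel, positions: np.ndarray | None = None) -> float:
    """End-to-end length L_ee in nm.

    For a single path: the distance between its terminal beads.  For a
    tetramer (two bead paths) L_ee is the maximum distance among the four
    terminal beads -- the length of the rod, which for the straight
    half-staggered build equals ~75 nm.
    """
    pos = model.positions if positions is None else positions
    if pos.shape[0] < 2:
        raise ValueError("need at least two beads")
    term = model.termini
    if len(term) <= 2:
        return float(np.linalg.norm(pos[term[0]] - pos[term[-1]]))
    pts = pos[term]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD between two equal-size bead sets over proper rigid
    motions (rotation + translation, no reflection), unweighted."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have matching shapes")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * np.array([1.0, 1.0, d])) @ vt  # proper rotation, maps b to a
    resid = a - b @ rot.T
    return float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))


def _principal_axes(pos: np.ndarray) -> np.ndarray:
    """Principal axes as columns, ordered by decreasing variance; ties and
    degenerate (collinear) sets broken deterministically."""
    centred = pos - pos.mean(axis=0)
    cov = centred.T @ centred / pos.shape[0]
    vals, vecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(vals)[::-1]
    axes = vecs[:, order]
    # deterministic sign convention: largest-magnitude entry positive
    for k in range(3):
        col = axes[:, k]
        imax = int(np.argmax(np.abs(col)))
        if col[imax] < 0:
            axes[:, k] = -col
    return axes


def projection_area(
    model_or_positions,
    radii=None,
    grid_resolution: float = 0.25,
    plane: str = "max_footprint",
) -> float:
    """Footprint area (nm^2) of the union of bead disks projected onto a
    principal plane.

    ``plane='max_footprint'`` (default) projects along the third principal
    axis, giving the maximal spread -- the analogue of the area a subunit
    covers on a surface.  ``plane='min_footprint'`` projects along the
    first principal axis (the minimal cross-section).  The area is counted
    as occupied raster cells times the cell area, so it is invariant under
    rigid motions up to grid error.
    """
    pos = _positions_of(model_or_positions)
    if radii is None:
        if hasattr(model_or_positions, "radii"):
            radii = model_or_positions.radii
        else:
            radii = np.ones(pos.shape[0])
    radii = np.asarray(radii, dtype=float)
    if grid_resolution > radii.min():
        raise ValueError("grid_resolution must not exceed the bead radius")
    axes = _principal_axes(pos)
    if plane == "max_footprint":
        basis = axes[:, :2]
    elif plane == "min_footprint":
        basis = axes[:, 1:]
    else:
        raise ValueError("plane must be 'max_footprint' or 'min_footprint'")
    xy = (pos - pos.mean(axis=0)) @ basis
    rmax = radii.max()
    lo = xy.min(axis=0) - rmax - grid_resolution
    hi = xy.max(axis=0) + rmax + grid_resolution
    nx = int(np.ceil((hi[0] - lo[0]) / grid_resolution))
    ny = int(np.ceil((hi[1] - lo[1]) / grid_resolution))
    gx = lo[0] + (np.arange(nx) + 0.5) * grid_resolution
    gy = lo[1] + (np.arange(ny) + 0.5) * grid_resolution
    occ = np.zeros((nx, ny), dtype=bool)
    for (cx, cy), r in zip(xy, radii):
        ix0 = max(int((cx - r - lo[0]) / grid_resolution) - 1, 0)
        ix1 = min(int((cx + r - lo[0]) / grid_resolution) + 2, nx)
        iy0 = max(int((cy - r - lo[1]) / grid_resolution) - 1, 0)
        iy1 = min(int((cy + r - lo[1]) / grid_resolution) + 2, ny)
        dx = gx[ix0:ix1, None] - cx
        dy = gy[None, iy0:iy1] - cy
        occ[ix0:ix1, iy0:iy1] |= dx * dx + dy * dy <= r * r
    return float(occ.sum()) * grid_resolution**2


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere point set."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def cg_sasa(
    model_or_positions,
    radii=None,
    probe_radius: float = 0.0,
    n_sphere_points: int = 960,
) -> float:
    """Shrake-Rupley surface area (nm^2) over beads inflated by the probe.

    Deterministic Fibonacci point set; a point on bead i's inflated sphere
    is exposed if it lies outside every other inflated sphere.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    pos = _positions_of(model_or_positions)
    if radii is None:
        if hasattr(model_or_positions, "radii"):
            radii = model_or_positions.radii
        else:
            radii = np.ones(pos.shape[0])
    rr = np.asarray(radii, dtype=float) + probe_radius
    # fully coincident beads contribute a single surface
    keep = np.ones(pos.shape[0], dtype=bool)
    for i in range(pos.shape[0]):
        if not keep[i]:
            continue
        dup = (
            (np.linalg.norm(pos - pos[i], axis=1) < 1e-9)
            & (np.abs(rr - rr[i]) < 1e-9)
        )
        dup[: i + 1] = False
        keep[dup] = False
    pos = pos[keep]
    rr = rr[keep]
    sphere = _fibonacci_sphere(n_sphere_points)
    total = 0.0
    for i in range(pos.shape[0]):
        pts = pos[i] + rr[i] * sphere
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in range(pos.shape[0]):
            if j == i:
                continue
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            exposed &= ~(d2 < rr[j] ** 2 - 1e-12)
        total += 4.0 * math.pi * rr[i] ** 2 * exposed.mean()
    return float(total)


def wlc_mean_tangent_angle(L: float, Lp: float) -> float:
    """Mean angle (degrees) between the tangents at the ends of a
    worm-like chain segment: arccos(exp(-L/Lp)).

    For a coiled-coil segment with L = Lp = 25 nm this gives ~68 degrees,
    the "around 70 degrees" end-tangent decorrelation.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    if Lp <= 0:
        raise ValueError("Lp must be positive")
    return math.degrees(math.acos(math.exp(-L / Lp)))


def _coil_tangent_correlations(traj, max_sep: int):
    """Pooled tangent correlations over bonds whose flanking joints are all
    COIL class, per separation in bonds; never crosses a hinge."""
    model = traj.model
    t = model.topology
    hinge_centers = set(
        int(j) for j, cls in zip(t.angles[:, 1], t.angle_class) if cls == JOINT_HINGE
    )
    # split each chain's bond list into runs not interrupted by hinges
    runs = []
    for cid in np.unique(model.chain_id):
        members = np.flatnonzero(model.chain_id == cid)
        bonds = [
            (i, j)
            for i, j in zip(members[:-1], members[1:])
        ]
        run = []
        for i, j in bonds:
            run.append((i, j))
            if j in hinge_centers:
                if len(run) > 1:
                    runs.append(run)
                run = []
        if len(run) > 1:
            runs.append(run)
    corr_sum = np.zeros(max_sep + 1)
    corr_n = np.zeros(max_sep + 1)
    for frame in traj.positions:
        for run in runs:
            i = np.array([b[0] for b in run])
            j = np.array([b[1] for b in run])
            tv = frame[j] - frame[i]
            tv /= np.linalg.norm(tv, axis=1)[:, None]
            m = len(run)
            for sep in range(0, min(max_sep, m - 1) + 1):
                c = np.sum(tv[: m - sep] * tv[sep:], axis=1)
                corr_sum[sep] += c.sum()
                corr_n[sep] += len(c)
    valid = corr_n > 0
    return corr_sum[valid] / corr_n[valid], np.flatnonzero(valid)


def estimate_persistence_length(
    traj,
    max_sep: int = 10,
    min_frames: int = 50,
) -> float:
    """Persistence length (nm) from exponential tangent decorrelation.

    Fits log<t(s).t(s+d)> = -d*b/Lp over coil bonds pooled across frames
    (hinges are never crossed).  Returns math.inf when the correlation
    does not decay (rigid chain: Lp is at least the contour length).
    """
    if traj.n_frames < min_frames:
        raise ValueError(
            f"need at least {min_frames} frames for the fit, got {traj.n_frames}"
        )
    corr, seps = _coil_tangent_correlations(traj, max_sep)
    b = float(np.median(traj.model.topology.bond_rest))
    # fit only the leading, statistically resolved part of the decay:
    # once the correlation falls to the sampling noise floor the log is
    # meaningless and would bias the slope towards zero
    floor = 0.05
    n_lead = 1
    while n_lead < len(corr) and corr[n_lead] > floor:
        n_lead += 1
    if n_lead < 2:
        # decorrelated within one bond (freely jointed limit)
        c1 = max(float(corr[1]), 1e-6) if len(corr) > 1 else 1e-6
        return float(-b / math.log(c1))
    x = seps[:n_lead] * b
    y = np.log(corr[:n_lead])
    slope = np.polyfit(x, y, 1)[0]
    if slope >= -1e-9:
        return math.inf
    return float(-1.0 / slope)


def equivalent_disk_diameter(area: float) -> float:
    """Diameter (nm) of the disk with the given area: 2 sqrt(area/pi)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * math.sqrt(area / math.pi)


def radius_of_gyration(model_or_positions) -> float:
    pos = _positions_of(model_or_positions)
    c = pos - pos.mean(axis=0)
    return float(np.sqrt(np.sum(c * c) / pos.shape[0]))


def metrics_for_frame(
    model: SubunitModel,
    positions: np.ndarray,
    reference: np.ndarray | None = None,
    probe_radius: float = 0.0,
) -> ConformationMetrics:
    """Convenience bundle of the per-frame observables."""
    return ConformationMetrics(
        end_to_end=end_to_end_length(model, positions),
        projection_area=projection_area(positions, model.radii),
        sasa=cg_sasa(positions, model.radii, probe_radius=probe_radius),
        rmsd_to_reference=(
            kabsch_rmsd(positions, reference) if reference is not None else 0.0
        ),
    )
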