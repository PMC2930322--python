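"""Synthetic AFM height maps of dried IF subunits.

Renders scenes that emulate the measured object statistics of air-dried
subunit populations on mica: dot-like particles (spherical caps) alongside
curly threads (2D worm-like ribbons), optionally with filaments (long
high ribbons).  Per-object footprint areas follow an exponential law (the
measured area distributions decrease exponentially) with the preset mean;
per-object peak heights are normal, truncated at zero, with the preset
mean and sd.  Every placed object is recorded as ground truth so the
morphometry pipeline can be validated without real data.

Presets (heights nm, areas nm^2) follow the measured populations:
vimentin in NaCl 0.31+-0.07 / 570; K5/K14 in NaCl 0.62+-0.07 / 909;
K5/K14 glutaraldehyde-fixed 0.66+-0.07 / 587; K5/K14 in CaCl2
0.51+-0.06 / 246; filaments 2.5+-0.8 nm high.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ScenePreset",
    "AFMImage",
    "PRESETS",
    "generate_scene",
    "render_tip_dilation",
    "add_noise",
    "write_tiff",
    "read_tiff",
]


@dataclass(frozen=True)
class ScenePreset:
    """Object statistics of one experimental condition."""

    name: str
    dot_fraction: float  # fraction of subunits rendered as dots vs threads
    mean_height: float  # nm
    sd_height: float  # nm
    mean_area: float  # nm^2 (exponential mean of the footprint area)
    thread_width: float = 6.0  # nm
    filament_density: float = 0.0  # count per um^2 (when filaments requested)
    filament_height: float = 2.5  # nm
    filament_width: float = 40.0  # nm (flat-tape morphology)


PRESETS = {
    "vimentin_NaCl": ScenePreset(
        "vimentin_NaCl", dot_fraction=0.75, mean_height=0.31, sd_height=0.07,
        mean_area=570.0, filament_density=1.0,
    ),
    "K5K14_NaCl": ScenePreset(
        "K5K14_NaCl", dot_fraction=0.60, mean_height=0.62, sd_height=0.07,
        mean_area=909.0,
    ),
    "K5K14_glutaraldehyde": ScenePreset(
        "K5K14_glutaraldehyde", dot_fraction=0.90, mean_height=0.66,
        sd_height=0.07, mean_area=587.0,
    ),
    "K5K14_CaCl2": ScenePreset(
        "K5K14_CaCl2", dot_fraction=0.90, mean_height=0.51, sd_height=0.06,
        mean_area=246.0,
    ),
}


@dataclass
class GroundTruthObject:
    kind: str  # "dot" | "thread" | "filament"
    drawn_area: float  # nm^2, the sampled target footprint area
    pixel_area: float  # nm^2, rendered footprint pixels x pixel^2
    height: float  # nm, peak height
    bbox: tuple  # (r0, r1, c0, c1) slice bounds into the image
    mask: np.ndarray  # bool, local footprint within bbox
    contacts_filament: bool = False


@dataclass
class AFMImage:
    """Single-channel height map with pixel size and provenance."""

    heights: np.ndarray  # (H, W) nm
    pixel_size: float  # nm
    preset: str = ""
    seed: int | None = None
    tip_radius: float = 0.0  # nm, 0 = undilated
    noise_sigma: float = 0.0  # nm
    ground_truth: list = field(default_factory=list)

    @property
    def shape(self):
        return self.heights.shape

    def support_mask(self) -> np.ndarray:
        """Union of all ground-truth footprints."""
        out = np.zeros(self.heights.shape, dtype=bool)
        for obj in self.ground_truth:
            r0, r1, c0, c1 = obj.bbox
            out[r0:r1, c0:c1] |= obj.mask
        return out

    def copy_with(self, heights: np.ndarray, **kw) -> "AFMImage":
        return AFMImage(
            heights=heights,
            pixel_size=self.pixel_size,
            preset=self.preset,
            seed=self.seed,
            tip_radius=kw.get("tip_radius", self.tip_radius),
            noise_sigma=kw.get("noise_sigma", self.noise_sigma),
            ground_truth=self.ground_truth,
        )


def _truncated_normal(rng, mean, sd, n):
    """Normal(mean, sd) truncated at zero, by rejection."""
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(mean, sd, size=n - got)
        keep = draw > 0
        k = int(keep.sum())
        out[got : got + k] = draw[keep]
        got += k
    return out


def _render_dot(area, height, pixel_size):
    """Spherical-cap height patch and footprint mask for one dot."""
    r = math.sqrt(area / math.pi)
    rc = (r * r + height * height) / (2.0 * height)  # cap sphere radius
    n = int(math.ceil(r / pixel_size)) + 1
    ax = (np.arange(2 * n + 1) - n) * pixel_size
    rho2 = ax[:, None] ** 2 + ax[None, :] ** 2
    mask = rho2 <= r * r
    patch = np.zeros_like(rho2)
    patch[mask] = np.sqrt(np.maximum(rc * rc - rho2[mask], 0.0)) - (rc - height)
    patch = np.maximum(patch, 0.0)
    patch[patch < 1e-9] = 0.0  # drop rounding dust at the rim
    return patch, patch > 0


def _wlc_path(rng, length, step, persistence):
    """Discrete 2D worm-like path: per-step heading diffusion with
    variance step/persistence (tangent correlation exp(-s/Lp))."""
    n = max(int(round(length / step)), 2)
    theta = rng.uniform(0, 2 * math.pi)
    pts = [np.zeros(2)]
    for _ in range(n):
        theta += rng.normal(0.0, math.sqrt(step / persistence))
        pts.append(pts[-1] + step * np.array([math.cos(theta), math.sin(theta)]))
    return np.array(pts)


def _render_ribbon(path, width, height, pixel_size, profile="cosine"):
    """Height patch for a ribbon of the given width along a 2D path."""
    # densify the path to sub-pixel resolution
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    dense = [path[0]]
    for p0, s, sl in zip(path[:-1], seg, seglen):
        k = max(int(math.ceil(sl / (0.4 * pixel_size))), 1)
        for t in np.linspace(1.0 / k, 1.0, k):
            dense.append(p0 + t * s)
    dense = np.array(dense)
    lo = dense.min(axis=0) - width
    hi = dense.max(axis=0) + width
    nr = int(math.ceil((hi[1] - lo[1]) / pixel_size)) + 1
    nc = int(math.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    # distance of each pixel centre to the path
    occ = np.ones((nr, nc), dtype=bool)
    cols = np.clip(((dense[:, 0] - lo[0]) / pixel_size).astype(int), 0, nc - 1)
    rows = np.clip(((dense[:, 1] - lo[1]) / pixel_size).astype(int), 0, nr - 1)
    on = np.zeros((nr, nc), dtype=bool)
    on[rows, cols] = True
    dist = ndimage.distance_transform_edt(~on, sampling=pixel_size)
    half = width / 2.0
    mask = dist <= half
    patch = np.zeros((nr, nc))
    if profile == "cosine":
        patch[mask] = height * np.cos(math.pi * dist[mask] / width)
    else:
        patch[mask] = height
    patch = np.maximum(patch, 0.0)
    patch[patch < 1e-9] = 0.0  # drop rounding dust at the rim
    return patch, patch > 0


def _try_place(rng, patch_mask, margin_masks, margin_px, strict_masks=(), near_mask=None):
    """Random placement of ``patch_mask``; returns (r0, c0) or None.

    ``margin_masks`` may not be hit by the margin-grown patch;
    ``strict_masks`` may not be hit by the patch itself; with a
    ``near_mask`` the 1-px-dilated patch must intersect it (used to place
    subunits deliberately in contact with filaments); candidate positions
    are then anchored near random near_mask pixels.
    """
    H, W = margin_masks[0].shape
    h, w = patch_mask.shape
    if h >= H or w >= W:
        return None
    grown = (
        ndimage.binary_dilation(patch_mask, iterations=margin_px)
        if margin_px
        else patch_mask
    )
    touch = ndimage.binary_dilation(patch_mask, iterations=1)
    if near_mask is not None:
        # anchor on the exterior rim of the target and align a rim pixel
        # of the dilated patch with it: adjacency (gap of at most two
        # pixels, within the 1-px contact rule on both sides) follows
        near_ok = ndimage.binary_dilation(near_mask, iterations=1)
        # second exterior shell: aligning a rim pixel of the dilated patch
        # here puts the patch two pixels from the target
        rim = ndimage.binary_dilation(near_ok, iterations=1) & ~near_ok
        anchors = np.argwhere(rim)
        ring = np.argwhere(touch & ~patch_mask)
        if len(anchors) == 0 or len(ring) == 0:
            return None
    else:
        anchors = ring = None
        near_ok = None
    for _ in range(300):
        if anchors is None:
            r0 = rng.integers(0, H - h)
            c0 = rng.integers(0, W - w)
        else:
            ar, ac = anchors[rng.integers(0, len(anchors))]
            pr, pc = ring[rng.integers(0, len(ring))]
            r0 = int(ar - pr)
            c0 = int(ac - pc)
            if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
                continue
        sl = (slice(r0, r0 + h), slice(c0, c0 + w))
        if any(np.any(m[sl] & grown) for m in margin_masks):
            continue
        if any(np.any(m[sl] & patch_mask) for m in strict_masks):
            continue
        if near_ok is not None and not np.any(near_ok[sl] & touch):
            continue
        return int(r0), int(c0)
    return None


def generate_scene(
    preset,
    n_subunits: int,
    image_size: float = 2000.0,
    pixel_size: float = 2.0,
    seed: int = 0,
    n_filaments: int = 0,
    contact_fraction: float = 0.0,
    min_area: float = 16.0,
    thread_persistence: float = 50.0,
    margin_px: int = 4,
) -> AFMImage:
    """Render a clean (noise-free, undilated) synthetic scene.

    Subunit footprint areas are drawn as min_area + Exponential(mean -
    min_area), keeping the population mean exactly at the preset value
    while guaranteeing detectability; peak heights are truncated-normal.
    A ``dot_fraction`` of subunits are spherical caps, the rest 2D
    worm-like threads of the preset width.  Objects are placed without
    overlap by rejection sampling (margin ``margin_px`` pixels); a
    ``contact_fraction`` of dots is deliberately placed touching a
    filament and flagged in the ground truth.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if pixel_size > 4.0:
        raise ValueError("pixel_size must be <= 4 nm to resolve subunits")
    if min_area >= preset.mean_area:
        raise ValueError("min_area must be below the preset mean area")
    rng = np.random.default_rng(seed)
    n_px = int(round(image_size / pixel_size))
    heights = np.zeros((n_px, n_px))
    occupied = np.zeros((n_px, n_px), dtype=bool)
    truth: list[GroundTruthObject] = []

    filament_mask = np.zeros((n_px, n_px), dtype=bool)
    for _ in range(n_filaments):
        # gently curved ribbon crossing the image
        length = image_size * 1.5
        path = _wlc_path(rng, length, 10.0, persistence=2000.0)
        path = path - path.mean(axis=0) + rng.uniform(
            0.25 * image_size, 0.75 * image_size, size=2
        )
        h_fil = max(rng.normal(preset.filament_height, 0.8), 0.5)
        patch, mask = _render_ribbon(
            path, preset.filament_width, h_fil, pixel_size
        )
        # clip patch to the image at its natural position
        r0 = int((path[:, 1].min() - preset.filament_width) / pixel_size)
        c0 = int((path[:, 0].min() - preset.filament_width) / pixel_size)
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1 = min(r0 + patch.shape[0], n_px)
        cc1 = min(c0 + patch.shape[1], n_px)
        if rr1 <= rr0 or cc1 <= cc0:
            continue
        sub = patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        msub = mask[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        heights[rr0:rr1, cc0:cc1] = np.maximum(heights[rr0:rr1, cc0:cc1], sub)
        occupied[rr0:rr1, cc0:cc1] |= msub
        filament_mask[rr0:rr1, cc0:cc1] |= msub
        truth.append(
            GroundTruthObject(
                kind="filament",
                drawn_area=float(msub.sum()) * pixel_size**2,
                pixel_area=float(msub.sum()) * pixel_size**2,
                height=float(h_fil),
                bbox=(rr0, rr1, cc0, cc1),
                mask=msub.copy(),
            )
        )
    fil_rim1 = None
    areas = min_area + rng.exponential(preset.mean_area - min_area, n_subunits)
    hts = _truncated_normal(rng, preset.mean_height, preset.sd_height, n_subunits)
    kinds = np.where(
        rng.random(n_subunits) < preset.dot_fraction, "dot", "thread"
    )
    contact = rng.random(n_subunits) < contact_fraction
    if n_filaments == 0:
        contact[:] = False

    for A, h, kind, want_contact in zip(areas, hts, kinds, contact):
        if kind == "dot":
            patch, mask = _render_dot(A, h, pixel_size)
        else:
            w = preset.thread_width
            length = max((A - math.pi * (w / 2) ** 2) / w, 2 * w)
            path = _wlc_path(rng, length, 2.0, thread_persistence)
            patch, mask = _render_ribbon(path, w, h, pixel_size)
        if want_contact:
            # separated from the filament by exactly one background pixel:
            # inside the pipeline's 1-px contact rule, yet still a
            # separate 8-connected object
            if fil_rim1 is None:
                # 8-connected rim: keeps contact objects segmentable as
                # separate 8-connected components
                fil_rim1 = ndimage.binary_dilation(
                    filament_mask, structure=np.ones((3, 3), dtype=bool)
                )
            spot = _try_place(
                rng,
                mask,
                margin_masks=[occupied & ~filament_mask],
                margin_px=margin_px,
                strict_masks=[fil_rim1],
                near_mask=filament_mask,
            )
        else:
            spot = _try_place(
                rng, mask, margin_masks=[occupied], margin_px=margin_px
            )
        if spot is None:
            raise RuntimeError(
                f"could not place {n_subunits} subunits without overlap in a "
                f"{image_size:.0f} nm field; enlarge the image or reduce n"
            )
        r0, c0 = spot
        r1, c1 = r0 + mask.shape[0], c0 + mask.shape[1]
        heights[r0:r1, c0:c1] = np.maximum(heights[r0:r1, c0:c1], patch)
        occupied[r0:r1, c0:c1] |= mask
        truth.append(
            GroundTruthObject(
                kind=str(kind),
                drawn_area=float(A),
                pixel_area=float(mask.sum()) * pixel_size**2,
                height=float(h),
                bbox=(r0, r1, c0, c1),
                mask=mask.copy(),
                contacts_filament=bool(want_contact),
            )
        )

    return AFMImage(
        heights=heights,
        pixel_size=pixel_size,
        preset=preset.name,
        seed=seed,
        ground_truth=truth,
    )


def render_tip_dilation(image: AFMImage, tip_radius: float) -> AFMImage:
    """Grayscale morphological dilation by a spherical tip of the given
    radius: the classic tip-convolution artifact.  Output >= input
    everywhere; zero radius is the identity."""
    if tip_radius < 0:
        raise ValueError("tip_radius must be non-negative")
    if tip_radius == 0:
        return image.copy_with(image.heights.copy())
    p = image.pixel_size
    n = int(math.floor(tip_radius / p))
    ax = (np.arange(2 * n + 1) - n) * p
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    footprint = d2 <= tip_radius**2
    # inverted tip profile: 0 at the apex, negative towards the rim
    structure = np.where(
        footprint, np.sqrt(np.maximum(tip_radius**2 - d2, 0.0)) - tip_radius, -np.inf
    )
    out = ndimage.grey_dilation(
        image.heights, footprint=footprint, structure=structure
    )
    return image.copy_with(np.maximum(out, image.heights), tip_radius=tip_radius)


def add_noise(image: AFMImage, sigma: float = 0.03, seed: int = 0) -> AFMImage:
    """Add zero-mean Gaussian height noise (instrument noise stand-in)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return image.copy_with(image.heights.copy())
    rng = np.random.default_rng(seed)
    out = image.heights + rng.normal(0.0, sigma, size=image.heights.shape)
    return image.copy_with(out, noise_sigma=sigma)


def write_ground_truth(path, image: AFMImage) -> None:
    """Dump the placed-object ground truth (class, areas, heights,
    bounding boxes, contact flags) as JSON; footprint masks are omitted
    (re-derivable from the clean height map support)."""
    rows = [
        {
            "kind": o.kind,
            "drawn_area_nm2": o.drawn_area,
            "pixel_area_nm2": o.pixel_area,
            "height_nm": o.height,
            "bbox_px": list(o.bbox),
            "contacts_filament": o.contacts_filament,
        }
        for o in image.ground_truth
    ]
    meta = {
        "preset": image.preset,
        "seed": image.seed,
        "pixel_size_nm": image.pixel_size,
        "objects": rows,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)


def write_tiff(path, image: AFMImage) -> None:
    """Write a single-channel 32-bit float TIFF with metadata."""
    import tifffile

    meta = {
        "pixel_size_nm": image.pixel_size,
        "preset": image.preset,
        "seed": image.seed,
        "tip_radius_nm": image.tip_radius,
        "noise_sigma_nm": image.noise_sigma,
    }
    tifffile.imwrite(
        str(path),
        image.heights.astype(np.float32),
        description=json.dumps(meta),
    )


def read_tiff(path) -> AFMImage:
    """Read a height map written by `write_tiff` (or any single-channel
    TIFF; pixel size defaults to 1 nm if no metadata is present)."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        heights = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return AFMImage(
        heights=heights,
        pixel_size=float(meta.get("pixel_size_nm", 1.0)),
        preset=str(meta.get("preset", "")),
        seed=meta.get("seed"),
        tip_radius=float(meta.get("tip_radius_nm", 0.0)),
        noise_sigma=float(meta.get("noise_sigma_nm", 0.0)),
    )
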