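"""Automated data preparation: masking, intensity matching, resampling,
mutual-information registration, and overlap-ROI extraction.

Pipeline order for a (cbct, mdct) pair: mask the CBCT background → fit and
apply a monotone linear intensity map taking CBCT onto the MDCT HU scale →
clip both volumes to [−1200, 3071] HU → rigid-then-affine registration
driven by Mattes mutual information on a 3-level pyramid → restrict both
fields of view to the overlapping cuboid.

Conventions: arrays are indexed (z, y, x), 0-based; cuboids are half-open;
world coordinates are ``index * spacing + origin`` in mm.  Transforms map
points of the *moving* frame into the *fixed* frame:
``p_fixed = linear @ (p_moving - center) + center + translation``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import HU_MAX, HU_MIN, Volume


@dataclass
class BinaryMask:
    """Boolean grid aligned with a source volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class AffineTransform:
    """Affine map between volume frames (world mm, (z, y, x) order)."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part is singular")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float))

    @classmethod
    def rigid(cls, rotation_deg, translation_mm, center) -> "AffineTransform":
        return cls(_rotation_zyx(rotation_deg), translation_mm, center)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.linear.T + self.center + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        # p_m = inv @ (p_f - c - t) + c  ==  inv @ (p_f - c) + c + [inv@(-t)]
        return AffineTransform(inv, -inv @ self.translation, self.center)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self ∘ other (apply ``other`` first)."""
        A, B = self, other
        lin = A.linear @ B.linear
        # expand both maps about A.center
        shift = A.linear @ (B.center - A.center + B.translation - (B.linear @ (B.center - A.center)))
        return AffineTransform(lin, shift + A.translation, A.center)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on (z, y, x, 1) world columns."""
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.center + self.translation - self.linear @ self.center
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3], np.zeros(3))

    def save(self, path) -> None:
        """Plain-text 4x4 homogeneous matrix, (z, y, x, 1) world columns."""
        np.savetxt(path, self.as_matrix(), fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls.from_matrix(np.loadtxt(path))


def _rotation_zyx(rotation_deg) -> np.ndarray:
    az, ay, ax = (math.radians(a) for a in rotation_deg)
    cz, sz = math.cos(az), math.sin(az)
    cy, sy = math.cos(ay), math.sin(ay)
    cx, sx = math.cos(ax), math.sin(ax)
    Rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    Ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    Rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class Cuboid:
    """Half-open index intervals [lo, hi) per axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        for l, h in zip(self.lo, self.hi):
            if not l < h:
                raise ValueError(f"degenerate cuboid: lo={self.lo} hi={self.hi}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def extent(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


# ---------------------------------------------------------------------------
# masking and intensity


def mask_background(vol: Volume, median_radius: int = 2) -> BinaryMask:
    """Median-filter + Otsu foreground mask, largest component, holes filled.

    Raises on (near-)constant volumes, where the Otsu threshold is undefined.
    """
    data = vol.data
    if np.ptp(data) == 0:
        raise ValueError("constant volume: Otsu threshold undefined")
    size = 2 * int(median_radius) + 1
    filt = ndimage.median_filter(data, size=size)
    if np.ptp(filt) == 0:
        raise ValueError("volume constant after median filtering; cannot threshold")
    thr = threshold_otsu(filt)
    fg = filt > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no foreground found above Otsu threshold")
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(counts)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(fg)


def fit_intensity_map(cbct: Volume, mdct: Volume, mask: BinaryMask,
                      n_quantiles: int = 256) -> tuple[float, float]:
    """Least-squares linear fit through paired quantiles inside the mask.

    Returns (slope, intercept) of the monotone map HU ≈ slope·cbct + intercept.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    a = cbct.data[m].astype(np.float64)
    b = mdct.data[m].astype(np.float64)
    if a.std() == 0:
        raise ValueError("zero intensity variance inside mask")
    q = np.linspace(0.0, 1.0, n_quantiles)
    qa = np.quantile(a, q)
    qb = np.quantile(b, q)
    slope, intercept = np.polyfit(qa, qb, 1)
    return float(slope), float(intercept)


def clip_hu(vol: Volume) -> Volume:
    return vol.with_data(np.clip(vol.data, HU_MIN, HU_MAX))


def clip_and_match_intensity(cbct: Volume, mdct: Volume,
                             mask: BinaryMask) -> tuple[Volume, Volume]:
    """Map CBCT intensities onto the MDCT HU scale and clip both volumes.

    Returns ``(cbct_matched, mdct_clipped)``, both within [−1200, 3071] HU.
    """
    slope, intercept = fit_intensity_map(cbct, mdct, mask)
    mapped = slope * cbct.data.astype(np.float64) + intercept
    cb = cbct.with_data(np.clip(mapped, HU_MIN, HU_MAX))
    return cb, clip_hu(mdct)


def resample(vol: Volume, target_spacing) -> Volume:
    """Trilinear resample onto ``round(shape * spacing / target)`` grid."""
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError("target_spacing must be positive")
    if target == vol.spacing:
        return Volume(vol.data.copy(), vol.spacing, vol.origin, vol.modality)
    factors = [o / t for o, t in zip(vol.spacing, target)]
    out = ndimage.zoom(vol.data.astype(np.float64), factors, order=1,
                       mode="nearest", grid_mode=False)
    return Volume(out.astype(np.float32), target, vol.origin, vol.modality)


# ---------------------------------------------------------------------------
# mutual information and registration


def _resample_through(fixed: Volume, moving: Volume,
                      transform: AffineTransform, stride: int = 1):
    """Sample the moving volume on the (optionally strided) fixed grid
    through ``transform``.

    Returns (values on the sample grid, validity mask of in-bounds samples,
    fixed values on the same grid).
    """
    inv = transform.inverse()
    axes = [np.arange(0, n, stride, dtype=np.float64) for n in fixed.shape]
    grid = np.meshgrid(*axes, indexing="ij")
    shape = grid[0].shape
    idx = np.stack([g.ravel() for g in grid], axis=1)
    world_f = idx * np.asarray(fixed.spacing) + np.asarray(fixed.origin)
    world_m = inv.apply(world_f)
    idx_m = (world_m - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    coords = idx_m.T.reshape((3,) + shape)
    vals = ndimage.map_coordinates(moving.data.astype(np.float64), coords,
                                   order=1, mode="constant", cval=np.nan)
    valid = np.isfinite(vals)
    fvals = fixed.data[tuple(g.astype(np.intp) for g in grid)].astype(np.float64)
    return vals, valid, fvals


def mattes_mi(fixed: Volume, moving: Volume,
              transform: AffineTransform | None = None, bins: int = 32,
              stride: int = 1) -> float:
    """Mattes-style mutual information (nats) over the overlap region.

    The joint histogram uses partial-volume (linear) binning: each sample
    spreads its unit mass over the four neighbouring (fixed, moving) bin
    pairs, which makes the score a smooth function of the transform.
    Intensities are binned between each image's own min/max over the
    overlap, so the score is exactly invariant to monotone linear
    rescaling of either image.
    """
    if bins < 8:
        raise ValueError("bins must be >= 8")
    if transform is None:
        transform = AffineTransform.identity(fixed.center_world())
    vals, valid, fvals = _resample_through(fixed, moving, transform, stride)
    if valid.sum() < bins:
        raise ValueError("empty (or near-empty) overlap region")
    a = fvals.ravel()[valid.ravel()]
    b = vals.ravel()[valid.ravel()]
    return _mi_partial_volume(a, b, bins)


def _mi_partial_volume(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    def bin_coords(v):
        lo, hi = v.min(), v.max()
        span = hi - lo
        if span == 0:
            return np.zeros_like(v)
        return (v - lo) / span * (bins - 1)

    ca, cb = bin_coords(a), bin_coords(b)
    ia = np.minimum(ca.astype(np.int64), bins - 2)
    ib = np.minimum(cb.astype(np.int64), bins - 2)
    fa, fb = ca - ia, cb - ib
    joint = np.zeros((bins, bins), dtype=np.float64)
    flat = joint.ravel()
    for da, wa in ((0, 1 - fa), (1, fa)):
        for db, wb in ((0, 1 - fb), (1, fb)):
            np.add.at(flat, (ia + da) * bins + (ib + db), wa * wb)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sig = (factor - 1) / 2.0
    sm = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sig)
    return Volume(sm[::factor, ::factor, ::factor].astype(np.float32),
                  tuple(s * factor for s in vol.spacing), vol.origin,
                  vol.modality)


def _params_to_transform(p: np.ndarray, center: np.ndarray,
                         affine: bool) -> AffineTransform:
    """p = [t_z, t_y, t_x (mm), rot_z, rot_y, rot_x (deg), (+log-scales, +shears)]."""
    lin = _rotation_zyx(p[3:6])
    if affine:
        scale = np.diag(np.exp(p[6:9]))
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = p[9], p[10], p[11]
        lin = lin @ shear @ scale
    return AffineTransform(lin, p[0:3], center)


def _coordinate_search(score, p: np.ndarray, steps: np.ndarray,
                       min_steps: np.ndarray, active: int,
                       max_rounds: int = 60):
    """Greedy per-parameter pattern search with step halving.

    For each active parameter, tries ±step and keeps walking in the
    improving direction; when a full sweep brings no improvement all steps
    are halved, until every step is below its floor.
    """
    best = score(p)
    if best == -np.inf:
        raise ValueError("empty overlap between volumes at start")
    step = steps.copy()
    for _ in range(max_rounds):
        improved = False
        for i in range(active):
            for sgn in (+1.0, -1.0):
                q = p.copy()
                q[i] += sgn * step[i]
                s = score(q)
                if s > best + 1e-12:
                    best, p = s, q
                    improved = True
                    while True:        # keep walking while it helps
                        q = p.copy()
                        q[i] += sgn * step[i]
                        s = score(q)
                        if s > best + 1e-12:
                            best, p = s, q
                        else:
                            break
                    break
        if not improved:
            if np.all(step <= min_steps):
                break
            step = np.maximum(step / 2.0, min_steps)
    return p, best


def register(fixed: Volume, moving: Volume, bins: int = 32,
             do_affine: bool = True,
             pyramid: tuple[int, ...] = (4, 2, 1)) -> AffineTransform:
    """Rigid-then-affine registration maximising Mattes mutual information.

    A derivative-free coordinate (pattern) search with per-level step
    halving runs coarse-to-fine on a Gaussian pyramid; translations are
    searched before rotations at each level.  Returns the transform mapping
    the moving frame onto the fixed frame.
    """
    center = fixed.center_world()
    p = np.zeros(12)
    # (level factor, MI sample stride at that level)
    levels = [(f, 2 if f == 1 else 1) for f in pyramid]
    vox = float(min(fixed.spacing))

    def solve(p, affine: bool, active: int, rot_scan: bool = False):
        for li, (factor, stride) in enumerate(levels):
            f = _downsample(fixed, factor)
            m = _downsample(moving, factor)
            coarse = li == 0
            t0 = (4.0 if coarse else 1.0) * factor * vox
            r0 = 4.0 if coarse else 1.0
            steps = np.array([t0, t0, t0, r0, r0, r0,
                              0.05, 0.05, 0.05, 0.04, 0.04, 0.04])
            min_steps = np.array([0.04, 0.04, 0.04, 0.05, 0.05, 0.05,
                                  0.002, 0.002, 0.002, 0.002, 0.002, 0.002])
            min_steps[0:3] *= factor * vox

            def score(q):
                try:
                    s = mattes_mi(f, m, _params_to_transform(q, center, affine),
                                  bins, stride=stride)
                except ValueError:
                    return -np.inf
                if not np.isfinite(s):
                    raise RuntimeError("non-finite registration score")
                return s

            if coarse and rot_scan:
                # rough translation first, then a global rotation grid scan:
                # quasi-periodic structures (evenly spaced teeth) put local MI
                # maxima at wrong rotations that a greedy search cannot escape
                p, _ = _coordinate_search(score, p, steps, min_steps, active=3)
                grid = np.arange(-15.0, 15.1, 5.0)
                best_s, best_rot = -np.inf, p[3:6].copy()
                for rz in grid:
                    for ry in grid:
                        for rx in grid:
                            q = p.copy()
                            q[3:6] = (rz, ry, rx)
                            s = score(q)
                            if s > best_s:
                                best_s, best_rot = s, np.array((rz, ry, rx))
                p[3:6] = best_rot
            p, _ = _coordinate_search(score, p, steps, min_steps, active)
        return p

    p = solve(p, affine=False, active=6, rot_scan=True)
    if do_affine:
        p = solve(p, affine=True, active=12)
    return _params_to_transform(p, center, do_affine)


def resample_moving(fixed: Volume, moving: Volume,
                    transform: AffineTransform) -> Volume:
    """Moving volume resampled onto the fixed grid (edge padding)."""
    vals, valid, _ = _resample_through(fixed, moving, transform)
    filled = np.where(valid, vals, 0.0)
    if (~valid).any():
        # edge-value padding: nearest valid sample
        _, idx = ndimage.distance_transform_edt(~valid, return_indices=True)
        filled = filled[tuple(idx)]
    return Volume(filled.astype(np.float32), fixed.spacing, fixed.origin,
                  moving.modality)


def overlap_roi(fixed: Volume, moving: Volume,
                transform: AffineTransform) -> tuple[Cuboid, BinaryMask]:
    """Axis-aligned overlap cuboid of the two fields of view, in the fixed
    frame, and the mask that zeroes everything outside it."""
    nz, ny, nx = moving.shape
    corners = np.array([[z, y, x] for z in (0, nz) for y in (0, ny)
                        for x in (0, nx)], dtype=float)
    world = corners * np.asarray(moving.spacing) + np.asarray(moving.origin)
    mapped = transform.apply(world)
    idx_f = (mapped - np.asarray(fixed.origin)) / np.asarray(fixed.spacing)
    lo_f = np.ceil(np.round(idx_f.min(axis=0), 6)).astype(int)
    hi_f = np.floor(np.round(idx_f.max(axis=0), 6)).astype(int)
    lo = np.maximum(lo_f, 0)
    hi = np.minimum(hi_f, np.asarray(fixed.shape))
    if np.any(lo >= hi):
        raise ValueError("disjoint fields of view: overlap cuboid is empty")
    cub = Cuboid(tuple(int(v) for v in lo), tuple(int(v) for v in hi))
    mask = np.zeros(fixed.shape, dtype=bool)
    mask[cub.slices] = True
    return cub, BinaryMask(mask)


def prepare_pair(cbct: Volume, mdct: Volume, median_radius: int = 2,
                 do_register: bool = True,
                 do_affine: bool = True) -> tuple[Volume, Volume, BinaryMask]:
    """Full preparation of one pair: mask → match/clip → register → overlap.

    Returns (cbct_prepared, mdct_prepared, overlap_mask) on the MDCT grid,
    with the CBCT resampled into the MDCT frame.  Values outside the
    overlap cuboid are left in place; the mask marks the region metrics
    and training should use.
    """
    if mdct.spacing != cbct.spacing:
        mdct = resample(mdct, cbct.spacing)
    fg = mask_background(cbct, median_radius)
    cbct_m, mdct_c = clip_and_match_intensity(cbct, mdct, fg)
    if do_register:
        t = register(mdct_c, cbct_m, do_affine=do_affine)
    else:
        t = AffineTransform.identity(mdct_c.center_world())
    cbct_reg = resample_moving(mdct_c, cbct_m, t)
    cbct_reg = clip_hu(cbct_reg)
    _, mask = overlap_roi(mdct_c, cbct_m, t)
    return cbct_reg, mdct_c, mask
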