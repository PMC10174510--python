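"""Synthetic paired CBCT/MDCT head-and-jaw phantoms.

The clinical data this method targets — paired dental cone-beam CT and
multidetector CT scans of the same patient — cannot be shipped, so this
module generates volume pairs with the statistical structure the method
assumes: a clean, HU-calibrated "MDCT-like" phantom (head ellipsoid, a
mandibular arc of cortical + textured trabecular bone, teeth with
enamel/dentin/pulp layers, some bearing metal restorations) and a degraded
"CBCT-like" counterpart carrying the defect classes seen on real cone-beam
scans: radial streaks around metal, concentric ring modulation about the
rotation axis, Gaussian noise, low-frequency cupping shade, a global
intensity transform off the HU scale, and a small rigid misalignment
emulating the different patient posture of the two scanners.

Streaks are simulated in the image domain (radial sinusoidal fans from the
metal centroids with distance decay) rather than by forward projection:
no physics model is claimed, and desk-scale tests need speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import HU_MAX, HU_MIN, Volume

#: Voxels at or above this HU are treated as metal when placing streaks.
METAL_THRESHOLD = 2500.0


@dataclass(frozen=True)
class JawArc:
    """Geometry of the mandibular arc, in mm relative to the grid centre."""

    center_offset_yx: tuple[float, float] = (2.0, 0.0)
    radius: float = 15.0
    thickness: float = 6.0
    z_extent: tuple[float, float] = (-14.0, 0.0)   # bone band, relative to centre
    tooth_z_extent: tuple[float, float] = (0.0, 12.0)
    span_deg: float = 230.0
    phase_deg: float = 0.0                          # 0 = anterior (+y)


@dataclass(frozen=True)
class TrabecularTexture:
    """Band-passed noise inside trabecular bone."""

    amplitude_hu: float = 150.0
    correlation_mm: float = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_radii: tuple[float, float, float] = (30.0, 27.0, 24.0)
    jaw_arc: JawArc = field(default_factory=JawArc)
    n_teeth: int = 10
    tissue_hu: dict = field(default_factory=lambda: {
        "air": -1000.0, "soft": 40.0, "trabecular": 300.0, "cortical": 1200.0,
        "pulp": 80.0, "dentin": 1600.0, "enamel": 2000.0, "metal": 3000.0,
    })
    metal_indices: tuple[int, ...] = (2, 7)
    trabecular_texture: TrabecularTexture = field(default_factory=TrabecularTexture)
    tooth_radius: float = 2.4
    dentin_radius: float = 1.6
    pulp_radius: float = 0.7
    cortical_shell: float = 1.5

    def validate(self) -> None:
        if any(int(s) < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 8, got {self.grid_shape}")
        for role, hu in self.tissue_hu.items():
            if not (HU_MIN <= hu <= HU_MAX):
                raise ValueError(f"tissue HU for {role!r} out of [{HU_MIN}, {HU_MAX}]: {hu}")
        if self.n_teeth < 0:
            raise ValueError("n_teeth must be >= 0")
        bad = [i for i in self.metal_indices if not (0 <= i < max(self.n_teeth, 1))]
        if self.n_teeth == 0 and self.metal_indices:
            raise ValueError("metal_indices given but n_teeth == 0")
        if bad:
            raise ValueError(f"metal_indices {bad} outside 0..{self.n_teeth - 1}")


@dataclass(frozen=True)
class Misalignment:
    """Rigid perturbation: translations in voxels, rotations in degrees (z, y, x)."""

    translation_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def is_zero(self) -> bool:
        return all(v == 0 for v in self.translation_vox) and \
            all(v == 0 for v in self.rotation_deg)


@dataclass(frozen=True)
class ArtifactParams:
    """Amplitudes of the simulated cone-beam defects (HU unless noted).

    With every amplitude zero, ``intensity_gain = 1``, ``intensity_offset = 0``
    and zero misalignment, degradation is the exact identity.
    """

    streak_amplitude: float = 200.0
    streak_count: int = 12
    ring_amplitude: float = 25.0
    noise_sigma: float = 40.0
    cupping_strength: float = 100.0
    intensity_gain: float = 0.75
    intensity_offset: float = -120.0
    misalignment: Misalignment = field(default_factory=Misalignment)
    seed: int = 0
    streak_decay_mm: float = 20.0
    ring_period_mm: float = 3.0

    def validate(self) -> None:
        for name in ("streak_amplitude", "ring_amplitude", "noise_sigma",
                     "cupping_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.streak_count < 1:
            raise ValueError("streak_count must be >= 1")
        if self.intensity_gain == 0:
            raise ValueError("intensity_gain must be non-zero")


def streak_dominant_params(seed: int = 0) -> ArtifactParams:
    """Artifact condition dominated by in-plane metal streaks: the regime in
    which averaging the three slicing directions helps most, since streaks
    that are hard to separate in the axial plane are readily visible as
    line patterns in the two orthogonal planes."""
    return ArtifactParams(streak_amplitude=300.0, ring_amplitude=15.0,
                          noise_sigma=20.0, cupping_strength=60.0, seed=seed)


def _coords_mm(spec: PhantomSpec):
    """Per-axis coordinates in mm relative to the grid centre."""
    out = []
    for n, s in zip(spec.grid_shape, spec.spacing):
        c = (n - 1) / 2.0 * s
        out.append(np.arange(n, dtype=np.float64) * s - c)
    return out  # z, y, x 1-D arrays


def _tooth_angles(arc: JawArc, n_teeth: int) -> np.ndarray:
    """Tooth centre angles (deg) spread evenly over the arc span."""
    k = np.arange(n_teeth, dtype=np.float64)
    return arc.phase_deg - arc.span_deg / 2 + arc.span_deg * (k + 0.5) / n_teeth


def generate_phantom(spec: PhantomSpec, seed: int) -> Volume:
    """Render a clean MDCT-like phantom; deterministic given (spec, seed)."""
    spec.validate()
    arc = spec.jaw_arc
    half_extent = [(n - 1) / 2.0 * s for n, s in zip(spec.grid_shape, spec.spacing)]
    reach = arc.radius + spec.tooth_radius + max(abs(c) for c in arc.center_offset_yx)
    if spec.n_teeth > 0 and reach > min(half_extent[1], half_extent[2]):
        raise ValueError(
            f"grid too small to contain jaw arc: needs {reach:.1f} mm in-plane, "
            f"grid half-extent is {min(half_extent[1], half_extent[2]):.1f} mm")

    hu = spec.tissue_hu
    z, y, x = _coords_mm(spec)
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]

    data = np.full(spec.grid_shape, hu["air"], dtype=np.float64)

    rz, ry, rx = spec.head_radii
    head = (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0
    data[head] = hu["soft"]

    # mandibular arc
    cy, cx = arc.center_offset_yx
    r_ax = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)             # (1, ny, nx)
    ang = np.degrees(np.arctan2(xx - cx, yy - cy))               # 0 deg = +y
    dphase = (ang - arc.phase_deg + 180.0) % 360.0 - 180.0
    in_arc = np.abs(dphase) <= arc.span_deg / 2
    zband = (zz >= arc.z_extent[0]) & (zz <= arc.z_extent[1])
    ring = np.abs(r_ax - arc.radius) <= arc.thickness / 2
    bone = head & zband & ring & in_arc
    data[bone] = hu["cortical"]
    core_half = arc.thickness / 2 - spec.cortical_shell
    core = head & zband & in_arc & (np.abs(r_ax - arc.radius) <= max(core_half, 0.0))
    rng = np.random.default_rng(seed)
    if np.any(core):
        tex = spec.trabecular_texture
        noise = rng.standard_normal(spec.grid_shape)
        sig = [max(tex.correlation_mm / s, 1e-6) for s in spec.spacing]
        noise = ndimage.gaussian_filter(noise, sigma=sig)
        sd = noise.std()
        if sd > 0 and tex.amplitude_hu > 0:
            noise = noise / sd * tex.amplitude_hu
            data[core] = hu["trabecular"] + noise[core]
        else:
            data[core] = hu["trabecular"]

    # teeth: concentric enamel/dentin/pulp cylinders along the arc
    if spec.n_teeth > 0:
        t_lo, t_hi = arc.tooth_z_extent
        tband = (zz >= t_lo) & (zz <= t_hi)
        for i, ang_i in enumerate(_tooth_angles(arc, spec.n_teeth)):
            ty = cy + arc.radius * math.cos(math.radians(ang_i))
            tx = cx + arc.radius * math.sin(math.radians(ang_i))
            d = np.sqrt((yy - ty) ** 2 + (xx - tx) ** 2)
            cyl = tband & (d <= spec.tooth_radius)
            if i in spec.metal_indices:
                data[cyl] = hu["metal"]
                continue
            data[cyl] = hu["enamel"]
            data[cyl & (d <= spec.dentin_radius)] = hu["dentin"]
            data[cyl & (d <= spec.pulp_radius)] = hu["pulp"]

    np.clip(data, HU_MIN, HU_MAX, out=data)
    return Volume(data=data.astype(np.float32), spacing=spec.spacing,
                  modality="mdct")


def _rigid_matrix(rotation_deg) -> np.ndarray:
    """Rotation matrix in (z, y, x) index order: R = Rz @ Ry @ Rx."""
    az, ay, ax = (math.radians(a) for a in rotation_deg)
    cz, sz_ = math.cos(az), math.sin(az)
    cy, sy = math.cos(ay), math.sin(ay)
    cx, sx = math.cos(ax), math.sin(ax)
    # rotation about the z axis mixes (y, x); about y mixes (z, x); about x mixes (z, y)
    Rz = np.array([[1, 0, 0], [0, cz, -sz_], [0, sz_, cz]])
    Ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    Rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_misalignment(data: np.ndarray, mis: Misalignment) -> np.ndarray:
    """Resample through the rigid perturbation (trilinear, edge padding)."""
    if mis.is_zero():
        return data.copy()
    R = _rigid_matrix(mis.rotation_deg)
    c = (np.asarray(data.shape, dtype=float) - 1) / 2.0
    t = np.asarray(mis.translation_vox, dtype=float)
    offset = c + t - R @ c
    return ndimage.affine_transform(data.astype(np.float64), R, offset=offset,
                                    order=1, mode="nearest")


def degrade_to_cbct(vol: Volume, params: ArtifactParams) -> Volume:
    """Apply the cone-beam defect stack to a clean volume.

    Order: streaks around metal → ring modulation → Gaussian noise →
    cupping shade → global intensity transform → rigid misalignment.
    RNG streams are split per artifact type so that toggling one artifact
    leaves the realisations of the others unchanged.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    streak_rng, ring_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    data = vol.data.astype(np.float64)
    nz, ny, nx = data.shape
    z, y, x = (np.arange(n, dtype=np.float64) * s - (n - 1) / 2.0 * s
               for n, s in zip(data.shape, vol.spacing))
    yy, xx = np.meshgrid(y, x, indexing="ij")

    if params.streak_amplitude > 0:
        metal = vol.data >= METAL_THRESHOLD
        for k in range(nz):
            if not metal[k].any():
                continue
            labels, n_lab = ndimage.label(metal[k])
            for c0, c1 in ndimage.center_of_mass(metal[k], labels,
                                                 range(1, n_lab + 1)):
                my = y[0] + c0 * vol.spacing[1]
                mx = x[0] + c1 * vol.spacing[2]
                theta = np.arctan2(xx - mx, yy - my)
                r = np.hypot(yy - my, xx - mx)
                phase = streak_rng.uniform(0, 2 * np.pi)
                fan = np.cos(params.streak_count * theta + phase)
                data[k] += params.streak_amplitude * fan * \
                    np.exp(-r / params.streak_decay_mm)

    r_ax = np.hypot(yy, xx)
    if params.ring_amplitude > 0:
        phase = ring_rng.uniform(0, 2 * np.pi)
        rings = params.ring_amplitude * np.cos(
            2 * np.pi * r_ax / params.ring_period_mm + phase)
        data += rings[None, :, :]

    if params.noise_sigma > 0:
        data += noise_rng.normal(0.0, params.noise_sigma, size=data.shape)

    if params.cupping_strength > 0:
        rmax = r_ax.max()
        shade = -params.cupping_strength * (1.0 - (r_ax / rmax) ** 2)
        data += shade[None, :, :]

    data = params.intensity_gain * data + params.intensity_offset
    data = apply_misalignment(data, params.misalignment)
    return Volume(data=data.astype(np.float32), spacing=vol.spacing,
                  origin=vol.origin, modality="cbct")


def make_dataset(n: int, spec: PhantomSpec, params: ArtifactParams,
                 seed: int) -> list[tuple[Volume, Volume]]:
    """Generate ``n`` (cbct, mdct) pairs, each with a randomised axial head
    pose and independent artifact realisations; reproducible from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = []
    for child in np.random.SeedSequence(seed).spawn(n):
        pose_rng = np.random.default_rng(child)
        pose = float(pose_rng.uniform(0.0, 360.0))
        s_phantom, s_artifacts = (int(v) for v in child.generate_state(2) >> 1)
        spec_i = replace(spec, jaw_arc=replace(spec.jaw_arc,
                                               phase_deg=spec.jaw_arc.phase_deg + pose))
        mdct = generate_phantom(spec_i, seed=s_phantom)
        cbct = degrade_to_cbct(mdct, replace(params, seed=s_artifacts))
        pairs.append((cbct, mdct))
    return pairs
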