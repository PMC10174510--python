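"""Preparation pipeline tests: masking, intensity, resampling, MI,
registration, overlap ROI."""

import math

import numpy as np
import pytest

from compunet import (AffineTransform, Misalignment, PhantomSpec, Volume,
                      clip_and_match_intensity, fit_intensity_map,
                      generate_phantom, mask_background, mattes_mi,
                      overlap_roi, prepare_pair, register, resample,
                      resample_moving)
from compunet.phantom import apply_misalignment
from compunet.prep import _rotation_zyx


def rotation_error_deg(R_rec, R_true):
    dR = R_rec @ R_true.T
    return math.degrees(math.acos(min(1.0, max(-1.0, (np.trace(dR) - 1) / 2))))


# ---------------------------------------------------------------------------
# masking


def test_mask_sphere_fraction():
    n = 48
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    r = 16.0
    sphere = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r ** 2
    vol = Volume(np.where(sphere, 500.0, -1000.0))
    mask = mask_background(vol, median_radius=1)
    expected = (4 / 3) * np.pi * r ** 3 / n ** 3
    assert abs(mask.fraction - expected) / expected < 0.10


def test_mask_constant_volume_raises():
    with pytest.raises(ValueError, match="[Oo]tsu|constant"):
        mask_background(Volume(np.zeros((16, 16, 16))))


def test_mask_covers_head(phantom):
    mask = mask_background(phantom)
    above = phantom.data > -200
    assert (mask.data & above).sum() / above.sum() >= 0.99
    assert 0 < mask.fraction < 1


# ---------------------------------------------------------------------------
# intensity


def test_intensity_identity_map(phantom):
    mask = mask_background(phantom)
    slope, icpt = fit_intensity_map(phantom, phantom, mask)
    assert abs(slope - 1.0) < 0.01
    assert abs(icpt) < 1.0


def test_intensity_recovers_known_affine(phantom):
    mask = mask_background(phantom)
    cbct = phantom.with_data(0.5 * phantom.data.astype(np.float64) - 100.0,
                             modality="cbct")
    slope, icpt = fit_intensity_map(cbct, phantom, mask)
    assert abs(slope - 2.0) / 2.0 < 0.01
    assert abs(icpt - 200.0) / 200.0 < 0.01


def test_clip_and_match_output_in_window(phantom):
    mask = mask_background(phantom)
    wild = phantom.with_data(np.clip(3.0 * phantom.data.astype(np.float64)
                                     + 2000.0, -32768, 32767), "cbct")
    cb, md = clip_and_match_intensity(wild, phantom, mask)
    for v in (cb, md):
        assert v.data.min() >= -1200
        assert v.data.max() <= 3071


def test_clip_and_match_idempotent(phantom):
    mask = mask_background(phantom)
    cbct = phantom.with_data(0.8 * phantom.data.astype(np.float64) - 50.0,
                             "cbct")
    once, _ = clip_and_match_intensity(cbct, phantom, mask)
    twice, _ = clip_and_match_intensity(once, phantom, mask)
    assert np.abs(twice.data.astype(np.float64)
                  - once.data).max() < 1e-2


def test_intensity_errors(phantom):
    from compunet.prep import BinaryMask
    empty = BinaryMask(np.zeros(phantom.shape, dtype=bool))
    with pytest.raises(ValueError, match="empty"):
        fit_intensity_map(phantom, phantom, empty)
    flat = phantom.with_data(np.zeros(phantom.shape))
    full = BinaryMask(np.ones(phantom.shape, dtype=bool))
    with pytest.raises(ValueError, match="variance"):
        fit_intensity_map(flat, phantom, full)


# ---------------------------------------------------------------------------
# resampling


def test_resample_identity(phantom):
    out = resample(phantom, phantom.spacing)
    assert np.array_equal(out.data, phantom.data)


def test_resample_shape_arithmetic(phantom):
    out = resample(phantom, tuple(2 * s for s in phantom.spacing))
    assert out.shape == tuple(round(n / 2) for n in phantom.shape)
    assert out.spacing == tuple(2 * s for s in phantom.spacing)


def test_resample_constant_stays_constant():
    vol = Volume(np.full((16, 16, 16), 123.0), spacing=(1.0, 1.0, 1.0))
    out = resample(vol, (0.7, 1.3, 0.4))
    assert np.allclose(out.data, 123.0)


# ---------------------------------------------------------------------------
# mutual information


def test_mi_self_similarity_peak(phantom):
    ident = AffineTransform.identity(phantom.center_world())
    shift = AffineTransform(np.eye(3), [5.0, 0.0, 0.0],
                            phantom.center_world())
    assert mattes_mi(phantom, phantom, ident) >= \
        mattes_mi(phantom, phantom, shift)


def test_mi_independent_noise_is_low():
    rng = np.random.default_rng(0)
    a = Volume(rng.uniform(0, 1, (64, 64, 64)))
    b = Volume(rng.uniform(0, 1, (64, 64, 64)))
    assert mattes_mi(a, b, bins=32) < 0.05


def test_mi_invariant_to_monotone_rescale(phantom):
    rescaled = phantom.with_data(
        np.clip(2.0 * phantom.data.astype(np.float64) + 10.0, -1e6, 1e6))
    a = mattes_mi(phantom, phantom)
    b = mattes_mi(phantom, rescaled)
    assert abs(a - b) < 1e-6


def test_mi_symmetry_under_swap(phantom):
    """MI(f, m, T) equals MI(m, f, T^-1) up to histogram/edge effects.
    An integer translation keeps resampling exact on both sides."""
    mis = Misalignment(translation_vox=(4.0, -3.0, 2.0))
    moved = phantom.with_data(
        apply_misalignment(phantom.data.astype(np.float64), mis))
    t = AffineTransform(np.eye(3), [4.0, -3.0, 2.0], phantom.center_world())
    fwd = mattes_mi(phantom, moved, t)
    rev = mattes_mi(moved, phantom, t.inverse())
    assert abs(fwd - rev) < 0.05


def test_mi_errors(phantom):
    with pytest.raises(ValueError, match="bins"):
        mattes_mi(phantom, phantom, bins=4)
    far = AffineTransform(np.eye(3), [1000.0, 0.0, 0.0],
                          phantom.center_world())
    with pytest.raises(ValueError, match="overlap"):
        mattes_mi(phantom, phantom, far)


# ---------------------------------------------------------------------------
# transforms


def test_affine_inverse_and_compose():
    rng = np.random.default_rng(1)
    t = AffineTransform.rigid((10.0, -5.0, 3.0), (2.0, 1.0, -4.0),
                              (5.0, 5.0, 5.0))
    pts = rng.normal(size=(20, 3)) * 10
    assert np.allclose(t.inverse().apply(t.apply(pts)), pts)
    t2 = AffineTransform.rigid((0.0, 2.0, 0.0), (1.0, 0.0, 0.0),
                               (1.0, 2.0, 3.0))
    comp = t.compose(t2)
    assert np.allclose(comp.apply(pts), t.apply(t2.apply(pts)))
    m = t.as_matrix()
    hom = np.c_[pts, np.ones(len(pts))] @ m.T
    assert np.allclose(hom[:, :3], t.apply(pts))


def test_transform_text_serialisation_round_trip(tmp_path):
    t = AffineTransform.rigid((10.0, -5.0, 3.0), (2.0, 1.0, -4.0),
                              (31.5, 31.5, 31.5))
    path = tmp_path / "transform.txt"
    t.save(path)
    back = AffineTransform.load(path)
    pts = np.random.default_rng(0).normal(size=(10, 3)) * 20
    assert np.allclose(back.apply(pts), t.apply(pts), atol=1e-12)


def test_rigid_linear_part_is_orthonormal():
    t = AffineTransform.rigid((7.0, -3.0, 12.0), (0, 0, 0), (0, 0, 0))
    assert np.allclose(t.linear @ t.linear.T, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(t.linear), 1.0)


# ---------------------------------------------------------------------------
# registration


def test_register_identity_recovery(phantom):
    t = register(phantom, phantom, do_affine=False)
    assert np.abs(t.translation).max() <= 0.1
    assert rotation_error_deg(t.linear, np.eye(3)) <= 0.1


def test_register_recovers_translation(phantom):
    mis = Misalignment(translation_vox=(4.0, -3.0, 2.0))
    moved = phantom.with_data(
        apply_misalignment(phantom.data.astype(np.float64), mis))
    t = register(phantom, moved, do_affine=False)
    assert np.abs(t.translation - np.array([4.0, -3.0, 2.0])).max() <= 0.5


def test_register_recovers_rotation_and_shift(phantom):
    mis = Misalignment(translation_vox=(2.0, 1.0, 0.0),
                       rotation_deg=(5.0, 0.0, 0.0))
    moved = phantom.with_data(
        apply_misalignment(phantom.data.astype(np.float64), mis))
    t = register(phantom, moved, do_affine=False)
    assert np.abs(t.translation - np.array([2.0, 1.0, 0.0])).max() <= 0.5
    assert rotation_error_deg(t.linear, _rotation_zyx((5.0, 0.0, 0.0))) <= 1.0


# ---------------------------------------------------------------------------
# overlap ROI


def test_overlap_identity_full_grid(phantom):
    cub, mask = overlap_roi(phantom, phantom,
                            AffineTransform.identity(phantom.center_world()))
    assert cub.lo == (0, 0, 0)
    assert cub.hi == phantom.shape
    assert mask.data.all()


def test_overlap_shift_reduces_extent(phantom):
    t = AffineTransform(np.eye(3), [10.0, 0.0, 0.0],
                        phantom.center_world())
    cub, mask = overlap_roi(phantom, phantom, t)
    assert cub.extent[0] == phantom.shape[0] - 10
    assert cub.extent[1:] == phantom.shape[1:]
    assert mask.data.sum() == np.prod(cub.extent)


def test_overlap_disjoint_raises(phantom):
    t = AffineTransform(np.eye(3), [1000.0, 0.0, 0.0],
                        phantom.center_world())
    with pytest.raises(ValueError, match="disjoint"):
        overlap_roi(phantom, phantom, t)


# ---------------------------------------------------------------------------
# full preparation


def test_prepare_pair_conserves_window(phantom, zero_artifacts):
    import dataclasses

    from compunet import degrade_to_cbct
    params = dataclasses.replace(zero_artifacts, noise_sigma=30.0,
                                 intensity_gain=0.8,
                                 intensity_offset=-100.0)
    cbct = degrade_to_cbct(phantom, params)
    cb, md, mask = prepare_pair(cbct, phantom, do_register=False)
    for v in (cb, md):
        assert v.data.min() >= -1200
        assert v.data.max() <= 3071
    assert mask.data.any()


# ---------------------------------------------------------------------------
# independent oracle: SimpleITK


def test_resampling_matches_simpleitk(phantom):
    """Cross-check our affine resampling against SimpleITK on a rigid map."""
    sitk = pytest.importorskip("SimpleITK")
    t = AffineTransform.rigid((4.0, 0.0, 0.0), (2.0, -1.0, 0.5),
                              phantom.center_world())
    ours = resample_moving(phantom, phantom, t)

    img = sitk.GetImageFromArray(phantom.data)  # sitk indexes (x,y,z)
    img.SetSpacing(phantom.spacing[::-1])
    tx = sitk.AffineTransform(3)
    # sitk applies the *inverse* map to output points; it works in (x,y,z)
    inv = t.inverse()
    tx.SetMatrix(inv.linear[::-1, ::-1].ravel())
    tx.SetCenter(inv.center[::-1])
    tx.SetTranslation(inv.translation[::-1])
    ref = sitk.Resample(img, img, tx, sitk.sitkLinear, 0.0)
    theirs = sitk.GetArrayFromImage(ref)
    interior = (slice(8, -8),) * 3
    assert np.allclose(ours.data[interior], theirs[interior], atol=2.0)
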