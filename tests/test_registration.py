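"""DIR engine: identity, rigid-shift recovery against simulator ground
truth, median wrapper vs a brute-force oracle, warping, guidance."""

from dataclasses import replace

import numpy as np
import pytest

from subfrax.grid import DisplacementField, ScalarImage, VoxelGrid
from subfrax.motion import MotionSample
from subfrax.phantom import deform_anatomy
from subfrax.planning import expand_margin, make_ring
from subfrax.protocol import TIGHT_MARGINS
from subfrax.registration import (
    GuidanceContours,
    RegistrationSettings,
    estimate_ctv_shift,
    median_field,
    median_of_repeats,
    register,
    register_contour_guided,
    warp_image,
)

SETTINGS = RegistrationSettings()


def test_identity_registration_is_near_zero(default_phantom):
    img, _ = default_phantom
    field = register(img, img, SETTINGS)
    assert field.magnitude().max() < 0.1


def test_known_ap_shift_recovered(default_phantom):
    """A 3 mm AP rigid prostate shift is recovered within 0.3 mm over the CTV."""
    img, lab = default_phantom
    moved, _ = deform_anatomy(img, lab, MotionSample((0, 3.0, 0), "MR1_MR2"))
    field = register(img, moved, SETTINGS)
    est = estimate_ctv_shift(field, lab["ctv"])
    assert np.linalg.norm(est - np.array([0, 3.0, 0])) < 0.3


def test_composite_shift_recovered(default_phantom):
    """Two successive shifts a then b are recovered as a+b within 0.5 mm."""
    img, lab = default_phantom
    a = np.array([1.0, -1.5, 0.5])
    b = np.array([-0.5, 1.0, 2.0])
    moved, _ = deform_anatomy(img, lab, MotionSample(a + b, "MR1_MR2"))
    field = register(img, moved, SETTINGS)
    est = estimate_ctv_shift(field, lab["ctv"])
    assert np.linalg.norm(est - (a + b)) < 0.5


def test_mismatched_grids_rejected(default_phantom):
    img, _ = default_phantom
    other = ScalarImage(
        VoxelGrid(img.grid.shape, (2.0, 2.0, 2.0)), img.data.copy()
    )
    with pytest.raises(ValueError):
        register(img, other, SETTINGS)


def test_estimate_ctv_shift_against_loop_oracle(rng):
    grid = VoxelGrid((12, 12, 12), (1, 1, 1))
    vec = rng.standard_normal(tuple(grid.shape) + (3,))
    field = DisplacementField(grid, vec)
    mask = rng.random(grid.shape) < 0.3
    est = estimate_ctv_shift(field, mask)
    # brute-force loop average
    acc = np.zeros(3)
    n = 0
    for i in range(12):
        for j in range(12):
            for k in range(12):
                if mask[i, j, k]:
                    acc += vec[i, j, k]
                    n += 1
    assert np.allclose(est, acc / n, atol=1e-9)
    assert np.allclose(
        np.linalg.norm(estimate_ctv_shift(DisplacementField.zero(grid), mask)), 0.0
    )
    with pytest.raises(ValueError):
        estimate_ctv_shift(field, np.zeros(grid.shape, bool))


def test_uniform_field_shift_magnitude():
    grid = VoxelGrid((10, 10, 10), (1, 1, 1))
    field = DisplacementField.uniform(grid, (1.0, 2.0, 2.0))
    mask = np.ones(grid.shape, bool)
    est = estimate_ctv_shift(field, mask)
    assert np.allclose(est, [1, 2, 2])
    assert np.linalg.norm(est) == pytest.approx(3.0)


def test_warp_image_zero_field_and_ramp():
    grid = VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0))
    z = np.arange(16, dtype=float) * 2.0
    ramp = np.broadcast_to(z, (16, 16, 16)).copy()
    img = ScalarImage(grid, ramp)
    assert np.array_equal(warp_image(img, DisplacementField.zero(grid)).data, ramp)
    # +4 mm SI displacement on an SI ramp: out(x) = ramp(x + 4 mm) = ramp + 4
    field = DisplacementField.uniform(grid, (0, 0, 4.0))
    out = warp_image(img, field).data
    assert np.allclose(out[:, :, :-2], ramp[:, :, :-2] + 4.0)
    # interpolation convexity: output range within input range
    assert out.min() >= ramp.min() - 1e-12 and out.max() <= ramp.max() + 1e-12


def test_median_field_equals_sort_oracle(rng):
    grid = VoxelGrid((8, 8, 8), (1, 1, 1))
    stacks = rng.standard_normal((5,) + tuple(grid.shape) + (3,))
    fields = [DisplacementField(grid, s) for s in stacks]
    med = median_field(fields)
    oracle = np.sort(stacks, axis=0)[2]  # explicit sort-based median of 5
    assert np.array_equal(med.vectors, oracle)


def test_median_of_repeats_identical_fields_exact():
    grid = VoxelGrid((8, 8, 8), (1, 1, 1))
    const = DisplacementField.uniform(grid, (0.5, -1.0, 2.0))
    out = median_of_repeats(lambda init: const, grid, SETTINGS, n_repeats=7)
    assert np.array_equal(out.vectors, const.vectors)


def test_default_repeat_count_is_30():
    assert RegistrationSettings().n_repeats == 30


def test_regularization_monotonically_smooths(smoke_phantom):
    """Field roughness is non-increasing over a 3-point regularization sweep."""
    img, lab = smoke_phantom
    moved, _ = deform_anatomy(img, lab, MotionSample((1.0, 2.0, -1.0), "MR1_MR2"))
    rough = []
    for reg in (0.8, 1.6, 3.2):
        s = replace(SETTINGS, regularization_mm=reg, max_iterations=40)
        f = register(img, moved, s)
        g = np.gradient(f.vectors, *img.grid.spacing, axis=(0, 1, 2))
        rough.append(float(np.mean([np.abs(x).mean() for x in g])))
    assert rough[0] >= rough[1] >= rough[2]


def _guidance(lab_fixed, lab_moving, grid):
    ptv = expand_margin(lab_fixed["ctv"], grid, TIGHT_MARGINS)
    ring = make_ring(ptv, grid)
    names = ("bladder", "prostate", "rectum")
    return GuidanceContours(
        {s: lab_fixed[s] for s in names}, {s: lab_moving[s] for s in names}, ring
    )


def test_guided_identity_near_zero(smoke_phantom):
    img, lab = smoke_phantom
    field = register_contour_guided(img, img, _guidance(lab, lab, img.grid), SETTINGS)
    assert field.magnitude().max() < 0.1


def test_guidance_weight_zero_equals_unguided(smoke_phantom):
    img, lab = smoke_phantom
    moved, lab2 = deform_anatomy(
        img, lab, MotionSample((0, -1, 1), "interfraction", bladder_amplitude_mm=2.0)
    )
    s = replace(SETTINGS, guidance_weight=0.0, max_iterations=40)
    guided = register_contour_guided(img, moved, _guidance(lab, lab2, img.grid), s)
    plain = register(img, moved, s)
    assert np.allclose(guided.vectors, plain.vectors)


def test_empty_ring_falls_back_to_unguided(smoke_phantom):
    img, lab = smoke_phantom
    s = replace(SETTINGS, max_iterations=20)
    gc = _guidance(lab, lab, img.grid)
    gc.ring = np.zeros(img.grid.shape, bool)
    guided = register_contour_guided(img, img, gc, s)
    plain = register(img, img, s)
    assert np.allclose(guided.vectors, plain.vectors)


def test_guidance_rescues_bladder_alignment_under_volume_change(default_phantom):
    """When a large bladder volume change comes with vanishing bladder
    contrast, contour guidance strictly improves the in-ring bladder Dice."""
    img, lab = default_phantom
    grid = img.grid
    m = MotionSample((0.5, -1.5, 2.0), "interfraction", bladder_amplitude_mm=6.0)
    moved, lab2 = deform_anatomy(img, lab, m)
    moved.data[lab2["bladder"]] = 128.0  # near-isointense: contrast gone
    gc = _guidance(lab, lab2, grid)

    def ring_dice(field):
        wm = warp_image(ScalarImage(grid, lab2["bladder"].astype(float)), field).data > 0.5
        inter = wm & lab["bladder"] & gc.ring
        return 2 * inter.sum() / ((wm & gc.ring).sum() + (lab["bladder"] & gc.ring).sum())

    plain = register(img, moved, SETTINGS)
    guided = register_contour_guided(img, moved, gc, SETTINGS)
    assert ring_dice(guided) > ring_dice(plain)


def test_ctv_shift_agrees_with_independent_demons_implementation(smoke_phantom):
    """Cross-check: an independent variational registration (SimpleITK's
    symmetric-forces demons) recovers the same CTV shift as this engine on
    a known rigid-shift phantom pair."""
    sitk = pytest.importorskip("SimpleITK")
    img, lab = smoke_phantom
    truth = np.array([0.5, 1.5, -1.0])
    moved, _ = deform_anatomy(img, lab, MotionSample(truth, "MR1_MR2"))

    def to_sitk(a, spacing):
        im = sitk.GetImageFromArray(np.ascontiguousarray(a.T))
        im.SetSpacing(tuple(float(s) for s in spacing))
        return im

    fixed = sitk.SmoothingRecursiveGaussian(to_sitk(img.data, img.grid.spacing), 1.0)
    moving = sitk.SmoothingRecursiveGaussian(to_sitk(moved.data, img.grid.spacing), 1.0)
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(100)
    demons.SetStandardDeviations(1.5)
    dfield = demons.Execute(fixed, moving)
    vec = np.transpose(sitk.GetArrayFromImage(dfield), (2, 1, 0, 3))
    est_sitk = vec[lab["ctv"]].mean(axis=0)

    est_ours = estimate_ctv_shift(register(img, moved, SETTINGS), lab["ctv"])
    assert np.linalg.norm(est_ours - truth) < 0.5
    assert np.linalg.norm(est_sitk - truth) < 0.5
    assert np.linalg.norm(est_ours - est_sitk) < 0.5
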