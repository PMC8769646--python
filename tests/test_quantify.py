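"""ROI measurements: oracle equivalence, invariances, closed forms."""

import math
from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from phagotrace import (ImageStack, acidification_index, annotation_from_scene,
                        box_intensity, disc_diameter_timecourse,
                        luminal_relative_intensity, measure_disc_diameter,
                        nuclear_diameter_ratio, preset_genotype, render_stack,
                        simulate_scene, surface_relative_intensity)
from phagotrace.quantify import RoiAnnotation, TimeCourse, rasterize_polygon
from phagotrace.render import Optics, default_channels

from conftest import make_spot_scene


def as_stack(arr):
    """Wrap a (T, C, Y, X) array with unit metadata."""
    return ImageStack(np.asarray(arr, dtype=float),
                      [f"ch{i}" for i in range(arr.shape[1])],
                      pixel_size=0.1, frame_interval=2.0)


# --- box sums -------------------------------------------------------


def test_box_intensity_constant_image():
    stack = as_stack(np.full((1, 1, 32, 32), 5.0))
    assert box_intensity(stack, 0, 0, (16, 16), 4) == 80.0
    assert box_intensity(stack, 0, 0, (16, 16), 3) == 45.0


def test_box_intensity_zero_image():
    stack = as_stack(np.zeros((1, 1, 16, 16)))
    assert box_intensity(stack, 0, 0, (8, 8), 4) == 0.0


@pytest.mark.parametrize("box_side", [1, 2, 3, 4, 5])
def test_box_intensity_equals_loop_oracle(box_side):
    rng = np.random.default_rng(0)
    img = rng.integers(0, 1000, size=(24, 24)).astype(float)
    stack = as_stack(img[None, None])
    for _ in range(20):
        cy, cx = rng.integers(6, 18, size=2)
        off = (box_side - 1) // 2
        brute = sum(img[cy - off + i, cx - off + j]
                    for i in range(box_side) for j in range(box_side))
        assert box_intensity(stack, 0, 0, (cy, cx), box_side) == brute


def test_box_out_of_bounds_raises():
    stack = as_stack(np.zeros((1, 1, 16, 16)))
    with pytest.raises(ValueError, match="out of bounds"):
        box_intensity(stack, 0, 0, (0, 8), 4)
    with pytest.raises(ValueError, match="out of bounds"):
        box_intensity(stack, 0, 0, (15, 15), 4)


# --- polygon rasterization -----------------------------------------


def test_rasterization_matches_shapely_point_in_polygon_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        pts = rng.uniform(2, 30, size=(8, 2))
        hull = Polygon(pts[:, ::-1]).convex_hull  # shapely wants (x, y)
        verts = np.array(hull.exterior.coords[:-1])[:, ::-1]  # back to (y, x)
        mask = rasterize_polygon(verts, (32, 32))
        oracle = np.zeros((32, 32), dtype=bool)
        for y in range(32):
            for x in range(32):
                oracle[y, x] = hull.contains(Point(x, y))
        assert np.array_equal(mask, oracle)


# --- relative intensity formulas -----------------------------------


def test_luminal_rint_arithmetic():
    """(500-50)/(200-50) = 3.0 on a hand-built two-frame stack."""
    img = np.zeros((2, 1, 32, 32))
    img[0, 0, 14:18, 14:18] = 200 / 16
    img[1, 0, 14:18, 14:18] = 500 / 16
    img[:, 0, 0:8, 0:8] = 50 / 16
    stack = as_stack(img)
    ann = RoiAnnotation(np.array([[15.0, 15.0]] * 2),
                        [np.zeros((3, 2))] * 2, [np.zeros((3, 2))] * 2,
                        background_box=(0, 0, 8, 8))
    tc = luminal_relative_intensity(stack, 0, ann, box_side=4)
    assert tc.values[0] == pytest.approx(1.0)
    assert tc.values[1] == pytest.approx(3.0)


def test_constant_stack_gives_unit_rint_everywhere(wt_annotation):
    img = np.full((5, 1, 128, 128), 7.0)
    stack = as_stack(img)
    ann = RoiAnnotation(wt_annotation.center_track[:5],
                        wt_annotation.inner_polygons[:5],
                        wt_annotation.outer_polygons[:5],
                        wt_annotation.background_box)
    with pytest.raises(ValueError):  # center - background == 0 at T0
        luminal_relative_intensity(stack, 0, ann)
    # the donut formula divides out the constant: undefined anchor too
    with pytest.raises(ValueError):
        surface_relative_intensity(stack, 0, ann)


def test_luminal_rint_tracks_ground_truth_lumen_label(wt_scene, wt_stack,
                                                      wt_annotation):
    """Noise-free wild type: RInt rises monotonically after the first
    fusion and stays 1 before it."""
    tc = luminal_relative_intensity(wt_stack, 0, wt_annotation)
    lumen = np.array([f.lumen_label["lgg"] for f in wt_scene.frames])
    first = int(np.argmax(lumen > 0))
    assert np.allclose(tc.values[:first], 1.0, atol=1e-6)
    shrink_started = np.array([f.phagosome_radius for f in wt_scene.frames]) < 19.9
    # before shrinkage confounds geometry, RInt and lumen label rise together
    grow = slice(first, int(np.argmax(shrink_started)) or len(tc))
    assert np.all(np.diff(tc.values[grow]) > -1e-9)
    assert tc.values[len(tc) - 1] > 3.0


def test_surface_rint_unit_intensity_formula():
    """(1000-400)/(100-60) = 15 via explicit rectangle polygons."""
    img = np.zeros((1, 1, 32, 32))
    # outer 10x10 pixel block [5,15) x [5,15); inner 60 px sub-block
    outer = np.array([[4.5, 4.5], [4.5, 14.5], [14.5, 14.5], [14.5, 4.5]])
    inner = np.array([[4.5, 4.5], [4.5, 10.5], [14.5, 10.5], [14.5, 4.5]])
    img[0, 0, 5:15, 5:15] = 15.0      # donut pixels at 15 each
    img[0, 0, 5:15, 5:11] = 400 / 60  # inner 6x10 block sums to 400
    # outer sum = 400 + 40*15 = 1000, inner = 400, areas 100 vs 60
    stack = as_stack(img)
    ann = RoiAnnotation(np.array([[10.0, 10.0]]), [inner], [outer],
                        background_box=(24, 24, 8, 8))
    tc = surface_relative_intensity(stack, 0, ann)
    # background is zero, so the anchor IS the unit intensity
    assert tc.anchor_value == pytest.approx((1000 - 400) / (100 - 60))


def test_surface_rint_flat_for_recruitment_defective(noise_free, lgg_channel):
    scene = simulate_scene(preset_genotype("ced1_like"), 11)
    stack = render_stack(scene, lgg_channel, noise_free, seed=3)
    ann = annotation_from_scene(scene)
    tc = surface_relative_intensity(stack, 0, ann)
    assert np.all((tc.values > 0.9) & (tc.values < 1.1))


def test_surface_rint_rises_with_rim_label(wt_scene, wt_stack, wt_annotation):
    tc = surface_relative_intensity(wt_stack, 0, wt_annotation)
    rim = np.array([f.rim_label["lgg"] for f in wt_scene.frames])
    first = int(np.argmax(rim > 0))
    assert tc.values[min(first + 15, len(tc) - 1)] > 2.0


# --- acidification index -------------------------------------------


def test_aidx_gfp_halves():
    img = np.ones((2, 2, 16, 16))
    img[1, 0] *= 0.5  # GFP channel halves, mCherry constant
    stack = as_stack(img)
    ann = RoiAnnotation(np.array([[8.0, 8.0]] * 2), [np.zeros((3, 2))] * 2,
                        [np.zeros((3, 2))] * 2, (0, 0, 3, 3))
    tc = acidification_index(stack, 0, 1, ann)
    assert tc.values[1] == pytest.approx(0.5)


def test_aidx_flat_for_acidification_defective(noise_free, nucleus_channels):
    scene = simulate_scene(preset_genotype("cup5_like"), 2)
    stack = render_stack(scene, nucleus_channels, noise_free, seed=2)
    ann = annotation_from_scene(scene)
    tc = acidification_index(stack, 0, 1, ann)
    assert np.allclose(tc.values, 1.0, atol=1e-9)


def test_aidx_matches_titration_closed_form(noise_free, nucleus_channels):
    """pH 7.2 -> 5.0 ramp, GFP pKa 6.0 vs mCherry pKa 4.5:
    A_idx -> (0.0909/0.7597)/(0.9407/0.9980) = 0.1267."""
    p = replace(preset_genotype("wild_type"), pH_tau=5.0,
                nucleus_decay_halftime=math.inf, shrink_onset=math.inf)
    scene = simulate_scene(p, 0)
    optics = replace(noise_free, background=0.0)
    stack = render_stack(scene, nucleus_channels, optics, seed=0)
    tc = acidification_index(stack, 0, 1, annotation_from_scene(scene))
    expected = ((1 / (1 + 10 ** (6.0 - 5.0))) / (1 / (1 + 10 ** (4.5 - 5.0)))) / \
               ((1 / (1 + 10 ** (6.0 - 7.2))) / (1 / (1 + 10 ** (4.5 - 7.2))))
    assert expected == pytest.approx(0.12695, abs=1e-5)
    assert tc.values[30] == pytest.approx(expected, rel=0.02)


def test_zero_mcherry_raises():
    img = np.ones((1, 2, 16, 16))
    img[0, 1] = 0.0
    stack = as_stack(img)
    ann = RoiAnnotation(np.array([[8.0, 8.0]]), [np.zeros((3, 2))],
                        [np.zeros((3, 2))], (0, 0, 3, 3))
    with pytest.raises(ValueError, match="mCherry"):
        acidification_index(stack, 0, 1, ann)


# --- invariances ----------------------------------------------------


def test_offset_invariance_of_background_subtracted_measures(
        wt_stack, wt_annotation):
    shifted = ImageStack(wt_stack.data + 37.0, wt_stack.channel_names,
                         wt_stack.pixel_size, wt_stack.frame_interval)
    for fn in (lambda s: luminal_relative_intensity(s, 0, wt_annotation),
               lambda s: surface_relative_intensity(s, 0, wt_annotation)):
        assert np.allclose(fn(wt_stack).values, fn(shifted).values, rtol=1e-9)
    # A_idx is deliberately NOT offset-invariant (no background term)
    a0 = acidification_index(wt_stack, 1, 2, wt_annotation).values
    a1 = acidification_index(shifted, 1, 2, wt_annotation).values
    assert not np.allclose(a0, a1, rtol=1e-6)


def test_scaling_invariance_of_relative_measures(wt_stack, wt_annotation):
    scaled = ImageStack(wt_stack.data * 3.7, wt_stack.channel_names,
                        wt_stack.pixel_size, wt_stack.frame_interval)
    for fn in (lambda s: luminal_relative_intensity(s, 0, wt_annotation),
               lambda s: surface_relative_intensity(s, 0, wt_annotation),
               lambda s: acidification_index(s, 1, 2, wt_annotation)):
        assert np.allclose(fn(wt_stack).values, fn(scaled).values, rtol=1e-9)


def test_every_normalized_timecourse_starts_at_one(wt_stack, wt_annotation):
    for tc in (luminal_relative_intensity(wt_stack, 0, wt_annotation),
               surface_relative_intensity(wt_stack, 0, wt_annotation),
               acidification_index(wt_stack, 1, 2, wt_annotation),
               nuclear_diameter_ratio(wt_stack, 2, wt_annotation)):
        assert tc.values[0] == pytest.approx(1.0)


# --- disc diameter --------------------------------------------------


def test_disc_diameter_of_rendered_disc(wt_stack, wt_scene, wt_annotation):
    """Phagosome disc: 20 px radius x 0.1 um/px -> 4.0 um (FWHM)."""
    d = measure_disc_diameter(wt_stack, 0, 3, tuple(wt_annotation.center_track[0]))
    assert d == pytest.approx(2 * 20 * 0.1, abs=0.1)


def test_disc_diameter_background_only_returns_nan():
    stack = as_stack(np.full((1, 1, 64, 64), 10.0))
    assert math.isnan(measure_disc_diameter(stack, 0, 0, (32, 32)))


def test_nucleus_diameter_tracks_ground_truth(wt_stack, wt_scene, wt_annotation):
    tc = disc_diameter_timecourse(wt_stack, 2, wt_annotation)
    for ti in range(0, 31, 5):
        truth_um = 2 * wt_scene.frames[ti].nucleus_radius * wt_scene.pixel_size
        assert tc.values[ti] == pytest.approx(truth_um, abs=0.1)  # 1 px


def test_nuclear_diameter_ratio_static_disc_stays_near_one(
        noise_free, nucleus_channels):
    p = replace(preset_genotype("cup5_like"))
    scene = simulate_scene(p, 1)
    stack = render_stack(scene, nucleus_channels, noise_free, seed=1)
    tc = nuclear_diameter_ratio(stack, 1, annotation_from_scene(scene))
    assert np.all(tc.values >= 0.9)


def test_nuclear_ratio_halves_at_decay_halftime(noise_free, nucleus_channels):
    p = replace(preset_genotype("wild_type"), nucleus_decay_halftime=30.0)
    scene = simulate_scene(p, 1)
    stack = render_stack(scene, nucleus_channels, noise_free, seed=1)
    tc = nuclear_diameter_ratio(stack, 1, annotation_from_scene(scene))
    idx = int(np.argmin(np.abs(tc.times - 30.0)))
    assert tc.values[idx] == pytest.approx(0.5, abs=0.05)


def test_luminal_rint_noise_robustness(wt_annotation):
    """Median measured RInt at 60 min under default noise stays within
    15% of the noise-free value (50 seeds)."""
    scene = simulate_scene(preset_genotype("wild_type"), 1)
    ann = annotation_from_scene(scene)
    lgg = [default_channels()[0]]
    clean = render_stack(scene, lgg, Optics(shot_noise=False, read_noise=0.0), seed=0)
    ref = luminal_relative_intensity(clean, 0, ann).values[30]
    vals = []
    for seed in range(50):
        noisy = render_stack(scene, lgg, Optics(), seed=100 + seed)
        vals.append(luminal_relative_intensity(noisy, 0, ann).values[30])
    assert np.median(vals) == pytest.approx(ref, rel=0.15)
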