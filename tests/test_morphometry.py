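"""Unit and property tests for the bright-field morphometry pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu as skimage_otsu

from conftest import brute_force_otsu, projection_scan_min_feret
from spheroquant import morphometry as mm
from spheroquant import synthetic
from spheroquant.morphometry import (
    BrightfieldImage,
    DegenerateHistogramError,
    OutlierConfig,
    feret_diameters,
    invert_image,
    measure_spheroid,
    measurements_to_frame,
    min_feret_diameter,
    otsu_threshold,
    pair_timepoints,
    remove_speckles,
    rout_outlier_screen,
    segment_spheroid,
)


# --------------------------------------------------------------- inversion

def test_invert_is_involution_and_uses_dtype_range():
    px = np.array([[0, 100], [200, 255]], dtype=np.uint8)
    img = BrightfieldImage(pixels=px)
    inv = invert_image(img)
    assert inv.pixels[0, 0] == 255 and inv.pixels[1, 1] == 0
    np.testing.assert_array_equal(invert_image(inv).pixels, px)


def test_invert_float_image_against_own_max():
    px = np.array([[0.2, 0.8]])
    inv = invert_image(BrightfieldImage(pixels=px))
    np.testing.assert_allclose(inv.pixels, [[0.6, 0.0]])
    np.testing.assert_allclose(invert_image(inv).pixels, [[0.2, 0.8]] - np.float64(0.2))


def test_invert_constant_image_stays_constant():
    inv = invert_image(BrightfieldImage(pixels=np.full((4, 4), 7, dtype=np.uint16)))
    assert np.unique(inv.pixels).size == 1


# --------------------------------------------------------------- Otsu

def test_otsu_two_spike_histogram_matches_brute_force():
    counts = np.zeros(256)
    counts[50] = 1000
    counts[200] = 1000
    t = otsu_threshold(counts)
    assert 50 <= t < 200
    assert t == brute_force_otsu(counts)


@pytest.mark.parametrize("seed", range(5))
def test_otsu_gaussian_mixture_matches_brute_force_and_skimage(seed):
    rng = np.random.default_rng(seed)
    x = np.r_[rng.normal(60, 10, 3000), rng.normal(190, 15, 2000)]
    counts, edges = np.histogram(np.clip(x, 0, 255), bins=np.arange(257))
    t = otsu_threshold(counts)
    assert t == brute_force_otsu(counts)
    # independent library cross-check: same bin (skimage returns bin centers)
    assert t == int(skimage_otsu(hist=(counts, np.arange(256))))


def test_otsu_degenerate_single_bin_raises():
    counts = np.zeros(256)
    counts[7] = 123
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(counts)


# --------------------------------------------------------------- speckles

def test_small_square_blob_removed_large_disk_retained():
    mask = np.zeros((64, 64), dtype=bool)
    mask[5:8, 5:8] = True                     # area 9, eq. diameter 3.39
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 6.0**2   # eq. diameter ~12
    out, removed = remove_speckles(mask | disk, 10.0)
    assert removed == 1
    assert not out[5:8, 5:8].any()
    np.testing.assert_array_equal(out, disk)


def test_empty_mask_passes_through():
    out, removed = remove_speckles(np.zeros((10, 10), dtype=bool))
    assert removed == 0 and not out.any()


# --------------------------------------------------------------- min Feret

def test_min_feret_rectangle_is_exact_width():
    mask = np.zeros((120, 120), dtype=bool)
    mask[10:110, 30:70] = True                # 100 x 40 px
    assert min_feret_diameter(mask) == pytest.approx(40.0, abs=0.5)


def test_min_feret_disk_diameter_200():
    gt = synthetic.ImageGroundTruth(true_diameter_px=200)
    _, mask = synthetic.generate_spheroid_image(gt)
    assert min_feret_diameter(mask) == pytest.approx(200.0, abs=1.0)


def test_min_feret_never_exceeds_max_feret():
    rng = np.random.default_rng(3)
    for _ in range(20):
        mask = _random_convex_mask(rng)
        d_min, d_max = feret_diameters(mask)
        assert d_min <= d_max


@pytest.mark.parametrize("seed", range(10))
def test_min_feret_matches_projection_scan_oracle(seed):
    mask = _random_convex_mask(np.random.default_rng(seed))
    ours = min_feret_diameter(mask)
    oracle = projection_scan_min_feret(mask)
    assert ours == pytest.approx(oracle, rel=0.005)


def test_min_feret_empty_mask_raises():
    with pytest.raises(ValueError):
        min_feret_diameter(np.zeros((5, 5), dtype=bool))


def _random_convex_mask(rng, size=110):
    from scipy.spatial import ConvexHull

    pts = rng.uniform(10, size - 10, size=(12, 2))
    hull = ConvexHull(pts)
    v = pts[hull.vertices]
    rr, cc = draw_polygon(v[:, 1], v[:, 0], shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


# --------------------------------------------------------------- segmentation

def test_noise_free_disk_segmentation_high_iou():
    gt = synthetic.ImageGroundTruth(true_diameter_px=240, seed=1)
    img, truth = synthetic.generate_spheroid_image(gt)
    seg = segment_spheroid(img)
    iou = (seg.primary_object & truth).sum() / (seg.primary_object | truth).sum()
    assert iou >= 0.98
    assert not seg.multi_object_flag


def test_speckles_filtered_out_single_object_remains():
    gt = synthetic.ImageGroundTruth(true_diameter_px=180, n_speckles=6, noise_sd=0.02, seed=2)
    img, _ = synthetic.generate_spheroid_image(gt)
    seg = segment_spheroid(img)
    assert seg.n_objects_after_filter == 1


def test_split_spheroid_well_sets_multi_object_flag():
    gt = synthetic.ImageGroundTruth(true_diameter_px=200, n_spheroids=2, seed=3)
    img, truth = synthetic.generate_spheroid_image(gt)
    seg = segment_spheroid(img)
    assert seg.multi_object_flag
    assert seg.n_objects_after_filter == 2


def test_only_speckles_raises_segmentation_error():
    # the only dark objects are debris below the 10 px cutoff
    px = np.full((64, 64), 55000, dtype=np.uint16)
    px[10:12, 10:12] = 15000
    px[40:43, 50:52] = 15000
    with pytest.raises(mm.SegmentationError):
        segment_spheroid(BrightfieldImage(pixels=px))


# --------------------------------------------------------------- measurement

def test_formulas_at_unit_radius():
    gt = synthetic.ImageGroundTruth(true_diameter_px=200, seed=4)
    img, _ = synthetic.generate_spheroid_image(gt)
    img.scale_um_per_px = 0.01                 # d = 2 um -> r = 1 um
    m = measure_spheroid(segment_spheroid(img))
    assert m.r == m.d / 2
    assert m.V == pytest.approx((4 / 3) * np.pi * (m.d / 2) ** 3, rel=1e-9)
    assert m.C == pytest.approx(np.pi * (m.d / 2) ** 2 / m.A, rel=1e-9)
    assert m.V == pytest.approx(4.18879, rel=0.02)   # near-unit radius sphere


def test_disk_circularity_near_one_ellipse_near_half():
    img, _ = synthetic.generate_spheroid_image(
        synthetic.ImageGroundTruth(true_diameter_px=220, seed=5)
    )
    c_disk = measure_spheroid(segment_spheroid(img)).C
    assert c_disk == pytest.approx(1.0, abs=0.05)

    # 2:1 ellipse, semi-axes 100/50: min Feret 100, A = pi*100*50 -> C = 0.5
    ecc = np.sqrt(1 - 0.25)                    # axis ratio 2 -> e = sqrt(3)/2
    img2, mask2 = synthetic.generate_spheroid_image(
        synthetic.ImageGroundTruth(true_diameter_px=100, eccentricity=ecc, seed=6)
    )
    assert min_feret_diameter(mask2) == pytest.approx(100.0, abs=1.0)
    c_ellipse = measure_spheroid(segment_spheroid(img2)).C
    assert c_ellipse == pytest.approx(0.5, abs=0.03)


def test_scaling_mask_scales_measurements_as_powers():
    gt1 = synthetic.ImageGroundTruth(true_diameter_px=120, seed=7)
    gt2 = synthetic.ImageGroundTruth(true_diameter_px=240, seed=7)
    m = []
    for gt in (gt1, gt2):
        img, _ = synthetic.generate_spheroid_image(gt)
        m.append(measure_spheroid(segment_spheroid(img)))
    assert m[1].d / m[0].d == pytest.approx(2.0, rel=0.02)
    assert m[1].A / m[0].A == pytest.approx(4.0, rel=0.04)
    assert m[1].V / m[0].V == pytest.approx(8.0, rel=0.06)


def test_nonpositive_scale_rejected():
    img, _ = synthetic.generate_spheroid_image(
        synthetic.ImageGroundTruth(true_diameter_px=100, seed=8)
    )
    seg = segment_spheroid(img)
    with pytest.raises(ValueError):
        measure_spheroid(seg, scale_um_per_px=0.0)


# --------------------------------------------------------------- ROUT

def test_single_gross_outlier_is_the_only_flag():
    values = np.r_[np.full(99, 5.0), 250.0]
    flags = rout_outlier_screen(values)
    assert flags[-1] and flags[:-1].sum() == 0


def test_rout_small_sample_skipped_with_warning():
    with pytest.warns(UserWarning):
        flags = rout_outlier_screen(np.arange(5.0))
    assert not flags.any()


def test_rout_null_false_flag_rate_controlled():
    rng = np.random.default_rng(11)
    fractions = [
        rout_outlier_screen(rng.normal(size=100)).mean() for _ in range(200)
    ]
    assert np.mean(fractions) <= 0.02


def test_rout_flags_planted_gross_outliers():
    rng = np.random.default_rng(12)
    hit = 0
    reps = 100
    for _ in range(reps):
        x = rng.normal(size=100)
        x[:5] = np.array([8.0, -8.0, 8.0, -8.0, 8.0])
        if rout_outlier_screen(x)[:5].all():
            hit += 1
    assert hit / reps >= 0.95


@given(st.floats(min_value=0.001, max_value=0.2))
@settings(max_examples=10, deadline=None)
def test_rout_flags_are_boolean_per_value(q):
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    flags = rout_outlier_screen(x, OutlierConfig(Q=q))
    assert flags.shape == x.shape and flags.dtype == bool


# --------------------------------------------------------------- pairing

def _records(wells, day, outlier=(), multi=()):
    rows = []
    for w in wells:
        rows.append(
            mm.SpheroidMeasurement(
                batch_id="b", well_id=w, timepoint_days=day,
                d_px=100, A_px=7850, d=100, r=50, A=7850,
                V=(4 / 3) * np.pi * 50**3, C=1.0,
                n_objects=2 if w in multi else 1,
                multi_object_flag=w in multi, outlier_flag=w in outlier,
            )
        )
    return measurements_to_frame(rows).rename(
        columns={"d_um": "d", "A_um2": "A", "V_um3": "V"}
    ).assign(outlier_flag=lambda d: d.outlier_flag, )


def test_pairing_is_well_intersection():
    t1 = _records(["B2", "B3", "B4"], 14)
    t2 = _records(["B3", "B4", "B5"], 28)
    paired, counts = pair_timepoints(t1, t2)
    assert sorted(paired["well_id"]) == ["B3", "B4"]
    assert counts["paired"] == 2


def test_flagged_wells_dropped_from_pairs():
    t1 = _records(["B2", "B3", "B4"], 14)
    t2 = _records(["B2", "B3", "B4"], 28, outlier={"B3"}, multi={"B4"})
    paired, counts = pair_timepoints(t1, t2)
    assert list(paired["well_id"]) == ["B2"]
    assert counts["excluded_outlier"] == 1 and counts["excluded_multi_object"] == 1


def test_disjoint_well_sets_raise():
    with pytest.raises(ValueError):
        pair_timepoints(_records(["B2"], 14), _records(["C2"], 28))
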