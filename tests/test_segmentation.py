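import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu as sk_otsu

from phenoscan import make_layout, simulate_plate
from phenoscan.errors import DegenerateInputError
from phenoscan.segmentation import (
    OTSU_NBINS,
    otsu_threshold,
    rgb_to_lab,
    segment_plants,
    white_balance,
)


# -- white balance -----------------------------------------------------------


def test_white_balance_neutral_image_unchanged():
    rng = np.random.default_rng(0)
    grey = np.repeat(rng.uniform(0.2, 0.8, (40, 40, 1)), 3, axis=2)
    out = white_balance(grey)
    np.testing.assert_allclose(out, grey, atol=1e-12)


def test_white_balance_equalizes_background_channel_means():
    rng = np.random.default_rng(1)
    img = np.empty((60, 60, 3))
    for c, m in enumerate((0.6, 0.5, 0.4)):
        img[..., c] = np.clip(rng.normal(m, 0.02, (60, 60)), 0, 1)
    bg = np.ones((60, 60), bool)
    bg[20:40, 20:40] = False          # pretend centre holds the subject
    out = white_balance(img, background=bg)
    means = out[bg].mean(axis=0)
    assert np.ptp(means) < 1e-6


def test_white_balance_all_black_raises():
    with pytest.raises(DegenerateInputError):
        white_balance(np.zeros((10, 10, 3)))


# -- Lab transform -----------------------------------------------------------


@pytest.mark.parametrize("rgb,check", [
    ((1.0, 1.0, 1.0), lambda lab: np.allclose(lab, [100, 0, 0], atol=1e-2)),
    ((0.0, 0.0, 0.0), lambda lab: abs(lab[0]) < 1e-6),
    ((0.0, 1.0, 0.0), lambda lab: lab[1] < 0),   # green has negative a*
    ((1.0, 0.0, 0.0), lambda lab: lab[1] > 0),   # red has positive a*
])
def test_lab_reference_points(rgb, check):
    lab = rgb_to_lab(np.array(rgb, dtype=float).reshape(1, 1, 3))[0, 0]
    assert check(lab)


# -- Otsu --------------------------------------------------------------------


def _otsu_bruteforce(values, nbins=OTSU_NBINS):
    """Naive exhaustive search over all interior bin boundaries."""
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    width = (hi - lo) / nbins
    bins = np.clip(np.floor((v - lo) / width).astype(int), 0, nbins - 1)
    best_k, best_sigma = None, -1.0
    for k in range(nbins - 1):
        c0 = v[bins <= k]
        c1 = v[bins > k]
        if c0.size == 0 or c1.size == 0:
            continue
        w0 = c0.size / v.size
        sigma = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if sigma > best_sigma:       # strict: keeps the smallest tie
            best_sigma, best_k = sigma, k
    return lo + (best_k + 1) * width


def test_otsu_bimodal_threshold_between_modes():
    v = np.r_[np.full(500, -30.0), np.full(500, 5.0)]
    t = otsu_threshold(v)
    assert -30 < t < 5


def test_otsu_matches_bruteforce_on_random_mixtures(rng):
    for _ in range(30):
        n0, n1 = rng.integers(50, 400, 2)
        mu = rng.uniform(-30, 30, 2)
        sd = rng.uniform(0.5, 6.0, 2)
        v = np.r_[rng.normal(mu[0], sd[0], n0), rng.normal(mu[1], sd[1], n1)]
        assert otsu_threshold(v) == pytest.approx(_otsu_bruteforce(v))


def test_otsu_close_to_skimage_on_clean_bimodal(rng):
    v = np.r_[rng.normal(-20, 1.5, 800), rng.normal(8, 1.5, 800)]
    width = np.ptp(v) / OTSU_NBINS
    assert abs(otsu_threshold(v) - sk_otsu(v, nbins=OTSU_NBINS)) <= 4 * width


def test_otsu_constant_sample_raises():
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full(100, 3.14))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_otsu_equals_bruteforce_property(seed):
    r = np.random.default_rng(seed)
    v = np.r_[r.normal(r.uniform(-40, 0), r.uniform(0.3, 5), 200),
              r.normal(r.uniform(1, 40), r.uniform(0.3, 5), 200)]
    assert otsu_threshold(v) == pytest.approx(_otsu_bruteforce(v))


# -- segmentation ------------------------------------------------------------


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


def test_segmentation_iou_noise_free(presets, small_layout):
    s = simulate_plate(small_layout, presets, 6, seed=11, noise_scale=0.0)
    wb = white_balance(s.rgb, background=~small_layout.well_disk_mask())
    mask = segment_plants(wb, small_layout)
    assert _iou(mask.foreground, s.truth_labels > 0) >= 0.95


def test_segmentation_iou_default_noise(plate_6hat, small_layout):
    wb = white_balance(plate_6hat.rgb,
                       background=~small_layout.well_disk_mask())
    mask = segment_plants(wb, small_layout)
    assert _iou(mask.foreground, plate_6hat.truth_labels > 0) >= 0.85


def test_segmentation_senescent_wells_still_found(presets):
    # late-timepoint plate mixing healthy control with necrotic wells
    layout = make_layout(6, 4, (720, 480), ["paraquat", "tiafenacil",
                                            "control"], seed=0)
    s = simulate_plate(layout, presets, 120, seed=12)
    wb = white_balance(s.rgb, background=~layout.well_disk_mask())
    mask = segment_plants(wb, layout)
    assert not mask.empty_wells.any()
    assert _iou(mask.foreground, s.truth_labels > 0) >= 0.85


def test_segmentation_background_only_image_all_empty(small_layout):
    rng = np.random.default_rng(3)
    h, w = small_layout.image_shape
    img = np.empty((h, w, 3))
    for c, chroma in enumerate((0.38, 0.32, 0.30)):   # plain warm plate
        img[..., c] = np.clip(chroma * 1.45
                              * (1 + rng.normal(0, 0.03, (h, w))), 0, 1)
    with pytest.warns(UserWarning, match="empty plate"):
        mask = segment_plants(img, small_layout)
    assert mask.empty_wells.all()
    assert not mask.foreground.any()


def test_masks_confined_to_well_disks(plate_6hat, small_layout):
    wb = white_balance(plate_6hat.rgb,
                       background=~small_layout.well_disk_mask())
    mask = segment_plants(wb, small_layout)
    disks = small_layout.label_image()
    fg = mask.foreground
    assert np.array_equal(mask.well_labels[fg], disks[fg])
    # per-well foreground never exceeds the disk area
    disk_area = np.bincount(disks.ravel())[1:]
    assert (mask.n_pixels_per_well <= disk_area).all()


def test_segmentation_invariant_to_balanced_brightness_scaling(plate_6hat,
                                                               small_layout):
    wb = white_balance(plate_6hat.rgb,
                       background=~small_layout.well_disk_mask())
    m1 = segment_plants(wb, small_layout)
    m2 = segment_plants(np.clip(wb * 0.7, 0, 1), small_layout)
    assert _iou(m1.foreground, m2.foreground) > 0.99
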