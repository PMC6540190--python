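"""Colour-space conversion, mean-shift chroma clustering, mask selection, erosion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopytherm import segmentation, synthetic
from canopytherm.segmentation import (
    erode_mask,
    mean_shift_ab,
    rgb_to_lab,
    select_plant_mask,
)

from conftest import small_scene_params


def _srgb_to_lab_reference(rgb8):
    """Independent closed-form sRGB(D65) -> CIELAB oracle (no skimage)."""
    c = np.asarray(rgb8, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])  # D65
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    b = 200 * (f[1] - f[2])
    return np.array([L, a, b])


class TestRgbToLab:
    def test_white_maps_to_achromatic_l100(self):
        lab = rgb_to_lab(np.full((1, 1, 3), 255, dtype=np.uint8))[0, 0]
        assert lab[0] == pytest.approx(100.0, abs=0.01)
        assert lab[1] == pytest.approx(0.0, abs=0.01)
        assert lab[2] == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("v", [0, 64, 128, 200])
    def test_gray_axis_is_achromatic(self, v):
        lab = rgb_to_lab(np.full((2, 2, 3), v, dtype=np.uint8))[0, 0]
        assert abs(lab[1]) < 0.3 and abs(lab[2]) < 0.3

    @pytest.mark.parametrize(
        "rgb", [(0, 128, 0), (60, 120, 40), (150, 110, 75), (255, 0, 0), (10, 40, 200)]
    )
    def test_matches_closed_form_oracle(self, rgb):
        img = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        got = rgb_to_lab(img)[0, 0]
        want = _srgb_to_lab_reference(rgb)
        assert np.allclose(got, want, atol=0.05)

    def test_green_is_negative_a_positive_b(self):
        lab = rgb_to_lab(np.array([[[0, 128, 0]]], dtype=np.uint8))[0, 0]
        assert lab[1] < 0 and lab[2] > 0

    def test_rejects_bad_shape_and_range(self):
        with pytest.raises(ValueError):
            rgb_to_lab(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            rgb_to_lab(np.full((2, 2, 3), 300))


def _two_color_image(c1, c2, h=20, w=20):
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:, : w // 2] = c1
    img[:, w // 2:] = c2
    return img


class TestMeanShift:
    def test_two_constant_colors_give_two_labels(self):
        img = _two_color_image((60, 120, 40), (150, 110, 75))
        lab = rgb_to_lab(img)
        d = np.linalg.norm(lab[0, 0, 1:] - lab[0, -1, 1:])
        res = mean_shift_ab(lab, bandwidth=d / 2 - 1)
        assert res.n_clusters == 2
        # every pixel of one half shares a label
        assert len(np.unique(res.labels[:, :10])) == 1
        assert len(np.unique(res.labels[:, 10:])) == 1

    def test_constant_image_gives_single_label(self):
        lab = rgb_to_lab(np.full((10, 10, 3), 90, dtype=np.uint8))
        res = mean_shift_ab(lab, bandwidth=5.0)
        assert res.n_clusters == 1
        assert np.all(res.labels == 0)

    def test_nonpositive_bandwidth_rejected(self):
        lab = rgb_to_lab(np.full((4, 4, 3), 90, dtype=np.uint8))
        with pytest.raises(ValueError, match="bandwidth"):
            mean_shift_ab(lab, bandwidth=0.0)

    def test_scene_modes_near_generator_truth(self):
        p = small_scene_params(rng_seed=8)
        rgb, _, _ = synthetic.generate_scene(p)
        lab = rgb_to_lab(rgb)
        res = mean_shift_ab(lab, bandwidth=12.0, subsample=500, seed=0)
        true_canopy = rgb_to_lab(
            np.array(p.canopy_color_mean, dtype=np.uint8).reshape(1, 1, 3)
        )[0, 0, 1:]
        true_soil = rgb_to_lab(
            np.array(p.background_color_mean, dtype=np.uint8).reshape(1, 1, 3)
        )[0, 0, 1:]
        d_canopy = np.linalg.norm(res.mode_centers - true_canopy, axis=1).min()
        d_soil = np.linalg.norm(res.mode_centers - true_soil, axis=1).min()
        # colour noise sd 8 in RGB maps to a few a*b* units; modes are means
        # over many pixels, so they sit well within 2 SD of the true chroma
        assert d_canopy < 4.0 and d_soil < 4.0

    def test_labels_invariant_to_global_lightness_shift(self):
        p = small_scene_params(rng_seed=9)
        rgb, _, _ = synthetic.generate_scene(p)
        lab = rgb_to_lab(rgb)
        shifted = lab.copy()
        shifted[..., 0] += 25.0
        a = mean_shift_ab(lab, bandwidth=12.0, subsample=300, seed=1)
        b = mean_shift_ab(shifted, bandwidth=12.0, subsample=300, seed=1)
        assert np.array_equal(a.labels, b.labels)


class TestSelectPlantMask:
    def test_green_cluster_selected_exactly(self):
        img = _two_color_image((60, 120, 40), (150, 110, 75))
        lab = rgb_to_lab(img)
        res = mean_shift_ab(lab, bandwidth=10.0)
        mask = select_plant_mask(res)
        want = np.broadcast_to(np.arange(20) < 10, (20, 20))
        assert np.array_equal(mask, want)

    def test_no_green_returns_empty_mask_with_warning(self):
        lab = rgb_to_lab(_two_color_image((150, 110, 75), (170, 120, 90)))
        res = mean_shift_ab(lab, bandwidth=10.0)
        with pytest.warns(UserWarning, match="empty mask"):
            mask = select_plant_mask(res)
        assert not mask.any()

    def test_override_labels_win(self):
        img = _two_color_image((60, 120, 40), (150, 110, 75))
        res = mean_shift_ab(rgb_to_lab(img), bandwidth=10.0)
        mask = select_plant_mask(res, override_labels=[1])
        assert np.array_equal(mask, res.labels == 1)

    def test_scene_precision_recall(self):
        p = small_scene_params(rng_seed=12, color_noise_sd=(6.0, 6.0, 6.0))
        rgb, _, truth = synthetic.generate_scene(p)
        res = mean_shift_ab(rgb_to_lab(rgb), bandwidth=12.0, subsample=500, seed=0)
        mask = select_plant_mask(res)
        tp = (mask & truth.true_mask).sum()
        assert tp / mask.sum() >= 0.95
        assert tp / truth.true_mask.sum() >= 0.95


def _erode_bruteforce(mask, radius):
    """Definitionally erode: a pixel survives iff its full square window is True."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            r0, r1 = r - radius, r + radius + 1
            c0, c1 = c - radius, c + radius + 1
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                continue  # out of frame counts as background
            out[r, c] = mask[r0:r1, c0:c1].all()
    return out


class TestErodeMask:
    def test_full_5x5_erodes_to_central_3x3(self):
        out = erode_mask(np.ones((5, 5), dtype=bool), selem_radius=1, iterations=1)
        want = np.zeros((5, 5), dtype=bool)
        want[1:4, 1:4] = True
        assert np.array_equal(out, want)

    def test_empty_and_singleton(self):
        assert not erode_mask(np.zeros((6, 6), dtype=bool)).any()
        single = np.zeros((6, 6), dtype=bool)
        single[3, 3] = True
        assert not erode_mask(single).any()

    @pytest.mark.parametrize("radius,iterations", [(1, 1), (1, 2), (2, 1)])
    def test_matches_bruteforce_on_random_masks(self, radius, iterations):
        rng = np.random.default_rng(42)
        for _ in range(5):
            mask = rng.random((12, 14)) > 0.3
            want = mask
            for _ in range(iterations):
                want = _erode_bruteforce(want, radius)
            got = erode_mask(mask, selem_radius=radius, iterations=iterations)
            assert np.array_equal(got, want)

    @given(seed=st.integers(0, 10_000), iters=st.integers(1, 3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_antiextensive_and_decreasing(self, seed, iters):
        mask = np.random.default_rng(seed).random((15, 15)) > 0.25
        once = erode_mask(mask, 1, iters)
        more = erode_mask(mask, 1, iters + 1)
        assert not (once & ~mask).any()  # output subset of input
        assert not (more & ~once).any()  # decreasing in iterations

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            erode_mask(np.ones((3, 3), dtype=bool), selem_radius=0)
        with pytest.raises(ValueError):
            erode_mask(np.ones((3, 3), dtype=bool), iterations=0)
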