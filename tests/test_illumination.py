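"""Brightness signature, power-law grid search, and the accuracy metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ripecolor import (DEFAULT_STANDARD_BRIGHTNESS, BrightnessComponents,
                       InvalidInputError, StandardBrightness,
                       adjustment_accuracy, aplt_adjust, brightness_components,
                       brightness_difference, overall_brightness,
                       power_law_transform, standard_brightness)
from ripecolor.illumination import C_GRID, GAMMA_BRIGHT_BRANCH, GAMMA_DARK_BRANCH

from conftest import random_rgb


def constant_image(value, h=8, w=8):
    return np.full((h, w, 3), value, dtype=np.uint8)


class TestOverallBrightness:
    def test_constant_image(self):
        assert overall_brightness(constant_image(100)) == pytest.approx(100.0)

    def test_all_zero(self):
        assert overall_brightness(constant_image(0)) == 0.0

    def test_two_pixel_quadratic_mean(self):
        img = np.zeros((1, 2, 3))
        img[0, 1] = 255
        assert overall_brightness(img, p=2) == pytest.approx(
            np.sqrt(255.0 ** 2 / 2))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            overall_brightness(np.zeros((0, 4, 3)))
        with pytest.raises(InvalidInputError):
            overall_brightness(constant_image(10), p=0)

    @settings(max_examples=30, derandomize=True)
    @given(alpha=st.floats(0.05, 1.0), seed=st.integers(0, 2**16))
    def test_homogeneous_in_scale(self, alpha, seed):
        img = np.random.default_rng(seed).uniform(0, 255, size=(6, 7, 3))
        assert overall_brightness(alpha * img) == pytest.approx(
            alpha * overall_brightness(img))


def brute_force_components(img):
    """Pixel-loop oracle for the 10-component signature."""
    arr = np.asarray(img, dtype=float)
    h, w, _ = arr.shape
    out = []
    for k in range(3):
        ch = arr[:, :, k]
        out.append(ch.sum() / (h * w))
    for k in range(3):
        ch = arr[:, :, k]
        m = ch.mean()
        out.append(np.sqrt(((ch - m) ** 2).sum() / (h * w)))
    for k in range(3):
        p = np.pad(arr[:, :, k], 1, mode="edge")
        total = 0.0
        for y in range(h):
            for x in range(w):
                gx = (p[y + 1, x + 2] - p[y + 1, x]) / 2.0
                gy = (p[y + 2, x + 1] - p[y, x + 1]) / 2.0
                total += np.hypot(gx, gy)
        out.append(total / (h * w))
    return out  # br bg bb cr cg cb gr gg gb


class TestBrightnessComponents:
    def test_constant_image(self):
        bc = brightness_components(constant_image(42))
        assert bc.ob == pytest.approx(42)
        assert (bc.br, bc.bg, bc.bb) == pytest.approx((42, 42, 42))
        assert (bc.cr, bc.cg, bc.cb) == (0, 0, 0)
        assert (bc.gr, bc.gg, bc.gb) == (0, 0, 0)

    def test_balanced_step_contrast(self):
        img = np.zeros((8, 8, 3))
        img[:, 4:] = 255
        bc = brightness_components(img)
        assert bc.cr == pytest.approx(127.5)

    def test_matches_pixel_loop_oracle(self, rng):
        img = random_rgb(rng, 9, 11)
        bc = brightness_components(img)
        got = [bc.br, bc.bg, bc.bb, bc.cr, bc.cg, bc.cb, bc.gr, bc.gg, bc.gb]
        assert got == pytest.approx(brute_force_components(img), rel=1e-12)

    def test_packaged_default_matches_reference_rig(self):
        c = DEFAULT_STANDARD_BRIGHTNESS.components
        assert [c.br, c.bg, c.bb, c.cr, c.cg, c.cb, c.gr, c.gg, c.gb] == [
            117.91, 117.44, 67.88, 45.44, 45.70, 71.96, 18.02, 18.54, 19.35]
        assert c.ob == 6.14


class TestStandardBrightness:
    def test_single_image_is_its_own_standard(self, rng):
        img = random_rgb(rng)
        sb = standard_brightness([img])
        assert sb.n_images == 1
        np.testing.assert_allclose(sb.components.as_array(),
                                   brightness_components(img).as_array())

    def test_two_constant_images_average(self):
        sb = standard_brightness([constant_image(10), constant_image(30)])
        assert sb.components.br == pytest.approx(20)
        assert sb.components.ob == pytest.approx(20)

    def test_matches_brute_force_mean(self, rng):
        imgs = [random_rgb(rng) for _ in range(10)]
        sb = standard_brightness(imgs)
        stack = np.stack([brightness_components(im).as_array() for im in imgs])
        np.testing.assert_allclose(sb.components.as_array(), stack.mean(axis=0))

    def test_empty_set_rejected(self):
        with pytest.raises(InvalidInputError):
            standard_brightness([])


class TestPowerLawTransform:
    def test_identity_within_rounding(self, rng):
        img = random_rgb(rng)
        out = power_law_transform(img, c=1, gamma=1)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_gamma_zero_saturates(self, rng):
        out = power_law_transform(random_rgb(rng), c=1, gamma=0)
        assert (out == 255).all()

    def test_scalar_closed_form(self):
        img = np.full((1, 1, 3), 0.25 * 255)
        out = power_law_transform(img, c=1, gamma=2)
        assert out[0, 0, 0] == round(0.0625 * 255)

    def test_invalid_c(self, rng):
        with pytest.raises(InvalidInputError):
            power_law_transform(random_rgb(rng), c=0, gamma=1)


class TestBrightnessDifference:
    def test_zero_on_itself(self, rng):
        bc = brightness_components(random_rgb(rng))
        assert brightness_difference(bc, StandardBrightness(bc)) == 0.0

    def test_single_component_offset(self):
        bc = brightness_components(constant_image(50))
        shifted = BrightnessComponents(**{**bc.to_dict(), "bg": bc.bg + 7.5})
        assert brightness_difference(shifted, StandardBrightness(bc)) == pytest.approx(7.5)

    def test_matches_ten_term_sum(self, rng):
        x = brightness_components(random_rgb(rng))
        y = brightness_components(random_rgb(rng))
        manual = sum(abs(a - b) for a, b in
                     zip(x.as_array(), y.as_array()))
        assert brightness_difference(x, StandardBrightness(y)) == pytest.approx(manual)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(10):
            x, y, z = (brightness_components(random_rgb(rng)) for _ in range(3))
            dxy = brightness_difference(x, StandardBrightness(y))
            dyx = brightness_difference(y, StandardBrightness(x))
            dxz = brightness_difference(x, StandardBrightness(z))
            dzy = brightness_difference(z, StandardBrightness(y))
            assert dxy >= 0
            assert dxy == pytest.approx(dyx)
            assert dxy <= dxz + dzy + 1e-9


def exhaustive_aplt(img, sb):
    """Independent brute-force loop over the full candidate grid."""
    ob = overall_brightness(img)
    gammas = GAMMA_BRIGHT_BRANCH if ob >= sb.components.ob else GAMMA_DARK_BRANCH
    results = []
    for g in gammas:
        for c in C_GRID:
            cand = power_law_transform(img, c, g)
            bd = brightness_difference(brightness_components(cand), sb)
            results.append((bd, abs(g - 1.0), c, g))
    results.sort()
    bd, _, c, g = results[0]
    return c, g, bd


class TestAplt:
    def test_identity_for_reference_image(self, rng):
        img = random_rgb(rng, 16, 16)
        sb = standard_brightness([img])
        res = aplt_adjust(img, sb)
        assert (res.c, res.gamma) == (1.0, 1.0)
        assert res.bd == 0.0

    def test_recovers_gamma_half_corruption(self, small_spec):
        from ripecolor import corrupt_brightness, generate_fruit_image
        fx = generate_fruit_image(small_spec, 5, seed=5)
        sb = standard_brightness([fx.image])
        res = aplt_adjust(corrupt_brightness(fx.image, 0.5), sb)
        assert (res.c, res.gamma) == (1.0, 2.0)
        err = np.abs(res.adjusted_image.astype(float) - fx.image.astype(float))
        assert err.mean() < 2.0

    def test_gamma_three_halves_corruption_selects_dark_branch(self, small_spec):
        from ripecolor import corrupt_brightness, generate_fruit_image
        fx = generate_fruit_image(small_spec, 5, seed=6)
        sb = standard_brightness([fx.image])
        res = aplt_adjust(corrupt_brightness(fx.image, 1.5), sb)
        assert res.c == 1.0
        assert res.gamma in (0.6, 0.7)

    def test_never_worse_than_identity_when_reachable(self, rng):
        imgs = [random_rgb(rng, 12, 12) for _ in range(6)]
        sb = standard_brightness(imgs)
        for img in imgs:
            if overall_brightness(img) < sb.components.ob:
                continue  # identity not in the searched branch
            own_bd = brightness_difference(brightness_components(img), sb)
            assert aplt_adjust(img, sb).bd <= own_bd + 1e-9

    def test_matches_exhaustive_oracle(self, rng):
        imgs = [random_rgb(rng, 10, 10) for _ in range(5)]
        sb = standard_brightness([random_rgb(rng, 10, 10) for _ in range(3)])
        for img in imgs:
            res = aplt_adjust(img, sb)
            c, g, bd = exhaustive_aplt(img, sb)
            assert (res.c, res.gamma) == (c, g)
            assert res.bd == pytest.approx(bd)

    def test_round_trip_restores_channel_means(self, small_spec):
        from ripecolor import corrupt_brightness, generate_fruit_image
        fx = generate_fruit_image(small_spec, 4, seed=9)
        sb = standard_brightness([fx.image])
        base = brightness_components(fx.image)
        for g in (0.5, 1.5):
            res = aplt_adjust(corrupt_brightness(fx.image, g), sb)
            got = res.components
            for name in ("br", "bg", "bb"):
                assert abs(getattr(got, name) - getattr(base, name)) < 5.0


class TestAdjustmentAccuracy:
    def test_perfect_match(self, rng):
        bc = brightness_components(random_rgb(rng))
        assert adjustment_accuracy(bc, StandardBrightness(bc)) == 100.0

    def test_one_component_fully_wrong(self):
        bc = brightness_components(constant_image(0))
        off = BrightnessComponents(**{**bc.to_dict(), "br": bc.br + 255})
        assert adjustment_accuracy(off, StandardBrightness(bc)) == pytest.approx(
            100 * (1 - (255 / 255) / 9))

    def test_uniform_ten_percent_error(self):
        bc = brightness_components(constant_image(100))
        d = bc.to_dict()
        shifted = BrightnessComponents(**{k: (v + 25.5 if k != "ob" else v)
                                          for k, v in d.items()})
        assert adjustment_accuracy(shifted, StandardBrightness(bc)) == pytest.approx(90.0)

    def test_ob_component_ignored(self, rng):
        bc = brightness_components(random_rgb(rng))
        off = BrightnessComponents(**{**bc.to_dict(), "ob": bc.ob + 100})
        assert adjustment_accuracy(off, StandardBrightness(bc)) == 100.0
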