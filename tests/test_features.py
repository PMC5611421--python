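"""Circularity, Similarity and intensity features against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ebiflow import Mask, ObjectImage, S_CAP, circularity, intensity_features, similarity

from oracles import circularity_bruteforce


def _mask(px):
    return Mask("t", "BF", px)


def _disk(shape, center, r):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r**2


def _random_blob(rng, size=48):
    px = np.zeros((size, size), bool)
    n = rng.integers(1, 5)
    for _ in range(n):
        cy, cx = rng.integers(12, size - 12, 2)
        px |= _disk((size, size), (cy, cx), rng.integers(4, 11))
    return px


class TestCircularity:
    def test_equals_bruteforce_on_random_masks(self, rng):
        for _ in range(100):
            px = _random_blob(rng)
            assert circularity(_mask(px)) == pytest.approx(
                circularity_bruteforce(px), abs=1e-12)

    def test_disk_rounder_than_square(self):
        disk = _disk((64, 64), (32, 32), 20)
        square = np.zeros((64, 64), bool)
        square[12:52, 12:52] = True
        c_disk, c_square = circularity(_mask(disk)), circularity(_mask(square))
        assert c_disk == pytest.approx(circularity_bruteforce(disk), abs=1e-12)
        assert c_disk > c_square

    def test_rotation_and_translation_invariance(self, rng):
        px = _random_blob(rng, size=40)
        c0 = circularity(_mask(px))
        assert circularity(_mask(np.rot90(px))) == pytest.approx(c0, abs=1e-12)
        assert circularity(_mask(np.roll(px, (3, -2), axis=(0, 1)))) == \
            pytest.approx(c0, abs=1e-12)

    def test_star_less_round_than_its_core(self):
        shape = (96, 96)
        core = _disk(shape, (48, 48), 14)
        star = core.copy()
        for k in range(6):
            th = k * np.pi / 3
            for t in range(0, 26):
                star |= _disk(shape, (48 + (13 + t) * np.sin(th),
                                      48 + (13 + t) * np.cos(th)),
                              max(1.5, 5 * (1 - t / 26)))
        c_star, c_core = circularity(_mask(star)), circularity(_mask(core))
        assert c_star == pytest.approx(circularity_bruteforce(star), abs=1e-12)
        assert c_star < c_core

    def test_elongating_ellipse_decreases_circularity(self):
        rr, cc = np.ogrid[:128, :128]
        values = []
        for ratio in (1.0, 2.0, 3.0, 4.0, 5.0):
            a, b = 18.0 * math.sqrt(ratio), 18.0 / math.sqrt(ratio)
            ell = ((cc - 64) / a) ** 2 + ((rr - 64) / b) ** 2 <= 1.0
            values.append(circularity(_mask(ell)))
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_scale_invariance_for_shapes_with_true_boundary_variation(self):
        # mean/SD is dimensionless: doubling an ellipse changes C only
        # through rasterization (a perfect circle's SD is *all*
        # rasterization, so the check needs genuine boundary variation)
        rr, cc = np.ogrid[:192, :192]
        small = ((cc - 96) / 24) ** 2 + ((rr - 96) / 14) ** 2 <= 1.0
        big = ((cc - 96) / 48) ** 2 + ((rr - 96) / 28) ** 2 <= 1.0
        c_small, c_big = circularity(_mask(small)), circularity(_mask(big))
        assert abs(c_big - c_small) / c_small < 0.05

    def test_too_few_boundary_pixels_raises(self):
        px = np.zeros((8, 8), bool)
        px[3, 3] = px[3, 4] = True
        with pytest.raises(ValueError, match="boundary"):
            circularity(_mask(px))


def _pair_img(a, b, region=None):
    img = ObjectImage("t", {"A": np.asarray(a, float),
                            "B": np.asarray(b, float)}, 1.0)
    if region is None:
        region = Mask("t", "A", np.ones(np.shape(a), bool))
    return img, region


class TestSimilarity:
    def test_perfect_linear_hits_cap(self, rng):
        a = rng.random((20, 20)) * 50
        img, region = _pair_img(a, 2 * a + 10)
        assert similarity(img, "A", "B", region) == pytest.approx(S_CAP)

    def test_negation_hits_negative_cap(self, rng):
        a = rng.random((20, 20)) * 50 + 10
        img, region = _pair_img(a, a.max() - a)
        assert similarity(img, "A", "B", region) == pytest.approx(-S_CAP)

    def test_symmetry_and_affine_invariance(self, rng):
        a = rng.random((30, 30)) * 40
        b = rng.random((30, 30)) * 40
        img, region = _pair_img(a, b)
        s_ab = similarity(img, "A", "B", region)
        s_ba = similarity(img, "B", "A", region)
        assert s_ab == pytest.approx(s_ba, abs=1e-12)
        img2, _ = _pair_img(3.5 * a + 7, b)
        assert similarity(img2, "A", "B", region) == pytest.approx(s_ab, abs=1e-9)

    def test_sign_flips_under_negation(self, rng):
        a = rng.random((30, 30)) * 40
        b = a + rng.normal(0, 5, a.shape)
        b -= b.min()
        img, region = _pair_img(a, b)
        s = similarity(img, "A", "B", region)
        img2, _ = _pair_img(a, b.max() - b)
        assert similarity(img2, "A", "B", region) == pytest.approx(-s, abs=1e-9)

    def test_independent_noise_mean_near_zero(self, rng):
        # Monte-Carlo null: S of two independent fields has mean 0
        n_rep, n_px = 300, 2500
        s = []
        region = Mask("t", "A", np.ones((50, 50), bool))
        for _ in range(n_rep):
            img, _ = _pair_img(rng.random((50, 50)), rng.random((50, 50)))
            s.append(similarity(img, "A", "B", region))
        se = np.std(s, ddof=1) / math.sqrt(n_rep)
        assert abs(np.mean(s)) < 3 * se + 1e-3

    def test_known_rho_recovers_closed_form(self, rng):
        # b = 0.8 z + 0.6 w on standardized fields -> rho = 0.8,
        # S = ln(1.8 / 0.2) = 2.197
        n = 200
        z = rng.standard_normal((n, n))
        w = rng.standard_normal((n, n))
        b = 0.8 * z + 0.6 * w
        img, region = _pair_img(z - z.min(), b - b.min())
        s = similarity(img, "A", "B", region)
        assert s == pytest.approx(math.log(1.8 / 0.2), abs=0.05)

    def test_zero_variance_gives_nan(self):
        img, region = _pair_img(np.ones((10, 10)), np.arange(100.0).reshape(10, 10))
        assert math.isnan(similarity(img, "A", "B", region))

    def test_tiny_region_raises(self, rng):
        img, _ = _pair_img(rng.random((10, 10)), rng.random((10, 10)))
        small = np.zeros((10, 10), bool)
        small[0, :4] = True
        with pytest.raises(ValueError, match="region"):
            similarity(img, "A", "B", Mask("t", "A", small))


class TestIntensityFeatures:
    def test_constant_level_zero_background(self):
        arr = np.zeros((32, 32))
        disk = _disk((32, 32), (16, 16), 8)
        arr[disk] = 7.0
        img = ObjectImage("t", {"C": arr}, 1.0)
        inten, mp = intensity_features(img, "C", Mask("t", "C", disk))
        assert inten == pytest.approx(7.0 * disk.sum())
        assert mp == pytest.approx(7.0)

    def test_constant_offset_shifts_mean_pixel_exactly(self, rng):
        arr = rng.random((32, 32)) * 20
        disk = _disk((32, 32), (16, 16), 8)
        img0 = ObjectImage("t", {"C": arr}, 1.0)
        img1 = ObjectImage("t", {"C": arr + 5.0}, 1.0)
        region = Mask("t", "C", disk)
        _, mp0 = intensity_features(img0, "C", region)
        _, mp1 = intensity_features(img1, "C", region)
        assert mp1 - mp0 == pytest.approx(5.0)

    def test_noisy_disk_within_three_sd(self, rng):
        level, sd, bg = 50.0, 3.0, 10.0
        disk = _disk((64, 64), (32, 32), 12)
        arr = np.clip(bg + level * disk + rng.normal(0, sd, (64, 64)), 0, None)
        img = ObjectImage("t", {"C": arr}, 1.0)
        inten, _ = intensity_features(img, "C", Mask("t", "C", disk))
        area = disk.sum()
        assert abs(inten - level * area) < 3 * sd * math.sqrt(2 * area)
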