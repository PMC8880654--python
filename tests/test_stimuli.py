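"""Stimulus synthesis: noise field, screening, targets, presentation plans."""

import math

import numpy as np
import pytest

import perlinspot as ps
from perlinspot.stimuli import (
    DEFAULT_SIDE_CM, InsufficientStimuliError, PresentationFormat,
    perlin_noise, visual_angle_deg,
)


def reference_perlin(angles, grid_cells, x_cm, y_cm, side_cm):
    """Independent scalar re-implementation of the gradient-noise value."""
    cell = side_cm / grid_cells
    u, v = x_cm / cell, y_cm / cell
    i = min(int(math.floor(u)), grid_cells - 1)
    j = min(int(math.floor(v)), grid_cells - 1)
    fx, fy = u - i, v - j
    total = 0.0
    for dj in (0, 1):
        for di in (0, 1):
            a = angles[j + dj, i + di]
            dot = math.cos(a) * (fx - di) + math.sin(a) * (fy - dj)
            wx = _ease(fx) if di else 1.0 - _ease(fx)
            wy = _ease(fy) if dj else 1.0 - _ease(fy)
            total += wx * wy * dot
    return total


def _ease(t):
    return 3.0 * t * t - 2.0 * t**3


def direct_spectrum_score(pixels, n_bins=8):
    """Orientation-energy ratio via explicit DFT matrices (no np.fft)."""
    data = pixels.astype(float)
    data = data - data.mean()
    h, w = data.shape
    wh = np.exp(-2j * np.pi * np.outer(np.arange(h), np.arange(h)) / h)
    ww = np.exp(-2j * np.pi * np.outer(np.arange(w), np.arange(w)) / w)
    power = np.abs(wh @ data @ ww.T) ** 2
    fy = (np.arange(h) - h * (np.arange(h) >= (h + 1) // 2)) / h
    fx = (np.arange(w) - w * (np.arange(w) >= (w + 1) // 2)) / w
    theta = np.mod(np.arctan2(fy[:, None], fx[None, :]), np.pi)
    bins = np.minimum((theta / (np.pi / n_bins)).astype(int), n_bins - 1)
    mask = np.ones_like(power, bool)
    mask[0, 0] = False
    energy = np.bincount(bins[mask], weights=power[mask], minlength=n_bins)
    return energy.max() / energy.mean()


# ---------------------------------------------------------------------------
# gradient lattice


class TestGradientLattice:
    def test_corner_count_and_unit_norm(self):
        lat = ps.make_gradient_lattice(seed=1, grid_cells=3)
        assert lat.angles.shape == (4, 4)
        gx, gy = lat.gradients
        assert np.allclose(np.hypot(gx, gy), 1.0)

    def test_determinism(self):
        a = ps.make_gradient_lattice(seed=5).angles
        b = ps.make_gradient_lattice(seed=5).angles
        assert np.array_equal(a, b)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            ps.make_gradient_lattice(seed=1, grid_cells=0)


# ---------------------------------------------------------------------------
# noise image


class TestPerlinImage:
    def test_default_size_348(self):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(1))
        assert img.pixels.shape == (348, 348)
        assert img.pixels.dtype == np.uint8

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_mean_luminance_near_128(self, seed):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(seed))
        assert abs(float(img.pixels.mean()) - 128.0) <= 2.0

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_noise_vanishes_at_lattice_corners(self, seed):
        lat = ps.make_gradient_lattice(seed)
        cell = DEFAULT_SIDE_CM / 3
        for i in range(4):
            for j in range(4):
                n = perlin_noise(lat, i * cell, j * cell, DEFAULT_SIDE_CM)
                assert abs(float(n)) < 1e-10

    @pytest.mark.parametrize("seed", [1, 7, 13])
    def test_probe_grid_matches_reference_implementation(self, seed):
        lat = ps.make_gradient_lattice(seed)
        probes = np.linspace(0.3, DEFAULT_SIDE_CM - 0.3, 10)
        for x in probes:
            for y in probes:
                ours = float(perlin_noise(lat, x, y, DEFAULT_SIDE_CM))
                ref = reference_perlin(lat.angles, 3, x, y, DEFAULT_SIDE_CM)
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_luminance_at_matches_pixels_within_rounding(self):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(3))
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.integers(0, img.side_px, 2)
            x = (j + 0.5) / img.scale_px_per_cm
            y = (i + 0.5) / img.scale_px_per_cm
            assert abs(img.luminance_at(x, y) - float(img.pixels[i, j])) <= 0.5 + 1e-9

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            ps.perlin_noise_image(ps.make_gradient_lattice(1), side_cm=-1.0)


# ---------------------------------------------------------------------------
# anisotropy screening


def _as_image(pixels):
    return ps.PerlinImage(pixels=pixels.astype(np.uint8), side_cm=8.7,
                          scale_px_per_cm=pixels.shape[0] / 8.7, lattice_seed=-1)


class TestAnisotropy:
    def test_grating_concentrates_energy(self):
        y = np.arange(64)[:, None]
        grating = (128 + 100 * np.sin(2 * np.pi * y / 8)) * np.ones((1, 64))
        score = ps.anisotropy_score(_as_image(grating))
        assert score >= 4.0  # >= n_bins / 2

    def test_rotation_invariance(self):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(2), scale_px_per_cm=10.0)
        s1 = ps.anisotropy_score(img)
        s2 = ps.anisotropy_score(_as_image(np.rot90(img.pixels)))
        assert s1 == pytest.approx(s2, abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 4, 9])
    def test_matches_direct_summation_oracle(self, seed):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(seed), scale_px_per_cm=10.0)
        ours = ps.anisotropy_score(img)
        ref = direct_spectrum_score(img.pixels)
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_screening_rejects_grating_keeps_noise(self):
        y = np.arange(348)[:, None]
        grating = _as_image((128 + 100 * np.sin(2 * np.pi * y / 16)) * np.ones((1, 348)))
        noise = ps.perlin_noise_image(ps.make_gradient_lattice(7))
        kept = ps.screen_artifacts([grating, noise], threshold=2.5)
        assert kept == [noise]

    def test_infinite_threshold_keeps_all(self):
        imgs = [ps.perlin_noise_image(ps.make_gradient_lattice(s), scale_px_per_cm=5.0)
                for s in range(5)]
        assert ps.screen_artifacts(imgs, threshold=np.inf) == imgs

    def test_all_rejected_raises(self):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(1), scale_px_per_cm=5.0)
        with pytest.raises(InsufficientStimuliError):
            ps.screen_artifacts([img], threshold=1.0)

    def test_filter_matches_oracle_over_seed_battery(self):
        imgs = [ps.perlin_noise_image(ps.make_gradient_lattice(s), scale_px_per_cm=10.0)
                for s in range(50)]
        kept = ps.screen_artifacts(imgs, threshold=2.5)
        expected = [i for i in imgs if direct_spectrum_score(i.pixels) < 2.5]
        assert kept == expected


# ---------------------------------------------------------------------------
# target embedding


class TestEmbedTarget:
    def test_polarity_positive_on_dark_background(self, rng):
        img = _as_image(np.full((87, 87), 100))
        pair = ps.embed_target(img, 50, rng)
        assert pair.target.polarity == 1

    def test_polarity_negative_at_mean_tie(self, rng):
        img = _as_image(np.full((87, 87), 128))
        pair = ps.embed_target(img, 50, rng)
        assert pair.target.polarity == -1

    def test_difference_confined_to_target_support(self, stimulus_set):
        for pair in stimulus_set[:5]:
            base = pair.base.pixels.astype(int)
            tgt = pair.with_target.pixels.astype(int)
            diff = tgt - base
            assert np.max(np.abs(diff)) <= pair.strength
            x, y = pair.base.pixel_centers_cm()
            d2 = (x - pair.target.center_x_cm) ** 2 + (y - pair.target.center_y_cm) ** 2
            support = np.rint(pair.strength * np.exp(-d2 / (2 * pair.target.sigma_cm**2))) > 0
            assert not np.any(diff[~support])

    def test_center_respects_margin(self, stimulus_set):
        for pair in stimulus_set:
            for c in (pair.target.center_x_cm, pair.target.center_y_cm):
                assert 1.0 <= c <= pair.base.side_cm - 1.0

    def test_visible_diameter_about_2cm(self, rng):
        img = _as_image(np.full((348, 348), 100))
        pair = ps.embed_target(img, 40, rng)
        x, y = pair.base.pixel_centers_cm()
        d = np.hypot(x - pair.target.center_x_cm, y - pair.target.center_y_cm)
        changed = pair.with_target.pixels.astype(int) != pair.base.pixels.astype(int)
        max_r = d[changed].max()
        assert 0.9 <= max_r <= 1.1
        # analytic radius where the increment drops below one luminance step
        assert 0.35 * math.sqrt(2 * math.log(40)) == pytest.approx(0.9507, abs=1e-3)

    def test_zero_strength_leaves_image_unchanged(self, rng):
        img = ps.perlin_noise_image(ps.make_gradient_lattice(5), scale_px_per_cm=10.0)
        pair = ps.embed_target(img, 0, rng, allowed_strengths=None)
        assert np.array_equal(pair.base.pixels, pair.with_target.pixels)

    def test_invalid_strength_rejected(self, rng):
        img = _as_image(np.full((87, 87), 100))
        with pytest.raises(ValueError):
            ps.embed_target(img, 55, rng)


# ---------------------------------------------------------------------------
# stimulus set


class TestBuildStimulusSet:
    def test_counts_and_strength_histogram(self, stimulus_set):
        assert len(stimulus_set) == 30
        hist = {s: 0 for s in (40, 50, 60)}
        for p in stimulus_set:
            hist[p.strength] += 1
        assert hist == {40: 10, 50: 10, 60: 10}

    def test_determinism(self, small_set):
        again = ps.build_stimulus_set(n_pairs=3, seed=3, scale_px_per_cm=10.0)
        for a, b in zip(small_set, again):
            assert a.pair_id == b.pair_id
            assert np.array_equal(a.base.pixels, b.base.pixels)
            assert np.array_equal(a.with_target.pixels, b.with_target.pixels)
            assert a.target == b.target

    def test_indivisible_n_pairs_rejected(self):
        with pytest.raises(ValueError):
            ps.build_stimulus_set(n_pairs=31, seed=1)

    def test_screening_exhaustion_propagates(self):
        with pytest.raises(InsufficientStimuliError):
            ps.build_stimulus_set(n_pairs=3, seed=1, scale_px_per_cm=5.0,
                                  screening_threshold=1.0, max_candidates=6)

    def test_screened_scores_below_threshold(self, stimulus_set):
        assert all(p.base.anisotropy < 2.5 for p in stimulus_set)


# ---------------------------------------------------------------------------
# presentation formats


class TestPresentation:
    def test_horizontal_canvas_width(self, small_set):
        fmt = ps.standard_formats()["horizontal"]
        plan = ps.render_presentation(small_set[0], fmt)
        assert plan.canvas_cm == (8.7 + 3.0 + 8.7, 8.7)
        assert plan.remaining_image == "right"

    def test_vertical_canvas_and_remaining(self, small_set):
        plan = ps.render_presentation(small_set[0], ps.standard_formats()["vertical"])
        assert plan.canvas_cm == (8.7, 20.4)
        assert plan.remaining_image == "top"

    def test_isi200_cycle_1200ms_and_total_30s(self, small_set):
        plan = ps.render_presentation(small_set[0], ps.standard_formats()["seq_isi200"])
        durations = [d for _, d in plan.frames]
        assert sum(durations) == pytest.approx(30_000.0)
        # one cycle: image 400, blank 200, image 400, blank 200
        assert durations[:4] == [400.0, 200.0, 400.0, 200.0]
        assert plan.frames[1][0] == "blank"

    def test_isi0_has_no_blanks(self, small_set):
        plan = ps.render_presentation(small_set[0], ps.standard_formats()["seq_isi0"])
        assert all(name != "blank" for name, _ in plan.frames)
        assert sum(d for _, d in plan.frames) == pytest.approx(30_000.0)
        # images alternate
        names = [n for n, _ in plan.frames]
        assert names[0] != names[1] and names[0] == names[2]

    def test_format_invariants_enforced(self):
        with pytest.raises(ValueError):
            PresentationFormat("horizontal", separation_cm=3.0, frame_ms=400.0, isi_ms=0.0)
        with pytest.raises(ValueError):
            PresentationFormat("seq_isi0", separation_cm=3.0)
        with pytest.raises(ValueError):
            PresentationFormat("diagonal", separation_cm=3.0)


def test_one_cm_subtends_about_one_degree():
    assert round(visual_angle_deg(1.0, 60.0)) == 1
    assert visual_angle_deg(1.0, 60.0) == pytest.approx(0.955, abs=1e-3)
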