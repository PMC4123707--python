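"""Stimulus generator contracts: polygon areas, dot placement, the Gaussian
amplitude/energy law, trial-pair bookkeeping, blob textures, mixed textures
and aperture masking — each checked against an independent oracle."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from matplotlib.path import Path as MplPath
from scipy import ndimage

from numtex import stimuli
from numtex.stimuli import (GenConfig, PlacementError, RenderError,
                            StimulusError, apply_aperture, build_dot_pattern,
                            default_exclusion, gen_mixed_texture,
                            gen_noise_blob_stimulus, gen_trial_pair,
                            kitchen_sink_config, make_polygon, place_dots,
                            regular_polygon, render_centred, render_pattern)


def shoelace(verts):
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


class TestPolygons:
    def test_random_polygon_areas_match_shoelace_oracle(self, rng):
        for target in rng.uniform(5_000, 100_000, size=200):
            verts = make_polygon(target, rng)
            assert abs(shoelace(verts) - target) <= 0.02 * target

    def test_standard_area_within_two_percent(self, rng):
        for _ in range(50):
            verts = make_polygon(50_000, rng)
            assert 49_000 <= shoelace(verts) <= 51_000

    def test_regular_square_area_is_2r2(self):
        assert shoelace(regular_polygon(4, 10.0)) == pytest.approx(200.0)

    def test_nonpositive_area_rejected(self, rng):
        with pytest.raises(StimulusError):
            make_polygon(0.0, rng)
        with pytest.raises(StimulusError):
            make_polygon(-5.0, rng)

    @given(st.floats(min_value=1e3, max_value=1e5))
    def test_area_property(self, target):
        rng = np.random.default_rng(42)
        verts = make_polygon(target, rng)
        assert abs(shoelace(verts) - target) <= 0.02 * target


class TestPlacement:
    def test_zero_dots(self, rng):
        assert place_dots(regular_polygon(6, 50), 0, 8.0, rng).shape == (0, 2)

    def test_placement_constraints_against_oracles(self, rng):
        poly = make_polygon(50_000, rng)
        pts = place_dots(poly, 64, 8.0, rng)
        assert len(pts) == 64
        # point-in-polygon oracle
        assert MplPath(poly).contains_points(pts).all()
        # brute-force pairwise distance oracle
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0

    def test_infeasible_packing_raises(self, rng):
        poly = regular_polygon(4, math.sqrt(100 / 2))  # area 100 px^2
        with pytest.raises(PlacementError, match="exclusion"):
            place_dots(poly, 10_000, 5.0, rng, max_attempts=50_000)

    def test_default_exclusion_matches_stated_rule(self):
        # sparse regime: 4 * s_max; dense regime capped at 0.6 mean spacing
        assert default_exclusion(50_000, 64, 2.0) == pytest.approx(8.0)
        dense = default_exclusion(50_000, 128, 6.0)
        assert dense == pytest.approx(0.6 * math.sqrt(50_000 / 128))


class TestRendering:
    @pytest.mark.parametrize("s, peak", [(2.0, 0.4), (6.0, 0.4 * 2 / 6)])
    def test_peak_amplitude_law(self, s, peak):
        pat = stimuli.DotPattern(
            [stimuli.DotSpec(40.0, 40.0, s, stimuli.dot_amplitude(s))],
            regular_polygon(4, 30) + 40)
        img = render_pattern(pat, (81, 81))
        assert img.values.max() == pytest.approx(peak, rel=1e-3)

    def test_contrast_energy_invariant_to_blur(self):
        # discrete sum of squares vs analytic integral A(s)^2 * pi * s^2
        energies = []
        for s in [2.0, 3.0, 4.0, 5.0, 6.0]:
            a = stimuli.dot_amplitude(s)
            pat = stimuli.DotPattern(
                [stimuli.DotSpec(60.0, 60.0, s, a)], regular_polygon(4, 40) + 60)
            img = render_pattern(pat, (121, 121))
            e = np.sum(img.values ** 2)
            assert e == pytest.approx(a * a * math.pi * s * s, rel=0.01)
            energies.append(e)
        assert np.ptp(energies) / np.mean(energies) < 0.01

    def test_dot_outside_margin_raises(self):
        pat = stimuli.DotPattern(
            [stimuli.DotSpec(3.0, 40.0, 2.0, 0.4)], regular_polygon(4, 30) + 40)
        with pytest.raises(RenderError, match="dot 0"):
            render_pattern(pat, (81, 81))

    def test_count_integrity_at_half_peak(self, rng):
        pat = build_dot_pattern(make_polygon(50_000, rng), 64, 2.0, rng)
        img, _ = render_centred(pat)
        labels, n = ndimage.label(np.abs(img.values) >= 0.2,
                                  structure=np.ones((3, 3)))
        assert n == 64


class TestTrialPairs:
    def test_counts_and_condition_areas(self, rng):
        cfg = GenConfig(condition="density")
        pair = gen_trial_pair(cfg, 0.25, 1, rng)
        assert pair.standard_pattern.n_dots == 64
        assert pair.n_test == pair.test_pattern.n_dots == 80
        assert pair.test_pattern.area == pytest.approx(50_000, rel=0.02)

    def test_size_condition_matches_density_oracle(self, rng):
        cfg = GenConfig(condition="size")
        pair = gen_trial_pair(cfg, 0.50, 1, rng)
        assert pair.n_test == 96
        # density equality: n/area equal for test and standard
        assert pair.test_pattern.area == pytest.approx(1.5 * 50_000, rel=0.02)
        dens_s = 64 / pair.standard_pattern.area
        dens_t = pair.n_test / pair.test_pattern.area
        assert dens_t == pytest.approx(dens_s, rel=0.04)

    def test_off_grid_w_rejected(self, rng):
        with pytest.raises(StimulusError):
            gen_trial_pair(GenConfig(), 0.33, 1, rng)

    def test_kitchen_sink_flags(self, rng):
        cfg = kitchen_sink_config(vary_contrast=True)
        pair = gen_trial_pair(cfg, 0.20, 1, rng)
        assert pair.condition == "kitchen-sink"
        blurs = [d.s for d in pair.test_pattern.dots]
        assert np.std(blurs) > 0.3  # per-element blur variation
        assert 0.13 <= pair.contrast_test <= 1.0
        with pytest.raises(StimulusError):
            gen_trial_pair(cfg, 0.20, -1, rng)  # test must be more numerous

    def test_determinism_bit_identical(self):
        cfg = GenConfig(blur_mode="unequal")
        a = gen_trial_pair(cfg, 0.15, 1, np.random.default_rng(123))
        b = gen_trial_pair(cfg, 0.15, 1, np.random.default_rng(123))
        assert np.array_equal(a.standard_image.values, b.standard_image.values)
        assert np.array_equal(a.test_image.values, b.test_image.values)


def flood_fill_count(mask):
    """Independent BFS connected-component (8-connectivity) counter."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < h and 0 <= xx < w
                                    and mask[yy, xx] and not seen[yy, xx]):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
    return count


class TestNoiseBlobs:
    def test_constant_input_has_no_blobs(self, rng):
        _, _, n = gen_noise_blob_stimulus(2.0, 64, rng,
                                          noise=np.zeros((64, 64)))
        assert n == 0

    def test_blob_count_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            raw, _, n = gen_noise_blob_stimulus(2.0, 96, rng)
            mask = np.abs(raw.values - raw.values.mean()) >= raw.values.std()
            assert n == flood_fill_count(mask)

    def test_blob_count_decreases_with_blur_scale(self, rng):
        means = []
        for scale in (2.0, 3.0, 4.5):
            counts = [gen_noise_blob_stimulus(scale, 96, rng)[2]
                      for _ in range(12)]
            means.append(np.mean(counts))
        assert means[0] >= means[1] >= means[2]


class TestMixedTextures:
    def test_polarity_bookkeeping(self, rng):
        tex = gen_mixed_texture("polarity", 40, 24, rng)
        labs = [e["class"] for e in tex.elements]
        assert labs.count("a") == 40 and labs.count("b") == 24
        assert tex.image.values.min() < -0.1 < 0.1 < tex.image.values.max()

    def test_orientation_classes_are_orthogonal(self, rng):
        from numtex.filters import channel_energy, make_oriented_kernel
        k0 = make_oriented_kernel(2.0, 0.0)
        k90 = make_oriented_kernel(2.0, 90.0)
        pure_a = gen_mixed_texture("orientation", 32, 0, rng)
        assert (channel_energy(pure_a.image, k0).E
                > 5 * channel_energy(pure_a.image, k90).E)

    def test_total_count_jitter_range(self, rng):
        totals = {stimuli.draw_mixed_total(rng) for _ in range(1000)}
        assert min(totals) >= 64 and max(totals) <= 85
        assert len(totals) > 15  # actually spans the range

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(StimulusError):
            gen_mixed_texture("colour", 10, 10, rng)


class TestAperture:
    def test_extreme_radii(self, rng):
        pat = stimuli.gen_aperture_pattern(40, rng)
        _, nb, nw = apply_aperture(pat, 1e9)
        assert (nb, nw) == (40, 24)
        _, nb0, nw0 = apply_aperture(pat, 0.0)
        assert (nb0, nw0) == (0, 0)

    def test_visible_counts_match_distance_oracle(self, rng):
        for _ in range(20):
            B = int(rng.integers(10, 55))
            pat = stimuli.gen_aperture_pattern(B, rng)
            radius = float(rng.uniform(20, 150))
            img, nb, nw = apply_aperture(pat, radius)
            # oracle: recompute from the rendered canvas geometry
            cpat, _ = stimuli.centre_pattern(pat)
            h, w = img.values.shape
            cy, cx = (h - 1) / 2, (w - 1) / 2
            vis = [d for d in cpat.dots
                   if (d.x - cx) ** 2 + (d.y - cy) ** 2 <= radius ** 2]
            assert nb == sum(1 for d in vis if d.amplitude < 0)
            assert nw == sum(1 for d in vis if d.amplitude > 0)
            # masked region really is zero
            yy, xx = np.mgrid[0:h, 0:w]
            outside = (xx - cx) ** 2 + (yy - cy) ** 2 > radius ** 2
            assert np.all(img.values[outside] == 0)
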