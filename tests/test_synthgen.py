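"""Synthetic patch generator: formulas, mask construction, placement, determinism."""

import numpy as np
import pytest

from rnadotseg import synthgen as sg


class TestFormulas:
    @pytest.mark.parametrize("r,expected", [(0.0, 2), (1.0, 64), (0.5, 11)])
    def test_dot_count_endpoints_and_midpoint(self, r, expected):
        assert sg.sample_dot_count(r) == expected

    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (1.0, 0.4), (0.5, 0.1)])
    def test_scale_offset(self, r, expected):
        assert sg.sample_scale_offset(r) == pytest.approx(expected)

    @pytest.mark.parametrize("func", [sg.sample_dot_count, sg.sample_scale_offset])
    @pytest.mark.parametrize("bad", [-0.01, 1.01, 2.0])
    def test_domain_errors(self, func, bad):
        with pytest.raises(ValueError):
            func(bad)

    def test_dot_count_range_and_skew(self):
        rng = np.random.default_rng(0)
        counts = np.array([sg.sample_dot_count(r) for r in rng.random(100_000)])
        assert counts.min() >= 2 and counts.max() <= 64
        # exponential scale: median well below the arithmetic midpoint
        assert np.median(counts) <= 33

    def test_scale_offset_monotone(self):
        rs = np.linspace(0, 1, 101)
        vals = [sg.sample_scale_offset(r) for r in rs]
        assert np.all(np.diff(vals) >= 0)


class TestColour:
    def test_endpoints(self):
        assert sg.interpolate_primary_colour(0.0) == pytest.approx((225, 253, 255))
        assert sg.interpolate_primary_colour(1.0) == pytest.approx((160, 200, 217))

    def test_midpoint_unquantized(self):
        assert sg.interpolate_primary_colour(0.5) == pytest.approx((192.5, 226.5, 236.0))

    def test_domain(self):
        with pytest.raises(ValueError):
            sg.interpolate_primary_colour(1.5)


class TestMasks:
    @pytest.mark.parametrize("colour,centre", [
        ((225, 253, 255), (30, 2, 0)),
        ((160, 200, 217), (95, 55, 38)),
    ])
    def test_primary_centre_rescaled_to_opposite_colour(self, colour, centre):
        m = sg.make_primary_dot_mask(sg.DotColour(*colour))
        r, c = m.anchor
        assert m.values[r, c] == pytest.approx(centre, abs=1e-9)

    def test_values_zero_outside_blur_support(self):
        m = sg.make_primary_dot_mask(sg.DotColour(160, 200, 217))
        r, c = m.anchor
        yy, xx = np.mgrid[:m.values.shape[0], :m.values.shape[1]]
        outside = np.hypot(yy - r, xx - c) > 4.5
        assert np.all(m.values[outside] == 0)

    def test_decay_along_rays(self):
        m = sg.make_primary_dot_mask(sg.DotColour(160, 200, 217))
        r, c = m.anchor
        profile = m.values[r, c:c + 5, 0]
        assert np.all(np.diff(profile) <= 0)

    def test_secondary_mask(self):
        m = sg.make_secondary_dot_mask()
        r, c = m.anchor
        assert m.values[r, c] == pytest.approx((55, 45, 40))
        assert m.values[r, c].min() >= 40  # darkening of at least 40 per channel
        yy, xx = np.mgrid[:m.values.shape[0], :m.values.shape[1]]
        assert np.all(m.values[np.hypot(yy - r, xx - c) > 2.5] == 0)

    def test_combine_identity_and_offset(self):
        p = sg.make_primary_dot_mask(sg.DotColour(200, 200, 200))
        zero = sg.DotMask(values=np.zeros((5, 5, 3)), anchor=(2, 2),
                          dot_type="secondary")
        combined = sg.combine_masks(p, zero, (0, 0))
        np.testing.assert_array_equal(combined.values, p.values)

        s = sg.make_secondary_dot_mask()
        shifted = sg.combine_masks(p, s, (1, 0))
        pr, pc = p.anchor
        expected = p.values[pr, pc + 1] + s.values[s.anchor[0], s.anchor[1]]
        assert shifted.values[pr, pc + 1] == pytest.approx(np.minimum(expected, 255))

    def test_combine_clips_at_255(self):
        big = sg.DotMask(values=np.full((3, 3, 3), 200.0), anchor=(1, 1))
        combined = sg.combine_masks(big, big, (0, 0))
        assert combined.values.max() == 255.0

    def test_combine_offset_domain(self):
        p = sg.make_primary_dot_mask(sg.DotColour(200, 200, 200))
        with pytest.raises(ValueError):
            sg.combine_masks(p, sg.make_secondary_dot_mask(), (2, 0))


def _extent(mask, direction):
    nz = mask.values.sum(axis=2) > 1e-9
    return sg._radial_extent(nz, mask.anchor, direction)


class TestPerturb:
    def test_identity_parameters(self):
        m = sg.make_primary_dot_mask(sg.DotColour(180, 210, 230))
        params = sg.PerturbParams(cardinal_stretch=(0, 0, 0, 0), base_scale_x=1.0,
                                  base_scale_y=1.0, shared_offset=0.0,
                                  noise_low=1.0, noise_high=1.0, rotation=0)
        out = sg.perturb_dot(m, params)
        np.testing.assert_array_equal(out.values, m.values)

    def test_cardinal_stretch_extends_radial_extent(self):
        m = sg.make_primary_dot_mask(sg.DotColour(160, 200, 217))
        assert _extent(m, "+x") == 4  # 9x9 blur support radius
        params = sg.PerturbParams(cardinal_stretch=(3, 0, 0, 0), base_scale_x=1.0,
                                  base_scale_y=1.0, shared_offset=0.0,
                                  noise_low=1.0, noise_high=1.0, rotation=0)
        out = sg.perturb_dot(m, params)
        assert _extent(out, "+x") == 7
        assert _extent(out, "-x") == 4

    def test_noise_bounds(self, rng):
        m = sg.DotMask(values=np.full((7, 7, 3), 100.0), anchor=(3, 3))
        params = sg.PerturbParams(cardinal_stretch=(0, 0, 0, 0), base_scale_x=1.0,
                                  base_scale_y=1.0, shared_offset=0.0, rotation=0)
        out = sg.perturb_dot(m, params, rng)
        assert np.all(out.values >= 100 * 0.975 - 1e-9)
        assert np.all(out.values <= 100 * 1.025 + 1e-9)

    def test_scaling_shrinks_support(self):
        m = sg.make_primary_dot_mask(sg.DotColour(160, 200, 217))
        params = sg.PerturbParams(cardinal_stretch=(0, 0, 0, 0), base_scale_x=0.5,
                                  base_scale_y=0.5, shared_offset=0.0,
                                  noise_low=1.0, noise_high=1.0, rotation=0)
        out = sg.perturb_dot(m, params)
        assert out.values.shape[0] < m.values.shape[0]

    def test_sampled_params_within_ranges(self, rng):
        for _ in range(200):
            p = sg.sample_perturb_params(rng)
            assert all(0 <= s <= 3 for s in p.cardinal_stretch)
            assert 0.25 <= p.base_scale_x <= 0.5
            assert 0.25 <= p.base_scale_y <= 0.5
            assert 0.0 <= p.shared_offset <= 0.4
            assert 0 <= p.rotation <= 359


class TestPlanAndPlacement:
    def test_plan_ranges(self, rng):
        for _ in range(500):
            plan = sg.plan_patch(rng)
            assert 2 <= plan.n <= 64
            lo, hi = plan.colour_window
            assert hi - lo == pytest.approx(0.2)
            assert 0.0 <= lo and hi <= 1.0 + 1e-12
            if not plan.has_secondary:
                assert plan.secondary_prob == 0.0
            else:
                assert 0.0 <= plan.secondary_prob <= 0.5

    def test_secondary_fraction_matches_one_quarter(self):
        rng = np.random.default_rng(99)
        n = 10_000
        frac = sum(sg.plan_patch(rng).has_secondary for _ in range(n)) / n
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * sigma

    def test_separation_enforced(self, rng):
        coords = sg.place_dots(40, [], (100, 100), rng)
        pts = np.asarray(coords, dtype=float)
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 3.0

    def test_respects_existing_dots(self, rng):
        existing = [(10, 10)]
        coords = sg.place_dots(5, existing, (30, 30), rng)
        for x, y in coords:
            assert np.hypot(x - 10, y - 10) >= 3.0

    def test_overcrowded_patch_raises(self, rng):
        with pytest.raises(sg.PlacementError):
            sg.place_dots(64, [], (10, 10), rng)


class TestBackgroundAndComposition:
    def test_background_deterministic_and_shaped(self):
        a = sg.generate_background((64, 64), np.random.default_rng(5))
        b = sg.generate_background((64, 64), np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        assert a.shape == (64, 64, 3) and a.dtype == np.uint8

    def test_background_haematoxylin_hue(self):
        img = sg.generate_background((96, 96), np.random.default_rng(7))
        assert img[:, :, 0].mean() > img[:, :, 2].mean()  # blue > red (BGR)
        assert img.min() >= 100  # never darker than the darkest dot centre

    def test_apply_zero_mask_is_identity(self, rng):
        img = sg.generate_background((32, 32), rng)
        zero = sg.DotMask(values=np.zeros((5, 5, 3)), anchor=(2, 2))
        patch = sg.apply_dots(img, [(zero, (16, 16))])
        np.testing.assert_array_equal(patch.image, img)
        assert patch.dots == [(16, 16, "primary")]

    def test_apply_clips_at_zero(self):
        img = np.full((9, 9, 3), 10, dtype=np.uint8)
        heavy = sg.DotMask(values=np.full((3, 3, 3), 200.0), anchor=(1, 1))
        patch = sg.apply_dots(img, [(heavy, (4, 4))])
        assert patch.image.min() == 0

    def test_patch_determinism_bit_exact(self):
        p1 = sg.generate_patch(shape=(96, 96), seed=31)
        p2 = sg.generate_patch(shape=(96, 96), seed=31)
        np.testing.assert_array_equal(p1.image, p2.image)
        assert p1.dots == p2.dots

    def test_patch_subtractive_vs_background(self, example_patch):
        bg = sg.generate_background((96, 96), np.random.default_rng(2024))
        assert np.all(example_patch.image.astype(int) <= bg.astype(int))

    def test_patch_separation_bruteforce(self, example_patch):
        pts = np.asarray([(x, y) for x, y, _ in example_patch.dots], dtype=float)
        if len(pts) > 1:
            d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                         pts[:, None, 1] - pts[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 3.0

    def test_dots_inside_bounds(self, example_patch):
        H, W = example_patch.image.shape[:2]
        for x, y, _ in example_patch.dots:
            assert 0 <= x < W and 0 <= y < H
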