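"""Contourlet transform: perfect reconstruction, directionality, equivalent
filters and noise-variance propagation."""

import numpy as np
import pytest

from pgchmm.contourlet import (
    ContourletConfig,
    VariancePropagator,
    contourlet_forward,
    contourlet_inverse,
    dfb_decompose,
    dfb_reconstruct,
    equivalent_filters,
    load_pyramid,
    lp_decompose,
    lp_reconstruct,
    propagate_variance,
    save_pyramid,
)


def _max_rel_err(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-300)


class TestLaplacianPyramid:
    def test_zero_image_gives_zero_bands(self):
        bands, low = lp_decompose(np.zeros((64, 64)), 3)
        assert all(np.all(b == 0) for b in bands) and np.all(low == 0)

    @pytest.mark.parametrize("lp_filter", ["9/7", "db8"])
    def test_perfect_reconstruction(self, lp_filter, rng):
        x = rng.standard_normal((64, 96))
        bands, low = lp_decompose(x, 3, lp_filter)
        xr = lp_reconstruct(bands, low, lp_filter)
        assert _max_rel_err(xr, x) < 1e-9

    def test_impulse_band_matches_equivalent_filter_shift(self):
        # the level-1 bandpass of a shifted impulse is the shifted bandpass
        # of a centred impulse (covariance under even shifts)
        x = np.zeros((64, 64))
        x[32, 32] = 1.0
        b1 = lp_decompose(x, 1)[0][0]
        x2 = np.zeros((64, 64))
        x2[34, 36] = 1.0
        b2 = lp_decompose(x2, 1)[0][0]
        np.testing.assert_allclose(np.roll(b1, (2, 4), axis=(0, 1)), b2, atol=1e-12)

    def test_divisibility_guard(self):
        with pytest.raises(ValueError):
            lp_decompose(np.zeros((66, 64)), 2)

    def test_too_many_levels_guard(self):
        with pytest.raises(ValueError):
            lp_decompose(np.zeros((64, 64)), 4)  # would leave a 4-px lowpass


class TestDFB:
    @pytest.mark.parametrize("depth", [1, 2, 3, 4])
    @pytest.mark.parametrize("shape", [(64, 64), (64, 32), (48, 64)])
    def test_perfect_reconstruction_and_critical_sampling(self, depth, shape, rng):
        if min(shape) < 4 * 2 ** (depth - 1):
            pytest.skip("grid too small for this depth")
        x = rng.standard_normal(shape)
        subs = dfb_decompose(x, depth)
        assert sum(s.size for s in subs) == x.size
        assert len(subs) == 2**depth
        xr = dfb_reconstruct(subs, depth, shape)
        assert _max_rel_err(xr, x) < 1e-9

    def test_zero_input_zero_subbands(self):
        subs = dfb_decompose(np.zeros((32, 32)), 2)
        assert all(np.all(s == 0) for s in subs)

    def test_horizontal_sinusoid_energy_concentrates(self):
        # oscillation along columns -> frequency on the f_c axis
        n = 64
        x = np.cos(2 * np.pi * 12 * np.arange(n)[None, :] / n) * np.ones((n, 1))
        subs = dfb_decompose(x, 2)
        en = np.array([np.sum(s**2) for s in subs])
        assert en.max() / en.sum() >= 0.9

    def test_linearity(self, rng):
        x = rng.standard_normal((32, 32))
        y = rng.standard_normal((32, 32))
        sx = dfb_decompose(x, 2)
        sy = dfb_decompose(y, 2)
        sxy = dfb_decompose(2.0 * x - 3.0 * y, 2)
        for a, b, c in zip(sx, sy, sxy):
            np.testing.assert_allclose(2.0 * a - 3.0 * b, c, atol=1e-10)


class TestFullTransform:
    @pytest.mark.parametrize("dirs", [2, 4, 8])
    def test_perfect_reconstruction_battery(self, dirs, rng, phantom_128):
        cfg = ContourletConfig(levels=3, dirs_per_scale=dirs)
        battery = {
            "impulse": np.eye(128)[:, ::-1] * 0,
            "constant": np.full((128, 128), 3.3),
            "random": rng.standard_normal((128, 128)),
            "phantom": phantom_128.values,
        }
        battery["impulse"][64, 64] = 1.0
        for name, x in battery.items():
            pyr = contourlet_forward(x, cfg)
            xr = contourlet_inverse(pyr)
            assert _max_rel_err(xr, x) < 1e-6, name

    def test_linearity(self, rng):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        x = rng.standard_normal((64, 64))
        p1 = contourlet_forward(x, cfg)
        p2 = contourlet_forward(2.5 * x, cfg)
        for s1, s2 in zip(p1.scales, p2.scales):
            for a, b in zip(s1, s2):
                np.testing.assert_allclose(2.5 * a.coeffs, b.coeffs, atol=1e-9)
        np.testing.assert_allclose(2.5 * p1.lowpass, p2.lowpass, atol=1e-9)

    def test_redundancy_is_four_thirds(self, phantom_256):
        cfg = ContourletConfig(levels=5, dirs_per_scale=4)
        pyr = contourlet_forward(phantom_256.values, cfg)
        ratio = pyr.n_coefficients() / phantom_256.values.size
        # LP adds 1/4 + 1/16 + ... -> 4/3 in the limit; DFB is critical
        assert abs(ratio - 4 / 3) < 0.01

    def test_roundtrip_serialization(self, tmp_path, rng):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        pyr = contourlet_forward(rng.standard_normal((64, 64)), cfg)
        save_pyramid(tmp_path / "p.npz", pyr)
        back = load_pyramid(tmp_path / "p.npz")
        np.testing.assert_allclose(back.lowpass, pyr.lowpass)
        np.testing.assert_allclose(
            back.scales[0][2].coeffs, pyr.scales[0][2].coeffs
        )


class TestEquivalentFilters:
    def test_filters_reproduce_forward_coefficients(self, rng):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        shape = (32, 32)
        x = rng.standard_normal(shape)
        pyr = contourlet_forward(x, cfg)
        filters = equivalent_filters(shape, cfg)
        for scale in pyr.scales:
            for sb in scale:
                entries = filters[(sb.scale_index, sb.direction_index)]
                e = entries[0]
                # coefficient at the anchor equals <h, x>
                i0, j0 = np.argwhere(
                    (sb.level_rows * (1 << (sb.scale_index - 1)) == e["anchor"][0])
                    & (sb.level_cols * (1 << (sb.scale_index - 1)) == e["anchor"][1])
                )[0]
                assert sb.coeffs[i0, j0] == pytest.approx(
                    float(np.sum(e["filter"] * x)), abs=1e-9
                )

    def test_constant_input_matches_filter_sums(self):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        shape = (32, 32)
        c = 2.7
        pyr = contourlet_forward(np.full(shape, c), cfg)
        filters = equivalent_filters(shape, cfg)
        for scale in pyr.scales:
            for sb in scale:
                h = filters[(sb.scale_index, sb.direction_index)][0]["filter"]
                # every coefficient of a constant image equals c * sum(h)
                assert np.allclose(sb.coeffs, c * h.sum(), atol=1e-9)


class TestVariancePropagation:
    def test_zero_map_gives_zero_pyramid(self):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        vp = propagate_variance(np.zeros((32, 32)), cfg)
        assert np.all(vp.lowpass == 0)
        assert all(np.all(v == 0) for sc in vp.scales for v in sc)

    def test_negative_variance_rejected(self):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        with pytest.raises(ValueError):
            propagate_variance(np.full((32, 32), -1.0), cfg)

    def test_constant_map_matches_squared_filter_sums(self):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        shape = (32, 32)
        v0 = 3.0
        vp = propagate_variance(np.full(shape, v0), cfg)
        filters = equivalent_filters(shape, cfg)
        for j, sc in enumerate(vp.scales, start=1):
            for d, v in enumerate(sc):
                entries = filters[(j, d)]
                assert len(entries) == 1  # diagonal lattices: single phase
                expect = v0 * np.sum(entries[0]["filter"] ** 2)
                np.testing.assert_allclose(v, expect, rtol=1e-9)

    def test_matches_monte_carlo_stationary_and_signal_dependent(self, rng):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        shape = (48, 48)
        for vmap in (np.full(shape, 2.0), 0.5 + 2.0 * rng.random(shape)):
            vp = VariancePropagator(shape, cfg)
            pred = vp.propagate(vmap)
            m = 1500
            acc = None
            for _ in range(m):
                noise = rng.standard_normal(shape) * np.sqrt(vmap)
                p = contourlet_forward(noise, cfg)
                sq = [sb.coeffs**2 for sc in p.scales for sb in sc]
                acc = sq if acc is None else [a + s for a, s in zip(acc, sq)]
            emp = [a / m for a in acc]
            prd = [v for sc in pred.scales for v in sc]
            for e, p_ in zip(emp, prd):
                rel = np.abs(e - p_) / np.maximum(p_, 1e-12)
                assert np.median(rel) < 0.05

    def test_shift_reuse_is_exact(self, rng):
        cfg = ContourletConfig(levels=2, dirs_per_scale=4)
        shape = (32, 32)
        vmap = 0.1 + rng.random(shape)
        vp = VariancePropagator(shape, cfg)
        a = vp.propagate(np.roll(vmap, (3, 5), axis=(0, 1)))
        b = vp.propagate(vmap, shift=(3, 5))
        np.testing.assert_allclose(a.lowpass, b.lowpass, atol=1e-12)
        for sa, sb_ in zip(a.scales, b.scales):
            for va, vb in zip(sa, sb_):
                np.testing.assert_allclose(va, vb, atol=1e-12)
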