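"""Hidden Markov tree: structure, EM, sampling, shrinkage."""

import numpy as np
import pytest

from pgchmm.contourlet import ContourletConfig, ContourletPyramid, Subband, VariancePyramid
from pgchmm.hmt import (
    EMConfig,
    HMTParams,
    build_trees,
    build_trees_from_shapes,
    em_train,
    sample_hmt,
    shrink,
)


def _shapes(levels, root, dirs=1):
    return {
        (j, d): (root[0] * 2 ** (levels - j), root[1] * 2 ** (levels - j))
        for j in range(levels, 0, -1)
        for d in range(dirs)
    }


def _true_params(levels, dirs=1, v=(1.0, 25.0), diag=0.9, prior2=0.2):
    eps = np.array([[diag, 1 - diag], [1 - diag, diag]])
    return HMTParams(
        variances={(j, d): np.array(v) for j in range(1, levels + 1) for d in range(dirs)},
        transitions={(j, d): eps for j in range(1, levels) for d in range(dirs)},
        root_priors={(levels, d): np.array([1 - prior2, prior2]) for d in range(dirs)},
        levels=levels,
    )


def _pyramid_from(coeffs, levels, dirs=1, noise_sd=0.0, rng=None):
    cfg = ContourletConfig(levels=levels, dirs_per_scale=max(2, dirs))
    scales = []
    for j in range(1, levels + 1):
        row = []
        for d in range(dirs):
            c = coeffs[(j, d)].astype(float)
            if noise_sd:
                c = c + rng.standard_normal(c.shape) * noise_sd
            h, w = c.shape
            R = np.repeat(np.arange(h)[:, None], w, 1)
            C = np.repeat(np.arange(w)[None, :], h, 0)
            row.append(Subband(c, j, d, R, C, "diag", (h, w)))
        scales.append(row)
    return ContourletPyramid(np.zeros((8, 8)), scales, cfg, (0, 0))


def _noise_pyr(shapes, levels, dirs, value):
    return VariancePyramid(
        np.zeros((8, 8)),
        [[np.full(shapes[(j, d)], value) for d in range(dirs)] for j in range(1, levels + 1)],
    )


class TestTreeStructure:
    def test_same_direction_counts_and_parents(self):
        cfg = ContourletConfig(levels=3, dirs_per_scale=4)
        from pgchmm.contourlet import contourlet_forward

        pyr = contourlet_forward(np.zeros((64, 64)), cfg)
        trees = build_trees(pyr)
        roots = np.flatnonzero(trees.parent < 0)
        # roots live exactly at the coarsest scale
        assert np.all(trees.scale[roots] == 3)
        # every non-root has a parent one scale coarser
        nr = np.flatnonzero(trees.parent >= 0)
        assert np.all(trees.scale[trees.parent[nr]] == trees.scale[nr] + 1)
        # each parent has exactly 4 children
        counts = np.bincount(trees.parent[nr], minlength=trees.n_nodes)
        assert np.all(counts[trees.scale > 1] == 4)
        assert np.all(counts[trees.scale == 1] == 0)

    def test_split_direction_mapping(self):
        shapes = _shapes(2, (4, 4), dirs=4)
        trees = build_trees_from_shapes(shapes, 2, "split_direction")
        nr = np.flatnonzero(trees.parent >= 0)
        counts = np.bincount(trees.parent[nr], minlength=trees.n_nodes)
        assert np.all(counts[trees.scale == 2] == 4)
        # children of a parent with direction d live in two subbands: the
        # pair (0,1) for d in {0,2}, the pair (2,3) for d in {1,3}
        for d in range(4):
            pids = trees.node_of[(2, d)]
            kid_dirs = set()
            for cd in range(4):
                ids = trees.node_of[(1, cd)]
                if np.any(np.isin(trees.parent[ids.ravel()], pids.ravel())):
                    kid_dirs.add(cd)
            assert kid_dirs == ({0, 1} if d in (0, 2) else {2, 3})

    def test_incompatible_shapes_rejected(self):
        shapes = {(2, 0): (4, 4), (1, 0): (12, 12)}
        with pytest.raises(ValueError):
            build_trees_from_shapes(shapes, 2)


class TestSampling:
    def test_root_marginal_matches_prior(self):
        trees = build_trees_from_shapes(_shapes(3, (32, 32)), 3)
        states, _ = sample_hmt(_true_params(3, prior2=0.2), trees, seed=4)
        frac = states[(3, 0)].mean()
        # binomial 3-sigma band at n=1024
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 1024)

    def test_full_persistence_copies_states(self):
        trees = build_trees_from_shapes(_shapes(3, (8, 8)), 3)
        states, _ = sample_hmt(_true_params(3, diag=1.0), trees, seed=0)
        for j in (1, 2):
            parent_states = states[(j + 1, 0)]
            child = states[(j, 0)]
            h, w = child.shape
            R = np.repeat(np.arange(h)[:, None], w, 1) // 2
            C = np.repeat(np.arange(w)[None, :], h, 0) // 2
            np.testing.assert_array_equal(child, parent_states[R, C])

    def test_pooled_variance_matches_mixture_moment(self):
        trees = build_trees_from_shapes(_shapes(2, (64, 64)), 2)
        params = _true_params(2, v=(1.0, 25.0), diag=0.5, prior2=0.3)
        states, coeffs = sample_hmt(params, trees, seed=8)
        w = coeffs[(1, 0)].ravel()
        # stationary state-2 probability is 0.3 at the root and mixes toward
        # 0.5 under diag=0.5 transitions; measure against the realized states
        s = states[(1, 0)].ravel()
        expect = np.mean(np.where(s == 1, 25.0, 1.0))
        assert abs(w.var() - expect) / expect < 0.1

    def test_seed_determinism(self):
        trees = build_trees_from_shapes(_shapes(2, (8, 8)), 2)
        p = _true_params(2)
        _, c1 = sample_hmt(p, trees, seed=5)
        _, c2 = sample_hmt(p, trees, seed=5)
        np.testing.assert_array_equal(c1[(1, 0)], c2[(1, 0)])


class TestEM:
    def test_degenerate_single_state_recovery(self):
        # both states forced equal: EM must recover the common variance
        levels = 3
        trees = build_trees_from_shapes(_shapes(levels, (16, 16)), levels)
        params = _true_params(levels, v=(4.0, 4.0), diag=0.5, prior2=0.5)
        _, coeffs = sample_hmt(params, trees, seed=2)
        pyr = _pyramid_from(coeffs, levels)
        fit, post, trace = em_train(pyr, None, trees, EMConfig(max_iter=300, tol=1e-9))
        assert np.all(np.diff(trace) >= -1e-9 * np.abs(trace[:-1]))
        # at an EM fixed point the posterior-pooled variance equals the
        # sample second moment, which estimates the common variance (the
        # coarsest subbands have few samples, so compare against the
        # empirical moment there)
        for j in range(1, levels + 1):
            v = fit.variances[(j, 0)]
            mix = post.subband(j, 0)[..., 1].mean()
            pooled = v[0] * (1 - mix) + v[1] * mix
            emp = float(np.mean(coeffs[(j, 0)] ** 2))
            assert abs(pooled - emp) / emp < 0.02
        finest = fit.variances[(1, 0)]
        mix = post.subband(1, 0)[..., 1].mean()
        assert abs(finest[0] * (1 - mix) + finest[1] * mix - 4.0) / 4.0 < 0.05

    def test_clean_fixture_recovery(self):
        levels = 4
        trees = build_trees_from_shapes(_shapes(levels, (32, 32)), levels)
        truth = _true_params(levels)
        _, coeffs = sample_hmt(truth, trees, seed=3)
        pyr = _pyramid_from(coeffs, levels)
        fit, post, trace = em_train(pyr, None, trees, EMConfig(max_iter=100, tol=1e-6))
        assert np.all(np.diff(trace) >= -1e-9 * np.abs(trace[:-1]))
        for j in range(1, levels + 1):
            v = fit.variances[(j, 0)]
            assert abs(v[0] - 1.0) < 0.15 and abs(v[1] - 25.0) / 25.0 < 0.15
        for j in range(1, levels):
            eps = fit.transitions[(j, 0)]
            assert abs(eps[0, 0] - 0.9) < 0.1 and abs(eps[1, 1] - 0.9) < 0.1

    def test_posteriors_normalized(self):
        levels = 3
        trees = build_trees_from_shapes(_shapes(levels, (8, 8)), levels)
        _, coeffs = sample_hmt(_true_params(levels), trees, seed=1)
        pyr = _pyramid_from(coeffs, levels)
        _, post, _ = em_train(pyr, None, trees, EMConfig(max_iter=10))
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)
        assert post.gamma.min() >= 0.0

    def test_noise_aware_beats_noise_blind(self):
        levels = 3
        trees = build_trees_from_shapes(_shapes(levels, (32, 32)), levels)
        truth = _true_params(levels)
        shapes = _shapes(levels, (32, 32))
        errs_aware, errs_blind = [], []
        for seed in range(3):
            _, coeffs = sample_hmt(truth, trees, seed=seed)
            rng = np.random.default_rng(100 + seed)
            pyr = _pyramid_from(coeffs, levels, noise_sd=2.0, rng=rng)
            nv = _noise_pyr(shapes, levels, 1, 4.0)
            cfgem = EMConfig(max_iter=150, tol=1e-7)
            fit_a, _, _ = em_train(pyr, nv, trees, cfgem)
            fit_b, _, _ = em_train(pyr, None, trees, cfgem)

            def err(fit):
                return np.mean(
                    [
                        abs(fit.variances[(j, 0)][1] - 25.0) / 25.0
                        + abs(fit.variances[(j, 0)][0] - 1.0)
                        for j in range(1, levels + 1)
                    ]
                )

            errs_aware.append(err(fit_a))
            errs_blind.append(err(fit_b))
        assert np.median(errs_aware) < np.median(errs_blind)

    def test_recovery_improves_with_field_size(self):
        errs = []
        for root in (16, 32):
            trees = build_trees_from_shapes(_shapes(3, (root, root)), 3)
            e = []
            for seed in range(3):
                _, coeffs = sample_hmt(_true_params(3), trees, seed=seed)
                pyr = _pyramid_from(coeffs, 3)
                fit, _, _ = em_train(pyr, None, trees, EMConfig(max_iter=100, tol=1e-6))
                e.append(
                    np.mean(
                        [
                            abs(fit.variances[(j, 0)][1] - 25.0) / 25.0
                            for j in range(1, 4)
                        ]
                    )
                )
            errs.append(np.median(e))
        assert errs[1] < errs[0]


class TestShrinkage:
    def _simple_setup(self):
        levels = 2
        trees = build_trees_from_shapes(_shapes(levels, (8, 8)), levels)
        _, coeffs = sample_hmt(_true_params(levels), trees, seed=0)
        pyr = _pyramid_from(coeffs, levels)
        return levels, trees, pyr

    def test_zero_noise_gains_are_one(self):
        levels, trees, pyr = self._simple_setup()
        nv = _noise_pyr(_shapes(levels, (8, 8)), levels, 1, 0.0)
        fit, post, _ = em_train(pyr, nv, trees, EMConfig(max_iter=5))
        out = shrink(pyr, nv, post, fit)
        for sc_in, sc_out in zip(pyr.scales, out.scales):
            np.testing.assert_allclose(sc_out[0].coeffs, sc_in[0].coeffs, atol=1e-9)

    def test_hand_computed_posterior_gain(self):
        # w=2, posteriors (0.3, 0.7), state variances (1, 9), noise 1:
        # 0.3*(1/2)*2 + 0.7*(9/10)*2 = 1.56
        gain = 0.3 * (1 / (1 + 1)) + 0.7 * (9 / (9 + 1))
        assert 2.0 * gain == pytest.approx(1.56)
        levels, trees, pyr = self._simple_setup()
        nv = _noise_pyr(_shapes(levels, (8, 8)), levels, 1, 1.0)
        fit, post, _ = em_train(pyr, nv, trees, EMConfig(max_iter=3))
        fit.variances = {k: np.array([1.0, 9.0]) for k in fit.variances}
        post.gamma[:] = [0.3, 0.7]
        pyr2 = pyr.map_coeffs(lambda sb: np.full(sb.coeffs.shape, 2.0))
        out = shrink(pyr2, nv, post, fit)
        np.testing.assert_allclose(out.scales[0][0].coeffs, 1.56, atol=1e-12)

    def test_contraction_property(self):
        levels, trees, pyr = self._simple_setup()
        nv = _noise_pyr(_shapes(levels, (8, 8)), levels, 1, 2.0)
        fit, post, _ = em_train(pyr, nv, trees, EMConfig(max_iter=10))
        out = shrink(pyr, nv, post, fit)
        for sc_in, sc_out in zip(pyr.scales, out.scales):
            assert np.all(np.abs(sc_out[0].coeffs) <= np.abs(sc_in[0].coeffs) + 1e-12)

    def test_zero_signal_variances_zero_details(self):
        levels, trees, pyr = self._simple_setup()
        nv = _noise_pyr(_shapes(levels, (8, 8)), levels, 1, 1.0)
        fit, post, _ = em_train(pyr, nv, trees, EMConfig(max_iter=3))
        fit.variances = {k: np.array([0.0, 0.0]) for k in fit.variances}
        out = shrink(pyr, nv, post, fit)
        for sc in out.scales:
            np.testing.assert_allclose(sc[0].coeffs, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.lowpass, pyr.lowpass)  # lowpass untouched
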