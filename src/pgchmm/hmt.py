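"""Two-state zero-mean Gaussian-mixture hidden Markov tree (HMT) over
contourlet coefficients.

Each coefficient has a hidden state (1 = "small", 2 = "large" variance);
states propagate across scale through parent-child links (persistence), and
the coefficient is conditionally ``N(0, sigma2_state)``.  Observed noisy
coefficients add a known per-coefficient noise variance, so the observation
likelihood of state ``m`` is ``N(w; 0, sigma2_state + sigma2_noise)``.
Training uses expectation-maximization with the exact upward-downward
(sum-product) E-step on the coefficient quad-trees; parameters are tied per
subband (state variances), per scale-pair (transition matrices) and per
coarsest subband (root priors) so that one image suffices to fit them.
Denoising is the posterior-weighted Wiener shrinkage of each coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .contourlet import ContourletPyramid, VariancePyramid

__all__ = [
    "TreeIndex",
    "HMTParams",
    "PosteriorField",
    "EMConfig",
    "build_trees",
    "build_trees_from_shapes",
    "em_train",
    "sample_hmt",
    "shrink",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# tree construction
# --------------------------------------------------------------------------


@dataclass
class TreeIndex:
    """Flat-array forest over all directional subbands.

    ``node_of[(scale, dir)]`` maps each coefficient position to its node id;
    ``parent`` holds the parent node id (-1 at roots, which live at the
    coarsest scale).  ``group`` is the subband id used for parameter tying
    (state variances and the transition matrix into that subband).
    """

    n_nodes: int
    parent: np.ndarray
    scale: np.ndarray
    group: np.ndarray
    node_of: dict
    group_key: list           # group id -> (scale, dir)
    levels: int
    mapping_mode: str

    def nodes_at_scale(self, j: int) -> np.ndarray:
        lo, hi = self.scale_range(j)
        return np.arange(lo, hi)

    def scale_range(self, j: int) -> tuple:
        """Nodes are allocated coarse-to-fine, so each scale is one
        contiguous id range [lo, hi)."""
        if not hasattr(self, "_ranges"):
            ranges = {}
            for jj in range(1, self.levels + 1):
                w = np.flatnonzero(self.scale == jj)
                ranges[jj] = (int(w[0]), int(w[-1]) + 1)
            self._ranges = ranges
        return self._ranges[j]

    def group_range(self, gi: int) -> tuple:
        """Groups (subbands) are also allocated contiguously."""
        if not hasattr(self, "_granges"):
            granges = {}
            for g in range(len(self.group_key)):
                w = np.flatnonzero(self.group == g)
                granges[g] = (int(w[0]), int(w[-1]) + 1)
            self._granges = granges
        return self._granges[gi]


def build_trees_from_shapes(
    shapes: dict, levels: int, mapping_mode: str = "same_direction"
) -> TreeIndex:
    """Build the quad-tree forest from subband shapes.

    ``shapes`` maps ``(scale, dir)`` to the subband array shape; scale
    ``levels`` is coarsest (roots).  ``same_direction`` links each coarse
    coefficient to its 2x2 block of children in the same direction index;
    ``split_direction`` distributes the four children over the two finer
    subbands sharing the parent's orientation (two spatial children in
    each), which requires four directions per scale.
    """
    if levels < 2:
        raise ValueError("need at least 2 directional scales for trees")
    if mapping_mode not in ("same_direction", "split_direction"):
        raise ValueError(f"unknown mapping mode {mapping_mode!r}")
    dirs = sorted({d for (_, d) in shapes})
    if mapping_mode == "split_direction" and dirs != [0, 1, 2, 3]:
        raise ValueError("split_direction mapping requires exactly 4 directions")

    node_of = {}
    group_key = []
    group_arrs = []
    scale_arrs = []
    total = 0
    for j in range(levels, 0, -1):
        for d in dirs:
            shp = shapes[(j, d)]
            ids = np.arange(total, total + shp[0] * shp[1]).reshape(shp)
            node_of[(j, d)] = ids
            group_key.append((j, d))
            g = len(group_key) - 1
            group_arrs.append(np.full(ids.size, g))
            scale_arrs.append(np.full(ids.size, j))
            total += ids.size

    parent = np.full(total, -1, dtype=np.int64)
    for j in range(levels - 1, 0, -1):
        for d in dirs:
            ids = node_of[(j, d)]
            h, w = ids.shape
            R = np.repeat(np.arange(h)[:, None], w, axis=1)
            C = np.repeat(np.arange(w)[None, :], h, axis=0)
            if mapping_mode == "same_direction":
                pids = node_of[(j + 1, d)]
                if pids.shape != (h // 2, w // 2):
                    raise ValueError(
                        f"subband shapes at scales {j} and {j + 1} are not 2:1"
                    )
                parent[ids.ravel()] = pids[R // 2, C // 2].ravel()
            else:
                # child subband d receives parents of two directions,
                # alternating by column parity
                pdirs = (0, 2) if d in (0, 1) else (1, 3)
                pd = np.where(C % 2 == 0, pdirs[0], pdirs[1])
                for pdir in pdirs:
                    pids = node_of[(j + 1, pdir)]
                    if pids.shape != (h // 2, w // 2):
                        raise ValueError(
                            f"subband shapes at scales {j} and {j + 1} are not 2:1"
                        )
                    sel = pd == pdir
                    parent[ids[sel]] = pids[R[sel] // 2, C[sel] // 2]

    return TreeIndex(
        n_nodes=total,
        parent=parent,
        scale=np.concatenate(scale_arrs),
        group=np.concatenate(group_arrs),
        node_of=node_of,
        group_key=group_key,
        levels=levels,
        mapping_mode=mapping_mode,
    )


def build_trees(pyramid: ContourletPyramid, mapping_mode: str = "same_direction") -> TreeIndex:
    """Tree forest over the directional subbands of a pyramid."""
    shapes = {
        (sb.scale_index, sb.direction_index): sb.coeffs.shape
        for scale in pyramid.scales
        for sb in scale
    }
    return build_trees_from_shapes(shapes, pyramid.config.levels, mapping_mode)


# --------------------------------------------------------------------------
# parameters and posteriors
# --------------------------------------------------------------------------


@dataclass
class HMTParams:
    """Tied HMT parameters.

    ``variances[(j, d)]`` are the two state variances (state 2 the larger);
    ``transitions[(j, d)]`` is the 2x2 matrix ``eps[m, r] = P(child state m |
    parent state r)`` into subband (j, d) (columns sum to one); root priors
    are attached to the coarsest subbands.  Means are fixed at zero.
    """

    variances: dict
    transitions: dict
    root_priors: dict
    levels: int
    mapping_mode: str = "same_direction"

    def validate(self) -> None:
        for v in self.variances.values():
            if len(v) != 2 or np.any(np.asarray(v) <= 0):
                raise ValueError("state variances must be positive pairs")
        for eps in self.transitions.values():
            eps = np.asarray(eps)
            if eps.shape != (2, 2) or not np.allclose(eps.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError("transition columns must sum to 1")
        for p in self.root_priors.values():
            if not np.isclose(np.sum(p), 1.0, atol=1e-8):
                raise ValueError("root priors must sum to 1")

    def to_json(self) -> str:
        def enc(d):
            return {f"{k[0]},{k[1]}": np.asarray(v).tolist() for k, v in d.items()}

        return json.dumps(
            {
                "variances": enc(self.variances),
                "transitions": enc(self.transitions),
                "root_priors": enc(self.root_priors),
                "levels": self.levels,
                "mapping_mode": self.mapping_mode,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "HMTParams":
        raw = json.loads(s)

        def dec(d):
            return {
                tuple(int(x) for x in k.split(",")): np.asarray(v)
                for k, v in d.items()
            }

        return cls(
            dec(raw["variances"]),
            dec(raw["transitions"]),
            dec(raw["root_priors"]),
            raw["levels"],
            raw["mapping_mode"],
        )


@dataclass
class PosteriorField:
    """Posterior state probabilities ``P(S_i = m | w, theta)`` per node."""

    gamma: np.ndarray        # (n_nodes, 2)
    trees: TreeIndex

    def subband(self, scale: int, direction: int) -> np.ndarray:
        ids = self.trees.node_of[(scale, direction)]
        return self.gamma[ids]


@dataclass(frozen=True)
class EMConfig:
    max_iter: int = 50
    tol: float = 1e-5
    var_floor_frac: float = 1e-8


# --------------------------------------------------------------------------
# EM internals
# --------------------------------------------------------------------------


def _gather_coeffs(pyramid: ContourletPyramid, trees: TreeIndex) -> np.ndarray:
    w = np.empty(trees.n_nodes)
    for scale in pyramid.scales:
        for sb in scale:
            w[trees.node_of[(sb.scale_index, sb.direction_index)]] = sb.coeffs
    return w


def _gather_noise(noise_vars, trees: TreeIndex) -> np.ndarray:
    nv = np.zeros(trees.n_nodes)
    if noise_vars is None:
        return nv
    for (j, d), ids in trees.node_of.items():
        nv[ids] = noise_vars.scales[j - 1][d]
    return nv


def _init_params(w, nv, trees: TreeIndex, floor_frac):
    G = len(trees.group_key)
    sv = np.empty((G, 2))
    floors = np.empty(G)
    for g in range(G):
        lo, hi = trees.group_range(g)
        sel = slice(lo, hi)
        e2 = float(np.mean(w[sel] ** 2))
        base = max(e2 - float(np.mean(nv[sel])), 0.0)
        floor = max(floor_frac * max(e2, 1e-30), 1e-30)
        sv[g] = (0.25 * base + floor, 4.0 * base + floor)
        floors[g] = floor
    eps = np.tile(np.array([[0.8, 0.2], [0.2, 0.8]]), (G, 1, 1))
    pri = np.tile(np.array([0.5, 0.5]), (G, 1))
    return sv, eps, pri, floors


def _upward_downward(w, nv, trees: TreeIndex, sv, eps, pri):
    """Exact E-step on the forest; returns (gamma, xi, loglik).

    ``xi[i]`` is the pair posterior P(S_i = m, S_parent = r | w) for
    non-root i (zeros at roots).
    """
    n = trees.n_nodes
    g = trees.group
    var = sv[g] + nv[:, None]                     # (n, 2)
    logf = -0.5 * (_LOG2PI + np.log(var) + (w[:, None] ** 2) / var)

    B = np.empty((n, 2))
    Bmsg = np.empty((n, 2))
    childacc = np.zeros((n, 2))
    lognorm = np.empty(n)

    # scale-contiguous node layout lets every per-scale pass use slices
    for j in range(1, trees.levels + 1):
        lo, hi = trees.scale_range(j)
        sl = slice(lo, hi)
        la = logf[sl] + childacc[sl]
        m = la.max(axis=1)
        la -= m[:, None]
        np.exp(la, out=la)
        Z = la.sum(axis=1)
        B[sl] = la / Z[:, None]
        lognorm[sl] = m + np.log(Z)
        if j < trees.levels:
            par = trees.parent[sl]
            e = eps[g[sl]]                        # (k, 2, 2) eps[m, r]
            msg = np.einsum("kmr,km->kr", e, B[sl])
            np.maximum(msg, 1e-300, out=msg)
            Bmsg[sl] = msg
            plo, phi = trees.scale_range(j + 1)
            lm = np.log(msg)
            for r in (0, 1):
                childacc[plo:phi, r] += np.bincount(
                    par - plo, weights=lm[:, r], minlength=phi - plo
                )

    rlo, rhi = trees.scale_range(trees.levels)
    pr = pri[g[rlo:rhi]]
    root_mix = (pr * B[rlo:rhi]).sum(axis=1)
    loglik = float(np.sum(np.log(np.maximum(root_mix, 1e-300))) + lognorm.sum())

    gamma = np.zeros((n, 2))
    xi = np.zeros((n, 2, 2))
    A = np.empty((n, 2))
    A[rlo:rhi] = pr
    gm = pr * B[rlo:rhi]
    gamma[rlo:rhi] = gm / gm.sum(axis=1, keepdims=True)

    for j in range(trees.levels - 1, 0, -1):
        lo, hi = trees.scale_range(j)
        sl = slice(lo, hi)
        par = trees.parent[sl]
        E = A[par] * B[par] / Bmsg[sl]            # (k, 2) indexed by r
        e = eps[g[sl]]
        Ai = np.einsum("kmr,kr->km", e, E)
        Ai /= np.maximum(Ai.sum(axis=1, keepdims=True), 1e-300)
        A[sl] = Ai
        gm = Ai * B[sl]
        gamma[sl] = gm / np.maximum(gm.sum(axis=1, keepdims=True), 1e-300)
        x = e * B[sl][:, :, None] * E[:, None, :]
        x /= np.maximum(x.sum(axis=(1, 2), keepdims=True), 1e-300)
        xi[sl] = x

    return gamma, xi, loglik


def _variance_update(w, nv, trees, gamma, sv_old, floors):
    """Closed-form M-step for the state variances with latent clean
    coefficients: sigma2_m <- sum gamma_m E[v^2|w,m] / sum gamma_m."""
    G = len(trees.group_key)
    sv = np.empty((G, 2))
    for gi in range(G):
        lo, hi = trees.group_range(gi)
        sel = slice(lo, hi)
        wg = w[sel]
        nvg = nv[sel]
        gam = gamma[sel]
        for m in (0, 1):
            s2 = sv_old[gi, m]
            tot = s2 + nvg
            gain = np.divide(s2, tot, out=np.zeros_like(tot), where=tot > 0)
            ev2 = (gain * wg) ** 2 + gain * nvg
            denom = max(gam[:, m].sum(), 1e-300)
            sv[gi, m] = max(float((gam[:, m] * ev2).sum() / denom), floors[gi])
    return sv


def _order_states(sv, eps, pri, trees: TreeIndex):
    """Relabel states per subband so that state 2 has the larger variance,
    cascading the relabel through transition matrices consistently."""
    G = len(trees.group_key)
    swap = sv[:, 0] > sv[:, 1]
    key_to_g = {k: i for i, k in enumerate(trees.group_key)}
    sv = sv.copy()
    eps = eps.copy()
    pri = pri.copy()
    perm = np.array([1, 0])
    for gi in range(G):
        if swap[gi]:
            sv[gi] = sv[gi][perm]
            pri[gi] = pri[gi][perm]
            eps[gi] = eps[gi][perm, :]        # child states relabeled
        j, d = trees.group_key[gi]
        # if this subband's parent subband(s) were relabeled, permute columns
        if trees.mapping_mode == "same_direction":
            pkeys = [(j + 1, d)]
        else:
            pkeys = [(j + 1, p) for p in ((0, 2) if d in (0, 1) else (1, 3))]
        pg = [key_to_g[k] for k in pkeys if k in key_to_g]
        if pg and any(swap[p] for p in pg):
            if len(pg) > 1 and len({bool(swap[p]) for p in pg}) > 1:
                # mixed parent relabels cannot be expressed with one tied
                # matrix; skip (only possible in split_direction mode)
                continue
            eps[gi] = eps[gi][:, perm]
    return sv, eps, pri, swap


def em_train(
    pyramid: ContourletPyramid,
    noise_vars,
    trees: TreeIndex,
    config: EMConfig = EMConfig(),
    init: "HMTParams | None" = None,
):
    """Fit the tied HMT by EM.

    Returns ``(params, posteriors, loglik_trace)``.  The log-likelihood is
    non-decreasing over iterations (exact E-step, closed-form M-step);
    iteration stops when its relative change drops below ``config.tol``.
    ``init`` warm-starts from previously fitted parameters (used across
    cycle-spinning shifts, whose statistics are nearly identical).
    """
    if noise_vars is not None:
        noise_vars.check_congruent(pyramid)
    w = _gather_coeffs(pyramid, trees)
    nv = _gather_noise(noise_vars, trees)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite coefficients")
    sv, eps, pri, floors = _init_params(w, nv, trees, config.var_floor_frac)
    if init is not None:
        for gi, key in enumerate(trees.group_key):
            if key in init.variances:
                sv[gi] = np.maximum(np.asarray(init.variances[key]), floors[gi])
            if key in init.transitions:
                eps[gi] = np.asarray(init.transitions[key])
            if key in init.root_priors:
                pri[gi] = np.asarray(init.root_priors[key])

    trace = []
    gamma = None
    for it in range(config.max_iter):
        gamma, xi, loglik = _upward_downward(w, nv, trees, sv, eps, pri)
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite log-likelihood in EM")
        trace.append(loglik)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if (trace[-1] - trace[-2]) / denom < config.tol:
                break
        if it == config.max_iter - 1:
            break   # keep returned parameters consistent with the posteriors
        sv_new = _variance_update(w, nv, trees, gamma, sv, floors)
        # priors / transitions from the same posteriors
        pri_new = pri.copy()
        eps_new = eps.copy()
        for gi, (j, _) in enumerate(trees.group_key):
            lo, hi = trees.group_range(gi)
            if j == trees.levels:
                pr = gamma[lo:hi].mean(axis=0)
                pri_new[gi] = pr / pr.sum()
            else:
                x = xi[lo:hi].sum(axis=0)
                eps_new[gi] = x / np.maximum(x.sum(axis=0, keepdims=True), 1e-300)
        sv, eps, pri = sv_new, eps_new, pri_new

    sv, eps, pri, swap = _order_states(sv, eps, pri, trees)
    if gamma is not None:
        for gi in np.flatnonzero(swap):
            lo, hi = trees.group_range(gi)
            gamma[lo:hi] = gamma[lo:hi, ::-1]

    variances = {k: sv[i] for i, k in enumerate(trees.group_key)}
    transitions = {
        k: eps[i] for i, k in enumerate(trees.group_key) if k[0] < trees.levels
    }
    root_priors = {
        k: pri[i] for i, k in enumerate(trees.group_key) if k[0] == trees.levels
    }
    params = HMTParams(
        variances, transitions, root_priors, trees.levels, trees.mapping_mode
    )
    return params, PosteriorField(gamma, trees), np.asarray(trace)


# --------------------------------------------------------------------------
# sampling and shrinkage
# --------------------------------------------------------------------------


def sample_hmt(params: HMTParams, trees: TreeIndex, seed: int | np.random.Generator = 0):
    """Ancestral sampling of states and coefficients from an HMT.

    Returns ``(states, coeffs)`` as dicts keyed by ``(scale, dir)``; states
    are 0/1 (0 = small-variance state).
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    key_to_g = {k: i for i, k in enumerate(trees.group_key)}
    states = np.zeros(trees.n_nodes, dtype=np.int8)
    u = rng.random(trees.n_nodes)
    for j in range(trees.levels, 0, -1):
        idx = trees.nodes_at_scale(j)
        for (jj, d), ids in trees.node_of.items():
            if jj != j:
                continue
            ids = ids.ravel()
            if j == trees.levels:
                p2 = params.root_priors[(j, d)][1]
                states[ids] = (u[ids] < p2).astype(np.int8)
            else:
                eps = np.asarray(params.transitions[(j, d)])
                pr = trees.parent[ids]
                p2 = eps[1, states[pr]]
                states[ids] = (u[ids] < p2).astype(np.int8)
    z = rng.standard_normal(trees.n_nodes)
    coeffs = np.empty(trees.n_nodes)
    for (j, d), ids in trees.node_of.items():
        sd = np.sqrt(np.asarray(params.variances[(j, d)]))
        coeffs[ids.ravel()] = z[ids.ravel()] * sd[states[ids.ravel()]]
    out_states = {k: states[ids] for k, ids in trees.node_of.items()}
    out_coeffs = {k: coeffs[ids] for k, ids in trees.node_of.items()}
    return out_states, out_coeffs


def shrink(
    pyramid: ContourletPyramid,
    noise_vars: VariancePyramid,
    posteriors: PosteriorField,
    params: HMTParams,
) -> ContourletPyramid:
    """Posterior-weighted Wiener shrinkage of every detail coefficient.

    Each coefficient is multiplied by ``sum_m P(S=m | w) * s2_m/(s2_m+n2)``,
    a gain in [0, 1]; the lowpass band passes through unchanged.
    """
    noise_vars.check_congruent(pyramid)

    def shrink_band(sb):
        key = (sb.scale_index, sb.direction_index)
        nv = noise_vars.scales[sb.scale_index - 1][sb.direction_index]
        if np.any(nv < 0):
            raise ValueError("negative noise variance")
        gam = posteriors.subband(*key)
        s2 = np.asarray(params.variances[key])
        gain = np.zeros(sb.coeffs.shape)
        for m in (0, 1):
            tot = s2[m] + nv
            gm = np.divide(s2[m], tot, out=np.ones_like(tot), where=tot > 0)
            gain += gam[..., m] * gm
        return gain * sb.coeffs

    return pyramid.map_coeffs(shrink_band)
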