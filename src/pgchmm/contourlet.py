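"""Contourlet transform: Laplacian pyramid + directional filter bank (DFB),
with exact propagation of per-pixel noise variance into every subband.

Design
------
The Laplacian pyramid stores, at each level, the difference between the
current band and the filtered upsampled coarse approximation; reconstruction
is exact by construction for any filter pair.  The directional filter bank is
implemented with ideal (brick-wall) frequency wedges on the periodic grid:

* depth 1: the two fan halves, critically sampled on the quincunx lattice;
* depth 2: four slope sectors, each decimated by diag(2, 2);
* depth 3-4: exact binary refinements of the depth-2 subbands, splitting each
  subband in its own sample grid according to the underlying image-domain
  frequency of every retained bin.

The wedge masks form an exact bin-level partition of the frequency grid and
are alias-free for each subband's decimation lattice, so analysis and
synthesis are mutually exact (reconstruction to machine precision) while the
bank stays critically sampled.  Grid bins that are their own alias partner
(a measure-zero set on wedge boundaries) are split across two subbands with
a conjugate 1/2, +-i/2 mask pair whose 2x2 synthesis system is solved
exactly, keeping every subband real-valued.

Noise-variance propagation follows from linearity: each subband coefficient
is an inner product of the image with one equivalent analysis filter ``h``
(obtained by probing the adjoint of the analysis operator), so under
independent per-pixel noise its variance is the cross-correlation of the
pixel-variance map with ``h**2``, sampled on the subband lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from .grid import ImageGrid

__all__ = [
    "ContourletConfig",
    "Subband",
    "ContourletPyramid",
    "VariancePyramid",
    "lp_decompose",
    "lp_reconstruct",
    "dfb_decompose",
    "dfb_reconstruct",
    "contourlet_forward",
    "contourlet_inverse",
    "equivalent_filters",
    "propagate_variance",
    "VariancePropagator",
    "save_pyramid",
    "load_pyramid",
]


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ContourletConfig:
    """Geometry and filter choice of the transform.

    ``levels`` pyramid levels (scale 1 = finest); every bandpass band is
    split into ``dirs_per_scale`` directional subbands.  ``lp_filter`` names
    the pyramid filter pair: "9/7" (symmetric biorthogonal, default) or
    "db8" (orthogonal).
    """

    levels: int = 5
    dirs_per_scale: int = 4
    lp_filter: str = "9/7"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.dirs_per_scale not in (2, 4, 8, 16):
            raise ValueError("dirs_per_scale must be one of 2, 4, 8, 16")

    @property
    def dfb_depth(self) -> int:
        return int(np.log2(self.dirs_per_scale))


@dataclass
class Subband:
    """One directional subband plus the metadata that maps each coefficient
    to its footprint: coordinates in the bandpass grid of its scale (the
    image-domain position is ``2**(scale_index-1)`` times that)."""

    coeffs: np.ndarray
    scale_index: int          # 1 = finest
    direction_index: int
    level_rows: np.ndarray    # coefficient rows in the bandpass grid
    level_cols: np.ndarray
    lattice: str              # "diag" or "quincunx"
    level_shape: tuple = None # shape of the bandpass grid at this scale

    @property
    def shape(self):
        return self.coeffs.shape


@dataclass
class ContourletPyramid:
    lowpass: np.ndarray
    scales: list        # scales[j-1] = list of Subband at scale j
    config: ContourletConfig
    shape: tuple

    def n_coefficients(self) -> int:
        return self.lowpass.size + sum(
            sb.coeffs.size for scale in self.scales for sb in scale
        )

    def map_coeffs(self, fn) -> "ContourletPyramid":
        """New pyramid with ``fn(subband) -> ndarray`` applied per subband."""
        scales = [
            [
                Subband(
                    np.asarray(fn(sb), dtype=np.float64),
                    sb.scale_index,
                    sb.direction_index,
                    sb.level_rows,
                    sb.level_cols,
                    sb.lattice,
                    sb.level_shape,
                )
                for sb in scale
            ]
            for scale in self.scales
        ]
        return ContourletPyramid(self.lowpass.copy(), scales, self.config, self.shape)


@dataclass
class VariancePyramid:
    """Per-coefficient noise variances, shape-congruent with a pyramid."""

    lowpass: np.ndarray
    scales: list        # scales[j-1][d] = ndarray of variances

    def check_congruent(self, pyramid: ContourletPyramid) -> None:
        if self.lowpass.shape != pyramid.lowpass.shape:
            raise ValueError("variance pyramid incongruent with pyramid (lowpass)")
        for vs, ps in zip(self.scales, pyramid.scales, strict=True):
            for v, sb in zip(vs, ps, strict=True):
                if v.shape != sb.coeffs.shape:
                    raise ValueError("variance pyramid incongruent with pyramid")
                if np.any(v < 0):
                    raise ValueError("negative noise variance")


# --------------------------------------------------------------------------
# Laplacian pyramid
# --------------------------------------------------------------------------


def _lp_taps(name: str):
    if name in ("9/7", "bior4.4"):
        w = pywt.Wavelet("bior4.4")
        return np.trim_zeros(np.asarray(w.dec_lo)), np.trim_zeros(np.asarray(w.rec_lo))
    if name in ("db8", "Daubechies8"):
        w = pywt.Wavelet("db8")
        return np.asarray(w.dec_lo), np.asarray(w.rec_lo)
    raise ValueError(f"unknown LP filter {name!r}")


def _transfer_1d(taps: np.ndarray, n: int) -> np.ndarray:
    if len(taps) > n:
        raise ValueError("filter longer than the grid")
    f = np.zeros(n)
    c = (len(taps) - 1) // 2
    f[(np.arange(len(taps)) - c) % n] = taps
    return np.fft.fft(f)


@lru_cache(maxsize=64)
def _lp_transfers(shape: tuple, name: str):
    h, g = _lp_taps(name)
    H, W = shape
    Hf = np.outer(_transfer_1d(h, H), _transfer_1d(h, W))
    Gf = np.outer(_transfer_1d(g, H), _transfer_1d(g, W))
    return Hf, Gf


def _filt(x, F):
    return np.fft.ifft2(np.fft.fft2(x) * F).real


def _down2(x):
    return x[::2, ::2].copy()


def _up2(x):
    out = np.zeros((2 * x.shape[0], 2 * x.shape[1]))
    out[::2, ::2] = x
    return out


def lp_decompose(image: np.ndarray, levels: int, lp_filter: str = "9/7"):
    """Laplacian pyramid analysis: ``levels`` bandpass bands + one lowpass.

    Periodic boundary handling; dimensions must be divisible by
    ``2**levels``, and the lowpass must stay at least 8 pixels wide.
    """
    x = np.asarray(image, dtype=np.float64)
    H, W = x.shape
    if H % (1 << levels) or W % (1 << levels):
        raise ValueError(f"image shape {x.shape} not divisible by 2^{levels}; pad first")
    if min(H, W) >> levels < 8:
        raise ValueError(
            f"{levels} levels leave a {min(H, W) >> levels}-pixel lowpass (need >= 8)"
        )
    bands = []
    for _ in range(levels):
        Hf, Gf = _lp_transfers(x.shape, lp_filter)
        c = _down2(_filt(x, Hf))
        bands.append(x - _filt(_up2(c), Gf))
        x = c
    return bands, x


def lp_reconstruct(bands, lowpass, lp_filter: str = "9/7"):
    """Exact inverse of :func:`lp_decompose`."""
    x = np.asarray(lowpass, dtype=np.float64)
    for b in reversed(bands):
        if (2 * x.shape[0], 2 * x.shape[1]) != b.shape:
            raise ValueError("band/lowpass shapes inconsistent")
        _, Gf = _lp_transfers(b.shape, lp_filter)
        x = b + _filt(_up2(x), Gf)
    return x


def _lp_adjoint(band_cts, lowpass_ct, lp_filter: str = "9/7"):
    """Adjoint of the LP analysis map (band cotangents -> image)."""
    x = np.asarray(lowpass_ct, dtype=np.float64)
    for b in reversed(band_cts):
        Hf, Gf = _lp_transfers(b.shape, lp_filter)
        inner = x - _down2(_filt(b, np.conj(Gf)))
        x = b + _filt(_up2(inner), np.conj(Hf))
    return x


# --------------------------------------------------------------------------
# DFB wedge-mask compiler
# --------------------------------------------------------------------------


def _herm_items(H, W):
    """Group grid bins into Hermitian classes {b, -b} (mod grid)."""
    U = np.repeat(np.arange(H)[:, None], W, axis=1)
    V = np.repeat(np.arange(W)[None, :], H, axis=0)
    NU, NV = (-U) % H, (-V) % W
    use_neg = (NU < U) | ((NU == U) & (NV < V))
    RU = np.where(use_neg, NU, U)
    RV = np.where(use_neg, NV, V)
    items = {}
    for u in range(H):
        for v in range(W):
            items.setdefault((int(RU[u, v]), int(RV[u, v])), set()).add((u, v))
    return {r: tuple(sorted(s)) for r, s in items.items()}


def _lat_key(b, lat, H, W):
    kind, p, q = lat
    if kind == "diag":
        return (b[0] % (H // p), b[1] % (W // q))
    o2 = ((b[0] + H // 2) % H, (b[1] + W // 2) % W)
    return min(b, o2)


def _assign_masks(H, W, lattices, raw, pref_of):
    """Assign every Hermitian bin-class to one channel so that no channel
    holds two bins of one alias orbit (classes aliasing themselves in every
    channel are split across two channels with a complex patch).  Returns
    (masks, patched)."""
    n = len(lattices)
    items = _herm_items(H, W)
    keys_cache = {}

    def slot_keys(rep, k):
        kk = (rep, k)
        if kk not in keys_cache:
            keys_cache[kk] = frozenset(_lat_key(b, lattices[k], H, W) for b in items[rep])
        return keys_cache[kk]

    occ = [dict() for _ in range(n)]
    assign = {}

    def place(rep, k):
        for key in slot_keys(rep, k):
            occ[k][key] = rep
        assign[rep] = k

    def unplace(rep):
        k = assign.pop(rep)
        for key in slot_keys(rep, k):
            if occ[k].get(key) == rep:
                del occ[k][key]

    patch_pairs = []
    special = [
        rep
        for rep in sorted(items)
        if len(items[rep]) == 2 and all(len(slot_keys(rep, k)) == 1 for k in range(n))
    ]
    for rep in special:
        b, nb = items[rep]
        done = False
        for k1 in pref_of(rep):
            key1 = next(iter(slot_keys(rep, k1)))
            if key1 in occ[k1]:
                continue
            for k2 in pref_of(rep):
                if k2 == k1:
                    continue
                key2 = next(iter(slot_keys(rep, k2)))
                if key2 in occ[k2]:
                    continue
                occ[k1][key1] = rep
                occ[k2][key2] = rep
                patch_pairs.append((k1, k2, b, nb))
                done = True
                break
            if done:
                break
        if not done:
            raise RuntimeError(f"DFB mask compiler: cannot patch bin pair {rep}")

    special_set = set(special)
    unplaced = []
    for rep in sorted(items):
        if rep in special_set:
            continue
        k = int(raw[rep])
        keys = slot_keys(rep, k)
        if len(keys) < len(items[rep]) or any(key in occ[k] for key in keys):
            unplaced.append(rep)
        else:
            place(rep, k)

    def augment(rep, visited):
        for k in pref_of(rep):
            keys = slot_keys(rep, k)
            if len(keys) < len(items[rep]):
                continue
            blockers = {occ[k][key] for key in keys if key in occ[k]}
            blockers.discard(rep)
            if any(b in visited or b not in assign for b in blockers):
                continue
            if not blockers:
                place(rep, k)
                return True
            saved = {b: assign[b] for b in blockers}
            for b in blockers:
                unplace(b)
            place(rep, k)
            ok = True
            for b in blockers:
                visited.add(b)
                if not augment(b, visited):
                    ok = False
                    break
            if ok:
                return True
            for b in list(saved):
                if b in assign:
                    unplace(b)
            unplace(rep)
            for b, kb in saved.items():
                place(b, kb)
        return False

    for rep in unplaced:
        if not augment(rep, {rep}):
            raise RuntimeError(f"DFB mask compiler: cannot place bin class {rep}")

    masks = [np.zeros((H, W), dtype=complex) for _ in range(n)]
    patched = [np.zeros((H, W), dtype=bool) for _ in range(n)]
    for rep, k in assign.items():
        for b in items[rep]:
            masks[k][b] = 1.0
    for (k1, k2, b, nb) in patch_pairs:
        masks[k1][b] = masks[k1][nb] = 0.5
        masks[k2][b] = 0.5j
        masks[k2][nb] = -0.5j
        patched[k1][b] = patched[k1][nb] = True
        patched[k2][b] = patched[k2][nb] = True
    return masks, patched


def _wedge_index(fr, fc, depth):
    """Directional wedge index of integer frequency pairs at a given depth.

    Wedges ``0..Q-1`` (Q = 2**(depth-1)) split the family |f_r| <= |f_c| by
    slope ``f_r/f_c`` in [-1, 1); wedges ``Q..2Q-1`` the transposed family.
    Symmetric under frequency negation.
    """
    Q = 1 << (depth - 1)
    fr = np.asarray(fr, dtype=float)
    fc = np.asarray(fc, dtype=float)
    neg = (fc < 0) | ((fc == 0) & (fr < 0))
    fr = np.where(neg, -fr, fr)
    fc = np.where(neg, -fc, fc)
    famA = np.abs(fr) <= np.abs(fc)
    with np.errstate(divide="ignore", invalid="ignore"):
        tA = np.where(fc != 0, fr / np.maximum(np.abs(fc), 1e-300), 0.0)
        tB = np.where(fr != 0, fc / np.maximum(np.abs(fr), 1e-300), 0.0)
    idxA = np.clip(np.floor((tA + 1.0) / 2.0 * Q), 0, Q - 1).astype(int)
    idxB = np.clip(np.floor((tB + 1.0) / 2.0 * Q), 0, Q - 1).astype(int) + Q
    return np.where(famA, idxA, idxB)


def _wedge_centers(depth):
    Q = 1 << (depth - 1)
    centers = []
    for k in range(2 * Q):
        t = ((k % Q) + 0.5) * 2.0 / Q - 1.0
        vec = (t, 1.0) if k < Q else (1.0, t)
        centers.append(np.arctan2(vec[0], vec[1]) % np.pi)
    return np.array(centers)


def _pref_factory(cr, cc, centers):
    cache = {}

    def pref(rep):
        if rep not in cache:
            a = np.arctan2(cr[rep], cc[rep]) % np.pi if (cr[rep] or cc[rep]) else 0.0
            d = np.abs(((centers - a) + np.pi / 2) % np.pi - np.pi / 2)
            cache[rep] = [int(x) for x in np.argsort(d, kind="stable")]
        return cache[rep]

    return pref


class _Node:
    """One analysis stage of the DFB plan (a mask + decimation); leaves carry
    the final direction index and coefficient coordinate maps."""

    __slots__ = (
        "mask", "patched", "lat", "chan0", "in_shape", "out_shape",
        "children", "direction", "rows", "cols",
    )

    def __init__(self, mask, patched, lat, chan0, in_shape):
        self.mask = mask
        self.patched = patched
        self.lat = lat
        self.chan0 = chan0
        self.in_shape = in_shape
        kind, p, q = lat
        H, W = in_shape
        if kind == "diag":
            self.out_shape = (H // p, W // q)
        else:
            self.out_shape = (H, W // 2) if chan0 else (H // 2, W)
        self.children = []
        self.direction = None
        self.rows = None
        self.cols = None

    @property
    def det(self):
        return 2 if self.lat[0] == "quincunx" else self.lat[1] * self.lat[2]


def _sample_idx(shape, lat, chan0):
    H, W = shape
    kind, p, q = lat
    if kind == "diag":
        R = np.repeat(np.arange(0, H, p)[:, None], W // q, axis=1)
        C = np.repeat(np.arange(0, W, q)[None, :], H // p, axis=0)
        return R, C
    if chan0:
        i = np.arange(H)[:, None]
        nn = np.arange(W // 2)[None, :]
        return np.repeat(i, W // 2, axis=1), 2 * nn + (i & 1)
    j = np.arange(W)[None, :]
    mm = np.arange(H // 2)[:, None]
    return 2 * mm + (j & 1), np.repeat(j, H // 2, axis=0)


def _refine_freq_map(mask, fu, fv, lat):
    """Underlying-frequency map of the decimated output of one stage."""
    h, w = fu.shape
    kind, p, q = lat
    hh, ww = h // p, w // q
    nfu = np.zeros((hh, ww), dtype=int)
    nfv = np.zeros((hh, ww), dtype=int)
    got = np.zeros((hh, ww), dtype=bool)
    for a in range(p):
        for b in range(q):
            du, dv = a * hh, b * ww
            sub = mask[du : du + hh, dv : dv + ww] != 0
            take = sub & ~got
            nfu[take] = fu[du : du + hh, dv : dv + ww][take]
            nfv[take] = fv[du : du + hh, dv : dv + ww][take]
            got |= sub
    if not got.all():
        raise AssertionError("stage mask does not cover a full alias set")
    return nfu, nfv


@lru_cache(maxsize=32)
def _dfb_plan(H, W, depth):
    """Compile the DFB analysis plan (a tree of masked decimation stages)."""
    Q = 1 << (depth - 1)
    if depth < 1 or depth > 4:
        raise ValueError("DFB depth must be 1..4")
    if H % (2 * Q) or W % (2 * Q) or min(H, W) < 4 * Q:
        raise ValueError(f"grid {H}x{W} too small or not divisible for depth-{depth} DFB")

    fr = np.fft.fftfreq(H, 1.0 / H).astype(int)
    fc = np.fft.fftfreq(W, 1.0 / W).astype(int)
    FR = np.repeat(fr[:, None], W, axis=1)
    FC = np.repeat(fc[None, :], H, axis=0)

    if depth == 1:
        lats = [("quincunx", None, None)] * 2
        raw = _wedge_index(FR, FC, 1)
        masks, patched = _assign_masks(
            H, W, lats, raw, _pref_factory(FR, FC, _wedge_centers(1))
        )
        roots = []
        for k in range(2):
            node = _Node(masks[k], patched[k], lats[k], k == 0, (H, W))
            node.direction = k
            roots.append(node)
    else:
        lat2 = ("diag", 2, 2)
        raw = _wedge_index(FR, FC, 2)
        masks, patched = _assign_masks(
            H, W, [lat2] * 4, raw, _pref_factory(FR, FC, _wedge_centers(2))
        )
        roots = []
        for k2 in range(4):
            node = _Node(masks[k2], patched[k2], lat2, True, (H, W))
            node.direction = k2
            roots.append(node)
        # binary refinement of every subband down to the target depth
        frontier = [
            (node, k2, *_refine_freq_map(masks[k2], FR, FC, lat2))
            for k2, node in enumerate(roots)
        ]
        for d_now in range(3, depth + 1):
            Qn = 1 << (d_now - 1)
            centers = _wedge_centers(d_now)
            new_frontier = []
            for node, widx, fu, fv in frontier:
                famA = widx < (Qn // 2)
                lat = ("diag", 2, 1) if famA else ("diag", 1, 2)
                kids = (2 * widx, 2 * widx + 1) if famA else (
                    Qn + 2 * (widx - Qn // 2), Qn + 2 * (widx - Qn // 2) + 1
                )
                wed = _wedge_index(fu, fv, d_now)
                # stray boundary bins (relocated at a coarser stage) go to the
                # angularly nearest of the two children
                a0, a1 = centers[kids[0]], centers[kids[1]]
                ang = np.arctan2(fu, np.where(fv == 0, 1e-300, fv)) % np.pi
                d0 = np.abs(((ang - a0) + np.pi / 2) % np.pi - np.pi / 2)
                d1 = np.abs(((ang - a1) + np.pi / 2) % np.pi - np.pi / 2)
                raw2 = np.where(wed == kids[0], 0, np.where(wed == kids[1], 1, (d1 < d0)))
                raw2 = raw2.astype(int)

                def pref2(rep, raw2=raw2):
                    k = int(raw2[rep])
                    return [k, 1 - k]

                h, w = fu.shape
                m2, p2 = _assign_masks(h, w, [lat, lat], raw2, pref2)
                for half in (0, 1):
                    child = _Node(m2[half], p2[half], lat, True, (h, w))
                    child.direction = kids[half]
                    node.children.append(child)
                    nfu, nfv = _refine_freq_map(m2[half], fu, fv, lat)
                    new_frontier.append((child, kids[half], nfu, nfv))
            frontier = new_frontier

    # leaf coordinate maps (positions in the DFB input grid) via index tracing
    def trace(node, R, C):
        Rs, Cs = _sample_idx(node.in_shape, node.lat, node.chan0)
        Rn, Cn = R[Rs, Cs], C[Rs, Cs]
        if node.children:
            for ch in node.children:
                trace(ch, Rn, Cn)
        else:
            node.rows, node.cols = Rn, Cn

    R0 = np.repeat(np.arange(H)[:, None], W, axis=1)
    C0 = np.repeat(np.arange(W)[None, :], H, axis=0)
    for node in roots:
        trace(node, R0, C0)

    leaves = []

    def collect(node):
        if node.children:
            for ch in node.children:
                collect(ch)
        else:
            leaves.append(node)

    for node in roots:
        collect(node)
    leaves.sort(key=lambda nd: nd.direction)
    return roots, leaves


def _dfb_apply(roots, band):
    out = {}

    def walk(nodes, arr):
        X = np.fft.fft2(arr)
        for node in nodes:
            Rs, Cs = _sample_idx(node.in_shape, node.lat, node.chan0)
            s = np.fft.ifft2(X * node.mask).real[Rs, Cs]
            if node.children:
                walk(node.children, s)
            else:
                out[node.direction] = s

    walk(roots, band)
    return [out[d] for d in sorted(out)]


def _dfb_unapply(roots, subs):
    subs = {d: np.asarray(s, dtype=np.float64) for d, s in enumerate(subs)}

    def rebuild(nodes, shape):
        acc = np.zeros(shape, dtype=complex)
        for node in nodes:
            s = rebuild(node.children, node.out_shape) if node.children else subs[node.direction]
            if s.shape != node.out_shape:
                raise ValueError("subband shape inconsistent with DFB plan")
            z = np.zeros(node.in_shape)
            Rs, Cs = _sample_idx(node.in_shape, node.lat, node.chan0)
            z[Rs, Cs] = s
            G = node.det * np.conj(node.mask) * (1.0 + node.patched)
            acc += np.fft.fft2(z) * G
        return np.fft.ifft2(acc).real

    return rebuild(roots, roots[0].in_shape)


def _dfb_adjoint(roots, subs):
    """Adjoint of the DFB analysis map (subband cotangents -> band)."""
    subs = {d: np.asarray(s, dtype=np.float64) for d, s in enumerate(subs)}

    def rebuild(nodes, shape):
        acc = np.zeros(shape, dtype=complex)
        for node in nodes:
            s = rebuild(node.children, node.out_shape) if node.children else subs[node.direction]
            z = np.zeros(node.in_shape)
            Rs, Cs = _sample_idx(node.in_shape, node.lat, node.chan0)
            z[Rs, Cs] = s
            acc += np.fft.fft2(z) * np.conj(node.mask)
        return np.fft.ifft2(acc).real

    return rebuild(roots, roots[0].in_shape)


def dfb_decompose(band: np.ndarray, depth: int):
    """Split a band into ``2**depth`` critically-sampled directional
    subbands (wedge-shaped frequency supports)."""
    band = np.asarray(band, dtype=np.float64)
    roots, _ = _dfb_plan(band.shape[0], band.shape[1], depth)
    return _dfb_apply(roots, band)


def dfb_reconstruct(subbands, depth: int, shape: tuple):
    """Exact inverse of :func:`dfb_decompose`."""
    roots, _ = _dfb_plan(shape[0], shape[1], depth)
    return _dfb_unapply(roots, subbands)


# --------------------------------------------------------------------------
# full transform
# --------------------------------------------------------------------------


def _image_values(image):
    return image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=np.float64)


def contourlet_forward(image, config: ContourletConfig = ContourletConfig()) -> ContourletPyramid:
    """Contourlet analysis: LP, then a DFB on every bandpass band."""
    x = _image_values(image)
    bands, lowpass = lp_decompose(x, config.levels, config.lp_filter)
    depth = config.dfb_depth
    scales = []
    for j, band in enumerate(bands, start=1):
        _, leaves = _dfb_plan(band.shape[0], band.shape[1], depth)
        subs = dfb_decompose(band, depth)
        scales.append(
            [
                Subband(
                    s, j, leaf.direction, leaf.rows, leaf.cols,
                    leaf.lat[0] if leaf.lat[0] == "quincunx" else "diag",
                    band.shape,
                )
                for s, leaf in zip(subs, leaves)
            ]
        )
    return ContourletPyramid(lowpass, scales, config, x.shape)


def contourlet_inverse(pyramid: ContourletPyramid) -> np.ndarray:
    """Contourlet synthesis, the exact inverse of :func:`contourlet_forward`."""
    cfg = pyramid.config
    bands = []
    for scale in pyramid.scales:
        subs = [sb.coeffs for sb in sorted(scale, key=lambda sb: sb.direction_index)]
        bands.append(dfb_reconstruct(subs, cfg.dfb_depth, scale[0].level_shape))
    return lp_reconstruct(bands, pyramid.lowpass, cfg.lp_filter)


# --------------------------------------------------------------------------
# equivalent filters and variance propagation
# --------------------------------------------------------------------------


def _contourlet_adjoint(pyramid: ContourletPyramid) -> np.ndarray:
    """Adjoint of the analysis map, evaluated on a cotangent pyramid."""
    cfg = pyramid.config
    band_cts = []
    for scale in pyramid.scales:
        roots, _ = _dfb_plan(*scale[0].level_shape, cfg.dfb_depth)
        subs = [sb.coeffs for sb in sorted(scale, key=lambda sb: sb.direction_index)]
        band_cts.append(_dfb_adjoint(roots, subs))
    return _lp_adjoint(band_cts, pyramid.lowpass, cfg.lp_filter)


def _zero_pyramid_like(shape, config):
    """An all-zero pyramid for the given image shape (via one forward pass
    on a zero image; cheap relative to the probing it supports)."""
    return contourlet_forward(np.zeros(shape), config)


def equivalent_filters(shape: tuple, config: ContourletConfig = ContourletConfig()):
    """Per-subband equivalent analysis filters.

    For every (scale, direction) subband — and for each sampling phase where
    the lattice has more than one (the quincunx case) — returns the
    image-domain filter ``h`` such that the subband coefficient at reference
    position ``p0`` equals ``sum_x h[x] * image[x]``, together with the
    image coordinates of ``p0``.  Other coefficients of the same phase use
    circular shifts of ``h`` along the subband lattice.

    Returns
    -------
    dict mapping ``(scale_index, direction_index)`` to a list of entries
    ``{"filter": h, "anchor": (r0, c0), "phase": (pr, pc)}``; key
    ``("lowpass",)`` holds the lowpass entry.
    """
    zero = _zero_pyramid_like(shape, config)
    out = {}
    for scale in zero.scales:
        for sb in scale:
            step = 1 << (sb.scale_index - 1)
            entries = []
            if sb.lattice == "quincunx":
                phases = [(0, 0), (1, 1)]
            else:
                phases = [(0, 0)]
            for ph in phases:
                pr = np.asarray(sb.level_rows) % 2 == ph[0]
                pc = np.asarray(sb.level_cols) % 2 == ph[1]
                cand = np.argwhere(pr & pc)
                i0, j0 = cand[0]
                probe = zero.map_coeffs(lambda s: np.zeros(s.shape))
                probe.scales[sb.scale_index - 1][
                    [b.direction_index for b in scale].index(sb.direction_index)
                ].coeffs[i0, j0] = 1.0
                h = _contourlet_adjoint(probe)
                r0 = int(sb.level_rows[i0, j0]) * step
                c0 = int(sb.level_cols[i0, j0]) * step
                entries.append({"filter": h, "anchor": (r0, c0), "phase": ph})
            out[(sb.scale_index, sb.direction_index)] = entries
    probe = zero.map_coeffs(lambda s: np.zeros(s.shape))
    probe.lowpass = np.zeros_like(probe.lowpass)
    probe.lowpass[0, 0] = 1.0
    h = _contourlet_adjoint(probe)
    out[("lowpass",)] = [{"filter": h, "anchor": (0, 0), "phase": (0, 0)}]
    return out


class VariancePropagator:
    """Propagates a per-pixel noise-variance map into every subband.

    Under the assumption of independent pixel noise, the noise variance of a
    coefficient with equivalent analysis filter ``h`` anchored at image
    position ``p`` is ``sum_x var[x] * h[x - p]**2`` — the variance map
    cross-correlated with the squared equivalent filter and sampled on the
    subband lattice.  The squared-filter spectra are precomputed once per
    image shape, so repeated propagation (e.g. across cycle-spinning shifts,
    where the variance map is merely rolled) costs one FFT per subband.
    """

    def __init__(self, shape: tuple, config: ContourletConfig = ContourletConfig()):
        self.shape = tuple(shape)
        self.config = config
        self._filters = equivalent_filters(shape, config)
        self._spectra = {
            key: [
                {
                    "K": np.conj(np.fft.fft2(e["filter"] ** 2)),
                    "anchor": e["anchor"],
                    "phase": e["phase"],
                }
                for e in entries
            ]
            for key, entries in self._filters.items()
        }
        self._template = _zero_pyramid_like(shape, config)

    def propagate(self, var_map: np.ndarray, shift=(0, 0)) -> VariancePyramid:
        """Variance pyramid for an image whose variance map is ``var_map``
        circularly shifted by ``shift`` (rows, cols)."""
        var_map = np.asarray(var_map, dtype=np.float64)
        if var_map.shape != self.shape:
            raise ValueError(f"variance map shape {var_map.shape} != {self.shape}")
        if np.any(var_map < 0):
            raise ValueError("negative variances in variance map")
        F = np.fft.fft2(var_map)
        H, W = self.shape
        dr, dc = shift
        scales = []
        for scale in self._template.scales:
            row = []
            for sb in scale:
                step = 1 << (sb.scale_index - 1)
                entries = self._spectra[(sb.scale_index, sb.direction_index)]
                V = np.zeros(sb.coeffs.shape)
                for e in entries:
                    C = np.fft.ifft2(F * e["K"]).real
                    r0, c0 = e["anchor"]
                    Rim = (sb.level_rows * step - r0 - dr) % H
                    Cim = (sb.level_cols * step - c0 - dc) % W
                    if len(entries) > 1:
                        ph = e["phase"]
                        sel = (sb.level_rows % 2 == ph[0]) & (sb.level_cols % 2 == ph[1])
                        V[sel] = C[Rim[sel], Cim[sel]]
                    else:
                        V = C[Rim, Cim]
                row.append(np.maximum(V, 0.0))
            scales.append(row)
        e = self._spectra[("lowpass",)][0]
        C = np.fft.ifft2(F * e["K"]).real
        step = 1 << self.config.levels
        lr = np.repeat(np.arange(self._template.lowpass.shape[0])[:, None],
                       self._template.lowpass.shape[1], axis=1)
        lc = np.repeat(np.arange(self._template.lowpass.shape[1])[None, :],
                       self._template.lowpass.shape[0], axis=0)
        Rim = (lr * step - dr) % H
        Cim = (lc * step - dc) % W
        low = np.maximum(C[Rim, Cim], 0.0)
        return VariancePyramid(low, scales)


def propagate_variance(
    var_map: np.ndarray,
    config: ContourletConfig = ContourletConfig(),
    shift=(0, 0),
) -> VariancePyramid:
    """One-shot variance propagation (see :class:`VariancePropagator`)."""
    return VariancePropagator(np.asarray(var_map).shape, config).propagate(var_map, shift)


# --------------------------------------------------------------------------
# serialization (debugging / fixtures)
# --------------------------------------------------------------------------


def save_pyramid(path, pyramid: ContourletPyramid) -> None:
    """Serialize a pyramid (arrays + config manifest) to one ``.npz`` file."""
    arrays = {"lowpass": pyramid.lowpass}
    meta = {
        "levels": pyramid.config.levels,
        "dirs_per_scale": pyramid.config.dirs_per_scale,
        "lp_filter": pyramid.config.lp_filter,
        "shape": list(pyramid.shape),
    }
    for scale in pyramid.scales:
        for sb in scale:
            arrays[f"s{sb.scale_index}_d{sb.direction_index}"] = sb.coeffs
    import json

    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_pyramid(path) -> ContourletPyramid:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = ContourletConfig(meta["levels"], meta["dirs_per_scale"], meta["lp_filter"])
        template = _zero_pyramid_like(tuple(meta["shape"]), cfg)
        for scale in template.scales:
            for sb in scale:
                sb.coeffs = np.array(data[f"s{sb.scale_index}_d{sb.direction_index}"])
        template.lowpass = np.array(data["lowpass"])
    return template
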