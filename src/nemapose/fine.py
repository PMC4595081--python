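"""Pixel-resolution boundary refinement by dynamic programming.

The coarse midline is smoothed, offset by half a worm width to hypothesize
the left and right body boundaries, and sampled into a single open chain
eta_0 .. eta_n .. eta_2n that runs up the left side from the tail, through
the head tip at index n, and back down the right side.  Each chain point is
restricted to a small corridor of admissible pixels around its hypothesized
location.  The data model rewards, along each rasterized chain segment, the
oriented polarized edge type expected for a dark body on that side of the
boundary (probability ``p_obj`` on the boundary vs ``p_bg`` elsewhere); the
prior penalizes deviations of the segment's quantized orientation from the
coarse prediction.  Because the log-posterior is a sum of terms in
consecutive chain points, the global maximizer is found exactly by a
chain dynamic program.

The hypothesized midline is extrapolated tangentially a little beyond both
coarse endpoints: the tapered tail and head tips carry no body features, so
the coarse stage systematically stops short of them.  Where the extrapolated
corridors run past the true tip the optimal chain simply folds back on
itself (zero-length segments cost nothing and collect no edge terms), so the
boundary remains anchored to the image evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edges import AXES, DIRS, EdgeMap, edge_index
from .coarse import CoarseInstantiation


@dataclass
class FineModelParams:
    p_obj: float = 0.75    # edge probability on the body boundary
    p_bg: float = 0.10     # edge probability elsewhere
    B: float = 4.0         # orientation-prior precision per 45-degree step
    corridor_halfwidth: float | None = None   # defaults to worm_width / 2
    max_step: float = 4.0  # largest Chebyshev hop between consecutive points

    def __post_init__(self) -> None:
        if not (0 < self.p_bg < self.p_obj < 1):
            raise ValueError("need 0 < p_bg < p_obj < 1")
        if self.B < 0:
            raise ValueError("orientation-prior precision B must be >= 0")

    @property
    def lr_on(self) -> float:
        return float(np.log(self.p_obj / self.p_bg))

    @property
    def lr_off(self) -> float:
        return float(np.log((1 - self.p_obj) / (1 - self.p_bg)))


@dataclass
class FineSearchSpace:
    admissible_sets: list[np.ndarray]   # per chain index, (k_i, 2) int pixels
    expected_dirs: np.ndarray           # (2n,) int direction index 0..7 per segment
    edge_types: np.ndarray              # (2n,) int edge-type index per segment
    head_tip_index: int                 # = n
    hypothesized: np.ndarray            # (2n+1, 2) float chain anchor points


@dataclass
class FineInstantiation:
    boundary: np.ndarray        # (2n+1, 2) int pixel coordinates
    midline: np.ndarray         # (m, 2) float, tail to head tip
    head_tip_index: int
    log_post: float


def quantize_direction(dr: float, dc: float) -> int:
    """Index 0..7 (E, SE, S, SW, W, NW, N, NE) of the nearest 45-degree
    direction of the vector ``(dr, dc)``."""
    ang = np.arctan2(dr, dc)            # 0 = east, positive = south/CW
    return int(np.rint(ang / (np.pi / 4))) % 8


def direction_deviation(k1: int, k2: int) -> int:
    """Circular distance between two direction indices, in 45-degree steps
    (0..4)."""
    d = abs(int(k1) - int(k2)) % 8
    return min(d, 8 - d)


def segment_edge_type(direction: int, body_side: str) -> int:
    """Edge type expected along a boundary segment of the given quantized
    direction, for a dark body lying to the ``body_side`` ('left' or
    'right') of the direction of travel.

    The edge axis is the one perpendicular to the segment; the polarity
    follows the adjacent-difference convention: stepping along the axis
    vector into the body gives a negative difference.
    """
    if body_side not in ("left", "right"):
        raise ValueError("body_side must be 'left' or 'right'")
    dr, dc = DIRS[direction % 8]
    if body_side == "right":
        nr, nc = dc, -dr      # right-hand normal in (row, col), y down
    else:
        nr, nc = -dc, dr
    for axis, (ar, ac) in enumerate(AXES):
        if (nr, nc) == (ar, ac):
            return edge_index(axis, -1)   # body on the +axis side
        if (nr, nc) == (-ar, -ac):
            return edge_index(axis, +1)   # body on the -axis side
    raise ValueError(f"degenerate direction {direction}")  # pragma: no cover


def _smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing with a clipped window near the ends."""
    pts = np.asarray(points, dtype=float)
    out = np.empty_like(pts)
    h = window // 2
    for i in range(len(pts)):
        lo, hi = max(0, i - h), min(len(pts), i + h + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def _resample(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0, s[-1], n)
    return np.stack([np.interp(t, s, points[:, 0]),
                     np.interp(t, s, points[:, 1])], axis=1)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    rr, cc = np.mgrid[-r:r + 1, -r:r + 1]
    sel = rr ** 2 + cc ** 2 <= radius ** 2 + 1e-9
    return np.stack([rr[sel], cc[sel]], axis=1)


def build_search_space(coarse: CoarseInstantiation, worm_width: float,
                       n_segments: int | None = None, *, coarse_unit: int = 1,
                       corridor_halfwidth: float | None = None,
                       image_shape: tuple[int, int] | None = None,
                       smooth_window: int = 5,
                       tip_extension_frac: float = 0.04) -> FineSearchSpace:
    """Derive admissible pixel sets and expected orientations from a coarse
    instantiation.

    The coarse points (head first) are mapped to pixel coordinates, smoothed
    with a moving average, extrapolated tangentially by
    ``tip_extension_frac`` of the arc length at both ends, and offset by
    half a worm width on both sides.  ``n_segments`` is the number of chain
    points per side (default: spacing of about 2 px along the boundary).
    """
    if len(coarse.points) < 3:
        raise ValueError("coarse instantiation too short (need >= 3 points)")
    u = coarse_unit
    mid = np.asarray(coarse.points, dtype=float)[::-1] * u + u // 2  # tail->head
    mid = _smooth_polyline(mid, smooth_window)
    mid = _resample(mid, max(2 * len(mid), 50))
    # tangential extrapolation at both ends (tips carry no coarse features)
    arc = np.hypot(*np.diff(mid, axis=0).T).sum()
    ext = tip_extension_frac * arc
    t0 = mid[0] - mid[4]
    t0 /= np.hypot(*t0) + 1e-12
    t1 = mid[-1] - mid[-5]
    t1 /= np.hypot(*t1) + 1e-12
    mid = np.vstack([mid[0] + t0 * ext, mid, mid[-1] + t1 * ext])
    mid = _resample(mid, max(len(mid), 50))

    if n_segments is None:
        n_segments = max(8, int(np.ceil((arc + 2 * ext) / 2.0)))
    n = int(n_segments)
    hw = float(worm_width) / 2 if corridor_halfwidth is None \
        else float(corridor_halfwidth)

    mid_n = _resample(mid, n + 1)                    # tail .. head tip
    tang = np.gradient(mid_n, axis=0)
    tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None] + 1e-12
    left = np.stack([-tang[:, 1], tang[:, 0]], axis=1)   # left of travel
    # taper the boundary offset toward both tips
    s = np.linspace(0, 1, n + 1)
    taper = np.clip(s / 0.08, 0, 1) * np.clip((1 - s) / 0.08, 0, 1)
    half = worm_width / 2 * np.sqrt(taper)
    left_bd = mid_n + left * half[:, None]
    right_bd = mid_n - left * half[:, None]
    # chain: tail-left .. head tip .. tail-right
    chain = np.vstack([left_bd[:-1], mid_n[-1:], right_bd[::-1][1:]])
    # arc position of each chain anchor relative to the un-extended midline:
    # anchors inside the extension zones get capsule corridors reaching back
    # to the pre-extension tip, so the chain can fold exactly at the tip
    total = arc + 2 * ext
    s_px = s * total
    tail_anchor_idx = int(np.searchsorted(s_px, ext))
    head_anchor_idx = int(np.searchsorted(s_px, ext + arc) - 1)
    anchor_of = np.full(2 * n + 1, -1)
    for k in range(n):                       # left side, tail->head
        if s_px[k] < ext:
            anchor_of[k] = tail_anchor_idx
        elif s_px[k] > ext + arc:
            anchor_of[k] = head_anchor_idx
    if s_px[n] > ext + arc:                  # head tip point
        anchor_of[n] = head_anchor_idx
    for j, k in enumerate(range(2 * n, n, -1)):   # right side, tail->head
        if s_px[j] < ext:
            anchor_of[k] = tail_anchor_idx
        elif s_px[j] > ext + arc:
            anchor_of[k] = head_anchor_idx

    dirs = np.zeros(2 * n, dtype=int)
    etypes = np.zeros(2 * n, dtype=int)
    for i in range(1, 2 * n + 1):
        d = chain[i] - chain[i - 1]
        if np.hypot(*d) < 1e-9:
            d = chain[min(i + 1, 2 * n)] - chain[i - 1]
        k = quantize_direction(d[0], d[1])
        dirs[i - 1] = k
        # traversal runs tail->head on the left side and head->tail on the
        # right side; the body is to the right of travel throughout
        etypes[i - 1] = segment_edge_type(k, "right")

    offs = _disk_offsets(hw)
    sets = []
    for i, p in enumerate(chain):
        if anchor_of[i] >= 0:
            # capsule: disks along the segment from the true-tip anchor
            a = mid_n[anchor_of[i]]
            length = np.hypot(*(p - a))
            ts = np.linspace(0, 1, max(2, int(length) + 1))[:, None]
            centers = np.rint(a[None, :] * (1 - ts) + p[None, :] * ts).astype(int)
            pix = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        else:
            pix = np.rint(p).astype(int) + offs
        if image_shape is not None:
            h, w = image_shape
            pix = pix[(pix[:, 0] >= 0) & (pix[:, 0] < h)
                      & (pix[:, 1] >= 0) & (pix[:, 1] < w)]
        pix = np.unique(pix, axis=0)
        if len(pix) == 0:
            raise ValueError("admissible set empty (corridor outside image)")
        sets.append(pix)
    return FineSearchSpace(admissible_sets=sets, expected_dirs=dirs,
                           edge_types=etypes, head_tip_index=n,
                           hypothesized=chain)


def _lr_images(edges: EdgeMap, params: FineModelParams) -> np.ndarray:
    """Per-edge-type log-likelihood-ratio images."""
    return np.where(edges.arrays, params.lr_on, params.lr_off)


def _pair_scores(a: np.ndarray, b: np.ndarray, etype: int, beta: int,
                 lr_img: np.ndarray, params: FineModelParams) -> np.ndarray:
    """(len(a), len(b)) matrix of segment scores g_i for all point pairs.

    The segment is rasterized as a digital line from a to b, excluding the
    start point so joins are not double counted; each raster pixel adds the
    log-LR of the expected edge type.  The prior subtracts B per 45-degree
    step of deviation between the actual quantized direction and beta.
    Zero-length segments contribute only their (zero) prior term.
    """
    la, lb = len(a), len(b)
    delta = b[None, :, :] - a[:, None, :]
    cheb = np.abs(delta).max(axis=2)
    alpha = np.rint(np.arctan2(delta[..., 0], delta[..., 1])
                    / (np.pi / 4)).astype(int) % 8
    dev = np.abs(alpha - beta) % 8
    dev = np.minimum(dev, 8 - dev)
    g = np.where(cheb > 0, -params.B * dev.astype(float), 0.0)
    # chain points advance in small steps; long hops along an edge line
    # would re-collect evidence and are excluded outright
    g = np.where(cheb > params.max_step, -np.inf, g)
    h, w = lr_img.shape[1:]
    img = lr_img[etype]
    for d in np.unique(cheb):
        if d == 0 or d > params.max_step:
            continue
        ai, bi = np.nonzero(cheb == d)
        t = (np.arange(1, d + 1) / d)[None, :, None]
        pts = a[ai][:, None, :] + delta[ai, bi][:, None, :] * t
        pr = np.clip(np.rint(pts[..., 0]).astype(int), 0, h - 1)
        pc = np.clip(np.rint(pts[..., 1]).astype(int), 0, w - 1)
        g[ai, bi] += img[pr, pc].sum(axis=1)
    return g


def fine_objective(boundary: np.ndarray, edges: EdgeMap,
                   space: FineSearchSpace, params: FineModelParams) -> float:
    """Log-posterior (up to a constant) of a candidate boundary chain."""
    bd = np.asarray(boundary, dtype=int)
    if len(bd) != len(space.admissible_sets):
        raise ValueError("boundary length does not match the search space")
    lr_img = _lr_images(edges, params)
    total = 0.0
    for i in range(1, len(bd)):
        total += float(_pair_scores(bd[i - 1:i], bd[i:i + 1],
                                    int(space.edge_types[i - 1]),
                                    int(space.expected_dirs[i - 1]),
                                    lr_img, params)[0, 0])
    return total


def dp_solve(edges: EdgeMap, space: FineSearchSpace,
             params: FineModelParams, *, n_midline: int = 21
             ) -> FineInstantiation:
    """Exact maximizer of the fine objective over the product of admissible
    sets, by the standard chain dynamic program (Viterbi recursion)."""
    sets = space.admissible_sets
    lr_img = _lr_images(edges, params)
    m = len(sets)
    score = np.zeros(len(sets[0]))
    back: list[np.ndarray] = []
    for i in range(1, m):
        g = _pair_scores(sets[i - 1], sets[i], int(space.edge_types[i - 1]),
                         int(space.expected_dirs[i - 1]), lr_img, params)
        tot = score[:, None] + g
        back.append(np.argmax(tot, axis=0))
        score = np.max(tot, axis=0)
    j = int(np.argmax(score))
    best = float(score[j])
    idx = [j]
    for bk in reversed(back):
        j = int(bk[j])
        idx.append(j)
    idx.reverse()
    boundary = np.array([sets[i][k] for i, k in enumerate(idx)], dtype=int)
    midline = boundaries_to_midline_points(boundary, space.head_tip_index)
    # the raw midpoint sequence carries +/-1 px digitization jitter that
    # would bias the arc length upward; a short moving average removes it
    midline = _smooth_polyline(midline, 3)
    return FineInstantiation(boundary=boundary,
                             midline=_resample(midline, n_midline),
                             head_tip_index=space.head_tip_index,
                             log_post=best)


def boundaries_to_midline_points(boundary: np.ndarray, n: int) -> np.ndarray:
    """Pair eta_i with eta_{2n-i} and take midpoints: the midline from the
    tail (i=0) to the head tip (i=n)."""
    bd = np.asarray(boundary, dtype=float)
    if len(bd) != 2 * n + 1:
        raise ValueError("boundary must have 2n+1 points")
    return (bd[:n + 1] + bd[2 * n::-1][:n + 1]) / 2.0


def boundaries_to_midline(fine: FineInstantiation, n_samples: int = 21
                          ) -> np.ndarray:
    """Midline resampled at ``n_samples`` points equally spaced in arc
    length, from the tail to the head tip."""
    mid = boundaries_to_midline_points(fine.boundary, fine.head_tip_index)
    length = np.hypot(*np.diff(mid, axis=0).T).sum()
    if length <= 0:
        raise ValueError("degenerate boundary: zero-length midline")
    return _resample(mid, n_samples)
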