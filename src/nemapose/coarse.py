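"""Coarse MAP midline search on the feature grid.

The worm midline is modeled as a sequence of 8-neighbor coarse-grid points
whose consecutive directions turn by at most 45 degrees and which never
revisit a cell.  The likelihood rewards, for each point, the presence of the
feature type parallel to the incoming direction at the point itself (high
probability) and at its two orthogonal neighbors (medium probability),
relative to a background model in which every feature is rare.  A Gaussian
prior on the number of points encodes the expected worm length.

The search is head-first: head features seed short sub-instantiations (one
per cluster of head features), each of which is extended into a full body
instantiation from either end using body and double-body features.  At every
length the search keeps all candidates whose log-posterior is within DIFF of
the best one (at most one per endpoint), which interpolates between
depth-first behavior where features are informative and breadth-first
behavior where they are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy import ndimage

from .edges import (AXES, DIRS, EdgeMap, FeatureMap, FeatureMask,
                    ORIENT_TO_AXIS, detect_edges, detect_features)


class NoHeadDetected(RuntimeError):
    """Raised when no head feature fires anywhere in the frame."""


@dataclass
class CoarseModelParams:
    p_high: float = 0.6
    p_med: float = 0.35
    p_low: float = 0.002
    lam: float = 48.0      # expected midline length, coarse-grid units
    A: float = 4.0         # length-prior precision
    turn_penalty: float = 0.5   # smoothness prior: cost per 45-degree turn
    alpha: float = 3.0     # DIFF multiplier
    head_stop: int = 2     # non-improving iterations before head search stops
    body_stop: int = 3
    max_candidates: int = 64    # beam width cap (kept best-first)

    def __post_init__(self) -> None:
        if not (0 < self.p_low < self.p_med < self.p_high < 1):
            raise ValueError("need 0 < p_low < p_med < p_high < 1")
        if self.A < 0:
            raise ValueError("length-prior precision A must be >= 0")

    @property
    def diff(self) -> float:
        """Beam tolerance: alpha times the log-likelihood-ratio gap between
        a perfect and a worst-case additional point."""
        on = log(self.p_high) + 2 * log(self.p_med) - 3 * log(self.p_low)
        off = (log(1 - self.p_high) + 2 * log(1 - self.p_med)
               - 3 * log(1 - self.p_low))
        return self.alpha * (on - off)

    # log-likelihood-ratio terms against the all-background model
    @property
    def lr_on(self) -> float:
        return log(self.p_high / self.p_low)

    @property
    def lr_off(self) -> float:
        return log((1 - self.p_high) / (1 - self.p_low))

    @property
    def lr_med_on(self) -> float:
        return log(self.p_med / self.p_low)

    @property
    def lr_med_off(self) -> float:
        return log((1 - self.p_med) / (1 - self.p_low))


@dataclass
class CoarseInstantiation:
    """An ordered midline hypothesis on the coarse grid.

    ``points`` runs from the head tip (index 0) to the tail for final
    detections; ``head_len`` is the number of points contributed by the
    head sub-instantiation.  ``log_post`` is relative to the all-background
    model and omits the theta-independent background constant.
    """

    points: tuple[tuple[int, int], ...]
    head_len: int = 0
    log_lr: float = 0.0
    log_post: float = 0.0
    status: str = "ok"
    head_cluster: int = -1

    def __len__(self) -> int:
        return len(self.points)

    def check_invariants(self) -> None:
        pts = self.points
        if len(set(pts)) != len(pts):
            raise AssertionError("midline revisits a coarse cell")
        for a, b in zip(pts, pts[1:]):
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) != 1:
                raise AssertionError("consecutive points are not 8-neighbors")
        for a, b, c in zip(pts, pts[1:], pts[2:]):
            k1 = DIRS.index((b[0] - a[0], b[1] - a[1]))
            k2 = DIRS.index((c[0] - b[0], c[1] - b[1]))
            if min((k2 - k1) % 8, (k1 - k2) % 8) > 1:
                raise AssertionError("turn sharper than 45 degrees")


def log_length_prior(n: float, params: CoarseModelParams) -> float:
    """Unnormalized log prior -A (n - lambda)^2 on the midline length.

    ``n`` is the instantiation's arc length in coarse-grid units (diagonal
    steps count sqrt(2)), so that the prior measures the same physical
    quantity regardless of the path's heading.
    """
    return -params.A * (n - params.lam) ** 2


_SQRT2 = float(np.sqrt(2.0))

#: window (in steps) of the chord-length estimator used by the length prior
LENGTH_WINDOW = 4


def path_arc_length(points) -> float:
    """Arc length of a grid path in cell units (diagonal steps = sqrt 2)."""
    total = 0.0
    for a, b in zip(points, points[1:]):
        total += _SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0
    return total


def effective_length(points, window: int = LENGTH_WINDOW) -> float:
    """Smoothed length of a grid path, in cell units.

    The raw step count of an 8-connected path over-measures a digitized
    curve by up to ~30% (the staircase effect), and by different amounts
    depending on heading, so neither the point count nor the raw arc length
    is comparable with the physical worm length.  Summing the Euclidean
    chord over a sliding ``window`` of steps (divided by the window) removes
    the staircase excess while leaving straight and diagonal runs exact, so
    the expected-length prior can be stated directly in physical units.
    """
    pts = points
    total = 0.0
    for i in range(1, len(pts)):
        k = min(i, window)
        a, b = pts[i - k], pts[i]
        total += float(np.hypot(b[0] - a[0], b[1] - a[1])) / k
    return total


def _turn_state(points) -> tuple[int, int]:
    """Sign and run length of the trailing run of same-sign 45-degree
    turns of a grid path."""
    if len(points) < 3:
        return 0, 0
    ks = [DIRS.index((b[0] - a[0], b[1] - a[1]))
          for a, b in zip(points, points[1:])]
    turns = [((k2 - k1 + 4) % 8) - 4 for k1, k2 in zip(ks, ks[1:])]
    sign, run = 0, 0
    for t in turns:
        if t == 0:
            sign, run = 0, 0
        elif t == sign:
            run += 1
        else:
            sign, run = t, 1
    return sign, run


def admissible_extensions(inst_points, grid_shape) -> list[tuple[int, int]]:
    """The at-most-three continuations of the last step (turn 0 or +/-45
    degrees), excluding visited points and points off the grid."""
    if len(inst_points) < 2:
        raise ValueError("need at least two points to extend")
    (pr, pc), (cr, cc) = inst_points[-2], inst_points[-1]
    k = DIRS.index((cr - pr, cc - pc))
    visited = set(inst_points)
    out = []
    gh, gw = grid_shape
    for dk in (0, -1, 1):
        dr, dc = DIRS[(k + dk) % 8]
        q = (cr + dr, cc + dc)
        if 0 <= q[0] < gh and 0 <= q[1] < gw and q not in visited:
            out.append(q)
    return out


def _terms_table(feats: np.ndarray, params: CoarseModelParams) -> np.ndarray:
    """Per-cell, per-orientation log-LR increment table.

    ``table[o, r, c]`` equals ``_point_terms((r, c), o, ...)``: the high/low
    term at the cell plus the med/low terms at its two orthogonal neighbors
    (off-grid neighbors contribute nothing).
    """
    on = np.where(feats, params.lr_on, params.lr_off)
    med = np.where(feats, params.lr_med_on, params.lr_med_off)
    table = on.astype(float).copy()
    for o in range(4):
        dr, dc = AXES[ORIENT_TO_AXIS[o]]
        for sign in (1, -1):
            # target[r,c] += med[o, r+sdr, c+sdc], zero outside the grid
            shifted = np.zeros_like(med[o])
            sdr, sdc = sign * dr, sign * dc
            gh, gw = med[o].shape
            r0, r1 = max(0, -sdr), min(gh, gh - sdr)
            c0, c1 = max(0, -sdc), min(gw, gw - sdc)
            shifted[r0:r1, c0:c1] = med[o, r0 + sdr:r1 + sdr, c0 + sdc:c1 + sdc]
            table[o] += shifted
    return table


def _point_terms(point, orientation, feats, params: CoarseModelParams) -> float:
    """Background-relative log-LR of the features around one midline point
    whose incoming direction has the given orientation."""
    gh, gw = feats.shape[1:]
    r, c = point
    s = params.lr_on if feats[orientation, r, c] else params.lr_off
    dr, dc = AXES[ORIENT_TO_AXIS[orientation]]
    for sign in (1, -1):
        nr, nc = r + sign * dr, c + sign * dc
        if 0 <= nr < gh and 0 <= nc < gw:
            s += params.lr_med_on if feats[orientation, nr, nc] \
                else params.lr_med_off
    return s


def point_log_lr(inst_tail, new_point, feats: np.ndarray,
                 params: CoarseModelParams) -> float:
    """Log-likelihood increment from appending ``new_point``.

    ``feats`` is a (4, Hh, Hw) boolean array of the features used by the
    current search stage.  Only the terms at the new point (high vs low
    probability for the feature parallel to the last step) and at its two
    orthogonal nearest neighbors (medium vs low) survive relative to the
    all-background model.
    """
    cur = inst_tail[-1]
    dr, dc = new_point[0] - cur[0], new_point[1] - cur[1]
    if (dr, dc) not in DIRS:
        raise ValueError("new point is not an 8-neighbor of the endpoint")
    gh, gw = feats.shape[1:]
    if not (0 <= new_point[0] < gh and 0 <= new_point[1] < gw):
        raise ValueError("new point outside the coarse grid")
    o = DIRS.index((dr, dc)) % 4
    return _point_terms(new_point, o, feats, params)


#: maximal run of consecutive same-sign 45-degree turns (a longer run would
#: bend tighter than the biomechanical curvature limit permits)
MAX_TURN_RUN = 3


@dataclass
class _Cand:
    points: tuple[tuple[int, int], ...]
    log_lr: float
    length: float       # smoothed arc length in cell units
    order: int          # creation order, for deterministic tie-breaking
    turn_sign: int = 0  # sign of the current run of turns
    turn_run: int = 0   # length of that run


def beam_search(seed, feats: np.ndarray, params: CoarseModelParams,
                stage: str = "body", *, seed_log_lr: float | None = None,
                max_iters: int | None = None) -> CoarseInstantiation:
    """Grow the seed instantiation one point at a time, tracking every
    candidate within DIFF of the best posterior (one per endpoint), and stop
    after a stage-specific number of non-improving iterations.

    ``seed`` is a tuple of at least two points; for the body stage it is
    typically a whole head sub-instantiation, so the length prior applies to
    the total point count.  The head stage scores only the seed's features
    and uses a uniform length prior (the prior concerns the full midline,
    not the head sub-sequence).
    """
    if stage not in ("head", "body"):
        raise ValueError("stage must be 'head' or 'body'")
    stop_after = params.head_stop if stage == "head" else params.body_stop
    use_prior = stage == "body"
    grid_shape = feats.shape[1:]
    table = _terms_table(feats, params)

    def prior(length: float) -> float:
        return log_length_prior(length, params) if use_prior else 0.0

    def rank(lr: float, length: float) -> float:
        # prospective posterior: candidates shorter than lambda can still
        # grow into a zero prior penalty, so ranking them by their current
        # prior would reward fast length growth (diagonal steps) over
        # evidence.  The admissible bound max_{L' >= L} prior(L') makes
        # same-iteration candidates comparable regardless of step geometry.
        return lr + prior(max(length, params.lam))

    seed = tuple(tuple(p) for p in seed)
    if seed_log_lr is None:
        # score the seed pair: both points under the seed direction
        o = DIRS.index((seed[1][0] - seed[0][0], seed[1][1] - seed[0][1])) % 4
        seed_log_lr = float(table[o][seed[0]] + table[o][seed[1]])
    counter = 0
    best = _Cand(seed, seed_log_lr, effective_length(seed), counter)
    best.turn_sign, best.turn_run = _turn_state(seed)
    best_post = seed_log_lr + prior(best.length)
    best_rank = rank(seed_log_lr, best.length)
    candidates = [best]
    since_improve = 0
    if max_iters is None:
        max_iters = int(4 * params.lam) + 20
    for _ in range(max_iters):
        new: dict[tuple[tuple[int, int], int], _Cand] = {}
        for cand in candidates:
            end = cand.points[-1]
            prev = cand.points[-2]
            k_last = DIRS.index((end[0] - prev[0], end[1] - prev[1]))
            for q in admissible_extensions(cand.points, grid_shape):
                k_new = DIRS.index((q[0] - end[0], q[1] - end[1]))
                turn = ((k_new - k_last + 4) % 8) - 4   # -1, 0 or +1
                if turn == 0:
                    sign, run = 0, 0
                elif turn == cand.turn_sign:
                    sign, run = turn, cand.turn_run + 1
                    if run > MAX_TURN_RUN:   # tighter than the worm can bend
                        continue
                else:
                    sign, run = turn, 1
                lr = cand.log_lr + table[k_new % 4][q]
                if turn != 0:   # smoothness prior on direction changes
                    lr -= params.turn_penalty
                kw = min(len(cand.points), LENGTH_WINDOW)
                anchor = cand.points[-kw]
                length = cand.length + float(
                    np.hypot(q[0] - anchor[0], q[1] - anchor[1])) / kw
                if rank(lr, length) < best_rank - params.diff:
                    continue
                counter += 1
                key = (q, k_new)
                old = new.get(key)
                if old is None or rank(lr, length) > rank(old.log_lr,
                                                          old.length):
                    new[key] = _Cand(cand.points + (q,), lr, length, counter,
                                     sign, run)
        if not new:
            break
        candidates = list(new.values())
        if len(candidates) > params.max_candidates:
            candidates.sort(key=lambda c: (-rank(c.log_lr, c.length), c.order))
            candidates = candidates[: params.max_candidates]
        it_best = max(candidates,
                      key=lambda c: (c.log_lr + prior(c.length), -c.order))
        it_post = it_best.log_lr + prior(it_best.length)
        best_rank = max(best_rank,
                        max(rank(c.log_lr, c.length) for c in candidates))
        if it_post > best_post:
            best, best_post = it_best, it_post
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= stop_after:
                break
    return CoarseInstantiation(points=best.points, log_lr=best.log_lr,
                               log_post=best_post)


def find_head_candidates(features: FeatureMap, max_clusters: int = 3
                         ) -> list[list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Cluster head-feature cells and emit seed pairs per cluster.

    Clusters are 8-connected components of cells where any head orientation
    fired, ordered by size (largest first).  Within a cluster the cell with
    the most head-feature support seeds the search, paired with each in-grid
    neighbor whose direction matches a fired head orientation.
    """
    any_head = features.head.any(axis=0)
    if not any_head.any():
        raise NoHeadDetected("no head feature fired anywhere in the frame")
    labels, n_lab = ndimage.label(any_head, structure=np.ones((3, 3), int))
    support = features.head.sum(axis=0)
    gh, gw = any_head.shape
    clusters = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        clusters.append(cells)
    clusters.sort(key=lambda c: (-len(c), tuple(map(tuple, c[:1]))))
    out = []
    for cells in clusters[:max_clusters]:
        sup = support[cells[:, 0], cells[:, 1]]
        order = np.lexsort((cells[:, 1], cells[:, 0], -sup))
        r0, c0 = map(int, cells[order[0]])
        fired = sorted({int(o) for o in range(4)
                        if features.head[o, cells[:, 0], cells[:, 1]].any()})
        seeds = []
        for k, (dr, dc) in enumerate(DIRS):
            if k % 4 not in fired:
                continue
            q = (r0 + dr, c0 + dc)
            if 0 <= q[0] < gh and 0 <= q[1] < gw:
                seeds.append(((r0, c0), q))
        if seeds:
            out.append(seeds)
    if not out:
        raise NoHeadDetected("head clusters produced no admissible seed")
    return out


def rescore_path(points, feats: np.ndarray, params: CoarseModelParams) -> float:
    """Accumulated log-LR plus turn penalties of a whole path (the length
    prior is not included).  Used to re-book a path after reversal, because
    per-point orientations are tied to the incoming step and shift when the
    traversal direction flips."""
    table = _terms_table(feats, params)
    ks = [DIRS.index((b[0] - a[0], b[1] - a[1]))
          for a, b in zip(points, points[1:])]
    lr = table[ks[0] % 4][points[0]]
    for q, k in zip(points[1:], ks):
        lr += table[k % 4][q]
    pen = params.turn_penalty * sum(k2 != k1 for k1, k2 in zip(ks, ks[1:]))
    return float(lr - pen)


def _extend_both_ends(head_inst: CoarseInstantiation, feats: np.ndarray,
                      params: CoarseModelParams) -> CoarseInstantiation:
    """Body search starting from either end of the head sub-instantiation.

    Each start is followed by a second pass from the far end of its result,
    so the full worm is covered even when the head sub-instantiation sits
    away from the true head (e.g. a false-positive head cluster mid-body).
    """
    results = []
    m = len(head_inst.points)
    for pts in (head_inst.points, head_inst.points[::-1]):
        first = beam_search(pts, feats, params, stage="body",
                            seed_log_lr=rescore_path(pts, feats, params))
        rev = first.points[::-1]
        # the far end is the head tip, already localized by head features;
        # allow only a small correction there, so the length prior pushes
        # any remaining deficit toward the featureless tail taper instead
        # of through a head-body contact zone
        res = beam_search(rev, feats, params, stage="body",
                          seed_log_lr=rescore_path(rev, feats, params),
                          max_iters=3)
        res.head_len = m
        results.append(res)
    return max(results, key=lambda r: r.log_post)


@dataclass
class CoarseDetection:
    instantiation: CoarseInstantiation
    features: FeatureMap
    edges: EdgeMap
    status: str  # 'ok' | 'low_confidence'


def detect_coarse(image: np.ndarray, params: CoarseModelParams,
                  masks: list[FeatureMask], *, coarse_unit: int,
                  edge_threshold: float,
                  fallback_body_seed: bool = True) -> CoarseDetection:
    """Full coarse detection: edges, features, head-candidate search, body
    search from both head ends, highest-posterior instantiation wins.

    If no head feature fires, and ``fallback_body_seed`` is set, a body-only
    search is seeded at the strongest body-feature cell and the result is
    flagged low-confidence; otherwise ``NoHeadDetected`` propagates.
    """
    edges = detect_edges(image, edge_threshold)
    features = detect_features(edges, masks, coarse_unit)
    body_ev = features.body_evidence()
    status = "ok"
    full: list[CoarseInstantiation] = []
    try:
        clusters = find_head_candidates(features)
        # the head is a short anatomical sub-sequence (~15-20% of the body),
        # and the head stage has no length prior, so cap its growth
        head_cap = max(4, int(0.2 * params.lam))
        for ci, seeds in enumerate(clusters):
            heads = [beam_search(s, features.head, params, stage="head",
                                 max_iters=head_cap)
                     for s in seeds]
            head_best = max(heads, key=lambda h: (h.log_post, -len(h.points)))
            res = _extend_both_ends(head_best, body_ev, params)
            res.head_cluster = ci
            # orient head-first: the end nearer the cluster's anchor cell
            anchor = seeds[0][0]
            d0 = max(abs(res.points[0][0] - anchor[0]),
                     abs(res.points[0][1] - anchor[1]))
            d1 = max(abs(res.points[-1][0] - anchor[0]),
                     abs(res.points[-1][1] - anchor[1]))
            if d1 < d0:
                res.points = res.points[::-1]
            full.append(res)
    except NoHeadDetected:
        if not fallback_body_seed:
            raise
        status = "low_confidence"
    truncated = all(effective_length(r.points) < 0.85 * params.lam
                    for r in full)
    if not full or truncated:
        # no usable head cluster, or every head-anchored result is clearly
        # shorter than the expected worm (e.g. a false-positive cluster
        # mid-body whose tip side may not be extended): fall back to seeds
        # on the strongest body stretch; head identity is then unanchored
        status = "low_confidence"
        full.extend(_body_only_search(body_ev, params))
    if not full:
        raise NoHeadDetected("no feature evidence to seed any search")
    winner = max(full, key=lambda r: (r.log_post, -len(r.points)))
    winner.status = status
    winner.check_invariants()
    return CoarseDetection(instantiation=winner, features=features,
                           edges=edges, status=status)


def _body_only_search(body_ev: np.ndarray,
                      params: CoarseModelParams) -> list[CoarseInstantiation]:
    support = body_ev.sum(axis=0)
    if support.max() == 0:
        return []
    r0, c0 = np.unravel_index(int(support.argmax()), support.shape)
    gh, gw = support.shape
    fired = [o for o in range(4) if body_ev[o, r0, c0]] or list(range(4))
    out = []
    for k, (dr, dc) in enumerate(DIRS):
        if k % 4 not in fired:
            continue
        q = (r0 + dr, c0 + dc)
        if not (0 <= q[0] < gh and 0 <= q[1] < gw):
            continue
        first = beam_search(((r0, c0), q), body_ev, params, stage="body")
        # second pass from the far end to cover the other half of the worm
        rev = first.points[::-1]
        res = beam_search(rev, body_ev, params, stage="body",
                          seed_log_lr=rescore_path(rev, body_ev, params))
        res.head_len = 0
        res.status = "low_confidence"
        out.append(res)
    return out


def enumerate_best(seeds, feats: np.ndarray, params: CoarseModelParams,
                   max_len: int, *, use_prior: bool = True) -> float:
    """Exhaustive search oracle: the best log-posterior over every
    admissible instantiation reachable from the seeds with at most
    ``max_len`` points.  Intended for small grids in tests."""
    grid_shape = feats.shape[1:]
    table = _terms_table(feats, params)

    def prior(length):
        return log_length_prior(length, params) if use_prior else 0.0

    best = -np.inf

    def rec(points, lr, length):
        nonlocal best
        best = max(best, lr + prior(length))
        if len(points) >= max_len:
            return
        end, prev = points[-1], points[-2]
        k_last = DIRS.index((end[0] - prev[0], end[1] - prev[1]))
        sign, run = _turn_state(points)
        for q in admissible_extensions(points, grid_shape):
            k_new = DIRS.index((q[0] - end[0], q[1] - end[1]))
            turn = ((k_new - k_last + 4) % 8) - 4
            if turn != 0 and turn == sign and run + 1 > MAX_TURN_RUN:
                continue
            pen = params.turn_penalty if turn != 0 else 0.0
            kw = min(len(points), LENGTH_WINDOW)
            anchor = points[-kw]
            step = float(np.hypot(q[0] - anchor[0], q[1] - anchor[1])) / kw
            rec(points + (q,), lr + table[k_new % 4][q] - pen, length + step)

    for seed in seeds:
        seed = tuple(tuple(p) for p in seed)
        o = DIRS.index((seed[1][0] - seed[0][0], seed[1][1] - seed[0][1])) % 4
        lr = float(table[o][seed[0]] + table[o][seed[1]])
        rec(seed, lr, effective_length(seed))
    return best
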