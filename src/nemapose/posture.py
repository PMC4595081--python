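"""Posture analytics: angles, coils, locomotion, eigenworms, events.

The midline of each frame is divided into 20 equal arc-length intervals and
represented by the 18 signed relative angles between next-nearest-neighbor
interval pairs, a discrete proxy for body curvature.  On top of this
representation the module provides coil detection (head or tail within a
fraction of the midline length of another body point), locomotion-state
classification from bend propagation, PCA eigenworms with spool
classification from the two leading amplitudes, k-means posture clustering,
coil-event extraction with Weibull duration fits, and transition-aligned
summaries of locomotion around coiling and dwelling events.

Sign convention: angles are positive for counter-clockwise turning in image
coordinates (row down, column right), i.e. the cross product
``dr1*dc2 - dc1*dr2`` of successive interval vectors is positive.  Mapping
the sign to dorsal/ventral requires knowing the animal's ventral side,
which real assays record and the synthetic generator defines; when it is
not configured the direction is reported as ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

N_INTERVALS = 20
N_ANGLES = 18

STATES = ("forward", "backward", "dwell", "quiescent")


@dataclass
class PostureAngles:
    angles: np.ndarray          # (18,) radians, tail-to-head ordering
    frame_time: float = 0.0     # seconds

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (N_ANGLES,):
            raise ValueError(f"expected {N_ANGLES} angles")


@dataclass
class CoilAnnotation:
    anterior: bool
    posterior: bool
    direction: str = "unknown"   # 'dorsal' | 'ventral' | 'unknown'


@dataclass
class EigenDecomposition:
    modes: np.ndarray               # (18, 18) rows = orthonormal modes
    mean: np.ndarray                # (18,)
    amplitudes: np.ndarray          # (n_frames, 18) projections
    explained_variance: np.ndarray  # (18,) fractions, non-increasing

    def project(self, angles: np.ndarray) -> np.ndarray:
        """Mode amplitudes of one or more posture vectors."""
        a = np.atleast_2d(np.asarray(angles, dtype=float))
        return (a - self.mean) @ self.modes.T

    def reconstruct(self, amplitudes: np.ndarray, n_modes: int | None = None
                    ) -> np.ndarray:
        amp = np.atleast_2d(np.asarray(amplitudes, dtype=float))
        k = amp.shape[1] if n_modes is None else n_modes
        return amp[:, :k] @ self.modes[:k] + self.mean


@dataclass
class CoilEvent:
    start: int            # first coil-positive frame
    end: int              # last coil-positive frame (inclusive)
    kind: str             # 'anterior' | 'posterior'
    duration: float       # seconds
    direction: str = "unknown"


def resample_midline(midline: np.ndarray, n_points: int) -> np.ndarray:
    pts = np.asarray(midline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("midline must be an (n, 2) polyline")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate midline of zero length")
    t = np.linspace(0, s[-1], n_points)
    return np.stack([np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])],
                    axis=1)


def midline_angles(midline: np.ndarray, frame_time: float = 0.0) -> PostureAngles:
    """The 18 relative angles between next-nearest-neighbor intervals.

    The midline (tail first) is resampled to 20 equal arc-length intervals;
    angle ``j`` is the signed angle between interval ``j`` and interval
    ``j+2``, so the vector runs from the most posterior pair (index 0) to
    the most anterior (index 17).
    """
    pts = resample_midline(midline, N_INTERVALS + 1)
    v = np.diff(pts, axis=0)                       # 20 interval vectors
    a, b = v[:-2], v[2:]                           # next-nearest pairs
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    return PostureAngles(angles=np.arctan2(cross, dot), frame_time=frame_time)


def posterior_body_angle(angles: PostureAngles) -> float:
    """The most posterior of the 18 relative angles (tail bend direction)."""
    return float(angles.angles[0])


def detect_coils(midline: np.ndarray, head: np.ndarray, tail: np.ndarray,
                 fraction: float = 0.05, exclusion_frac: float = 0.15,
                 chirality: str | None = None) -> CoilAnnotation:
    """Anterior / posterior coil flags for one posture.

    The anterior flag is set when the head end lies within ``fraction`` of
    the midline arc length (Euclidean distance) of any midline point more
    than ``exclusion_frac`` of the arc length away from the head; the
    posterior flag is symmetric for the tail.  The two flags are not
    mutually exclusive.  The turn direction is the sign of the summed
    relative angles between the end and its nearest approach; it is mapped
    to dorsal/ventral only when ``chirality`` is given (``'ccw-ventral'`` or
    ``'cw-ventral'``).
    """
    pts = resample_midline(midline, 101)           # 1% arc resolution
    if np.hypot(*(pts[0] - np.asarray(tail))) > np.hypot(*(pts[0] - np.asarray(head))):
        pts = pts[::-1]                            # force tail-first order
    length = np.hypot(*np.diff(pts, axis=0).T).sum()
    thresh = fraction * length
    k = int(round(exclusion_frac * 100))

    def _coiled(end_idx: int, body: np.ndarray) -> tuple[bool, int]:
        d = np.hypot(*(body - pts[end_idx]).T)
        j = int(np.argmin(d))
        return bool(d[j] < thresh), j

    ant, ja = _coiled(-1, pts[: 101 - k])
    post, jp = _coiled(0, pts[k:])
    direction = "unknown"
    if chirality in ("ccw-ventral", "cw-ventral") and (ant or post):
        ang = midline_angles(pts).angles
        if ant:
            lo = max(0, int(ja * N_ANGLES / 100) - 1)
            turn = ang[lo:].sum()
        else:
            hi = min(N_ANGLES, int((jp + k) * N_ANGLES / 100) + 1)
            turn = ang[:hi].sum()
        ccw = turn > 0
        direction = "ventral" if ccw == (chirality == "ccw-ventral") else "dorsal"
    return CoilAnnotation(anterior=ant, posterior=post, direction=direction)


def classify_locomotion(series: np.ndarray, fps: float,
                        window: float = 2.0, *, motion_threshold: float = 0.01,
                        coherence_threshold: float = 0.1) -> list[str]:
    """Per-frame locomotion state from the dynamics of the 18 angles.

    Bend propagation is estimated in a centered window around each frame by
    the lag-1 cross-correlation asymmetry between each angle and its
    posterior neighbor: coherent anterior-to-posterior propagation marks
    forward locomotion, the reverse marks backward.  Frames whose mean
    absolute angle change falls below ``motion_threshold`` (radians/frame)
    are quiescent; frames with motion but no coherent propagation are
    dwelling.
    """
    a = np.asarray(series, dtype=float)
    if a.ndim != 2 or a.shape[1] != N_ANGLES:
        raise ValueError("series must be (n_frames, 18)")
    half = int(round(window * fps / 2))
    if len(a) < 2 * half + 2:
        raise ValueError("series shorter than the analysis window")
    states = []
    dadt = np.abs(np.diff(a, axis=0)).mean(axis=1)
    for t in range(len(a)):
        lo, hi = max(0, t - half), min(len(a), t + half + 1)
        w = a[lo:hi]
        move = dadt[max(0, lo - 1):hi - 1].mean() if hi - lo > 1 else 0.0
        if move < motion_threshold:
            states.append("quiescent")
            continue
        x = w - w.mean(axis=0)
        sd = x.std(axis=0) + 1e-12
        # angle j is posterior to angle j+1 (tail-to-head ordering)
        fwd, bwd = 0.0, 0.0
        for j in range(N_ANGLES - 1):
            post_a, ant_a = x[:, j], x[:, j + 1]
            # anterior leads posterior: ant(t) correlates with post(t+1)
            fwd += (ant_a[:-1] * post_a[1:]).mean() / (sd[j] * sd[j + 1])
            bwd += (post_a[:-1] * ant_a[1:]).mean() / (sd[j] * sd[j + 1])
        score = (fwd - bwd) / (N_ANGLES - 1)
        if score > coherence_threshold:
            states.append("forward")
        elif score < -coherence_threshold:
            states.append("backward")
        else:
            states.append("dwell")
    return states


def eigenworms(angle_matrix: np.ndarray) -> EigenDecomposition:
    """Principal decomposition of mean-centered 18-angle posture vectors.

    Modes are orthonormal; explained-variance fractions are non-increasing
    and sum to one; reconstruction from all modes is exact.
    """
    a = np.asarray(angle_matrix, dtype=float)
    if a.ndim != 2 or a.shape[1] != N_ANGLES:
        raise ValueError("angle matrix must be (n_frames, 18)")
    if a.shape[0] < N_ANGLES + 1:
        raise ValueError("need at least 19 frames for the decomposition")
    mean = a.mean(axis=0)
    x = a - mean
    # SVD of the data matrix: right singular vectors are the modes
    _, s, vt = np.linalg.svd(x, full_matrices=True)
    # deterministic sign convention: each mode's largest-magnitude loading
    # is positive (SVD signs are otherwise arbitrary)
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    var = np.zeros(N_ANGLES)
    var[: len(s)] = s ** 2
    total = var.sum()
    ev = var / total if total > 0 else var
    return EigenDecomposition(modes=vt, mean=mean, amplitudes=x @ vt.T,
                              explained_variance=ev)


def classify_spool(a1: float, a2: float) -> str:
    """Spool taxonomy from the product of the two leading amplitudes."""
    prod = a1 * a2
    if prod > 4:
        return "severe_spool"
    if prod > 1:
        return "spool"
    if prod < -4:
        return "figure8"
    return "neither"


def cluster_postures(amplitudes: np.ndarray, k: int = 50, redundancy: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-means over mode amplitudes, restarted ``redundancy`` times with
    distinct seeds, keeping the lowest-inertia solution.

    Returns (centroids, assignments, population counts), with clusters
    sorted by population (largest first).
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.ndim != 2:
        raise ValueError("amplitudes must be 2-D")
    if len(x) < k:
        raise ValueError(f"need at least k={k} postures, got {len(x)}")
    best = None
    for r in range(redundancy):
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + r).fit(x)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    counts = np.bincount(best.labels_, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return best.cluster_centers_[order], remap[best.labels_], counts[order]


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end-inclusive) index pairs."""
    f = np.asarray(flags, dtype=bool)
    if not f.any():
        return []
    d = np.diff(f.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if f[0]:
        starts.insert(0, 0)
    if f[-1]:
        ends.append(len(f) - 1)
    return list(zip(starts, ends))


@dataclass
class CoilStats:
    events: list[CoilEvent]
    frequency: float                   # events per second
    durations: np.ndarray              # seconds
    weibull_shape: float | None
    weibull_scale: float | None        # the characteristic duration
    fit_ok: bool


def extract_events(flags: np.ndarray, kind: str, fps: float,
                   directions: list[str] | None = None) -> list[CoilEvent]:
    """Maximal runs of coil-positive frames as events (exact partition of
    the positive frames; no frame lost or double counted)."""
    events = []
    for s, e in _runs(flags):
        direction = "unknown"
        if directions is not None:
            vals = [directions[i] for i in range(s, e + 1)
                    if directions[i] != "unknown"]
            if vals:
                direction = max(set(vals), key=vals.count)
        events.append(CoilEvent(start=s, end=e, kind=kind,
                                duration=(e - s + 1) / fps,
                                direction=direction))
    return events


def coil_event_stats(flags: np.ndarray, fps: float, kind: str = "anterior",
                     directions: list[str] | None = None,
                     min_events_for_fit: int = 5) -> CoilStats:
    """Event extraction plus a maximum-likelihood Weibull fit of durations.

    The fitted scale is the characteristic coil duration.  Durations under
    two frames are censored out of the fit (they are at the resolution
    limit); the fit is skipped, with a flag, when fewer than
    ``min_events_for_fit`` events remain.
    """
    flags = np.asarray(flags, dtype=bool)
    events = extract_events(flags, kind, fps, directions)
    total_time = len(flags) / fps
    durations = np.array([ev.duration for ev in events])
    fit_d = durations[durations >= 2.0 / fps]
    if len(fit_d) >= min_events_for_fit:
        shape, _, scale = stats.weibull_min.fit(fit_d, floc=0.0)
        fit_ok = True
    else:
        shape = scale = None
        fit_ok = False
    return CoilStats(events=events,
                     frequency=len(events) / total_time if total_time else 0.0,
                     durations=durations, weibull_shape=shape,
                     weibull_scale=scale, fit_ok=fit_ok)


@dataclass
class TransitionSummaries:
    aligned: pd.DataFrame        # state probabilities vs offset around events
    fraction_after_initiation: float | None
    propensities: pd.DataFrame   # during-coil vs baseline, per directed state
    n_events: int


def transition_summaries(states: list[str], coil_flags: np.ndarray,
                         fps: float, window: float = 5.0,
                         dwell_split: bool = True) -> TransitionSummaries:
    """Locomotion statistics aligned on coil events.

    Produces (a) per-offset state probabilities around coil-event entry and
    exit (and around dwell events, split by whether coiling followed the
    dwell onset); (b) the fraction of coil events that begin within
    ``window`` seconds of a forward or backward initiation; (c) the
    propensity of each directed state during coiling against its
    non-coiling baseline.
    """
    states = list(states)
    flags = np.asarray(coil_flags, dtype=bool)
    if len(states) != len(flags):
        raise ValueError("states and coil flags must be aligned")
    t = len(states)
    w = int(round(window * fps))
    events = _runs(flags)
    arr = np.array([STATES.index(s) for s in states])

    rows = []
    def _aligned(anchor: int, align: str, group: str) -> None:
        for off in range(-w, w + 1):
            i = anchor + off
            if 0 <= i < t:
                rows.append({"group": group, "align": align, "offset_s": off / fps,
                             "state": states[i]})

    dwell_runs = _runs(arr == STATES.index("dwell"))
    for s, e in events:
        _aligned(s, "entry", "coil")
        _aligned(e, "exit", "coil")
    if dwell_split:
        for s, e in dwell_runs:
            followed = flags[s:min(t, s + w + 1)].any()
            g = "dwell_then_coil" if followed else "dwell_no_coil"
            _aligned(s, "entry", g)
            _aligned(e, "exit", g)
    if rows:
        df = pd.DataFrame(rows)
        aligned = (df.groupby(["group", "align", "offset_s", "state"])
                   .size().unstack(fill_value=0))
        aligned = aligned.div(aligned.sum(axis=1), axis=0).reset_index()
    else:
        aligned = pd.DataFrame(columns=["group", "align", "offset_s"])

    # (b) coil events starting within `window` of a directed-locomotion start
    init_frames = [i for i in range(1, t)
                   if states[i] in ("forward", "backward")
                   and states[i - 1] not in (states[i],)]
    frac = None
    if events:
        hits = 0
        for s, _ in events:
            if any(0 <= s - i <= w for i in init_frames):
                hits += 1
        frac = hits / len(events)

    # (c) propensities during coiling vs baseline
    prop_rows = []
    in_coil = flags
    for st in ("forward", "backward", "dwell"):
        sel = arr == STATES.index(st)
        during = sel[in_coil].mean() if in_coil.any() else np.nan
        baseline = sel[~in_coil].mean() if (~in_coil).any() else np.nan
        prop_rows.append({"state": st, "during_coil": during,
                          "baseline": baseline})
    return TransitionSummaries(aligned=aligned,
                               fraction_after_initiation=frac,
                               propensities=pd.DataFrame(prop_rows),
                               n_events=len(events))
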