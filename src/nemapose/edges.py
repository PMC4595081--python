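"""Oriented binary edges and mid-level head/body features.

The first stage of the detector converts a grayscale frame into eight binary
edge arrays (four orientations, two polarities) and then into coarse-grid
feature arrays by testing small oriented arrangements of edges ("masks")
against a low-edge-probability background model.

Conventions used throughout the package
---------------------------------------
* Coordinates are ``(row, col)``, 0-based, origin at the top-left pixel.
* The eight unit step directions are indexed 0..7 in the order
  E, SE, S, SW, W, NW, N, NE (``DIRS``).
* An *orientation* is a direction modulo 180 degrees, indexed 0..3:
  0 = horizontal (E/W), 1 = the SE/NW diagonal, 2 = vertical (S/N),
  3 = the SW/NE diagonal.
* Edge differences are taken along one of four *axes* (``AXES``): for axis
  ``a`` with step vector ``d``, ``D(y) = I(y + d) - I(y)``.  An edge of axis
  ``a`` therefore has its edge *line* perpendicular to ``d``; the axis whose
  step is perpendicular to an orientation is given by ``ORIENT_TO_AXIS``.
* Polarity is the sign of the difference.  For a dark object on a light
  background, crossing the boundary along ``+d`` from outside to inside
  gives a negative difference (polarity -1) and inside to outside gives a
  positive one (polarity +1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

# Unit steps, indexed 0..7: E, SE, S, SW, W, NW, N, NE.
DIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)

# Difference axes: step vectors for the four orientations of edge pairs.
AXES: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

# Axis whose step vector is perpendicular to each segment orientation:
# orientation 0 (horizontal) -> axis 1 (vertical step), orientation 1
# (SE/NW diagonal) -> axis 3, orientation 2 (vertical) -> axis 0,
# orientation 3 (SW/NE diagonal) -> axis 2.
ORIENT_TO_AXIS: tuple[int, int, int, int] = (1, 3, 0, 2)

N_EDGE_TYPES = 8


def direction_index(dr: int, dc: int) -> int:
    """Index 0..7 of a unit step ``(dr, dc)`` in ``DIRS``."""
    return DIRS.index((int(np.sign(dr)), int(np.sign(dc))))


def orientation_of_direction(k: int) -> int:
    """Orientation index 0..3 of direction index ``k``."""
    return k % 4


def edge_index(axis: int, polarity: int) -> int:
    """Flat index 0..7 of the edge type with the given axis and polarity."""
    return axis * 2 + (0 if polarity > 0 else 1)


@dataclass
class EdgeMap:
    """Eight binary edge arrays on the image grid.

    ``arrays[edge_index(axis, polarity)]`` is a boolean array with the shape
    of the source image; several edge types may be set at the same pixel.
    """

    arrays: np.ndarray  # (8, H, W) bool
    threshold_used: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.arrays.shape[1:]

    def get(self, axis: int, polarity: int) -> np.ndarray:
        return self.arrays[edge_index(axis, polarity)]

    def counts(self) -> np.ndarray:
        """Total number of set pixels per edge type (length 8)."""
        return self.arrays.reshape(8, -1).sum(axis=1)


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image too small: {arr.shape}; need at least 8x8")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixel values")
    if np.any(arr < 0):
        raise ValueError("image contains negative intensities")
    return arr


def detect_edges(image: np.ndarray, threshold: float) -> EdgeMap:
    """Detect the eight oriented, polarized binary edge types.

    For each axis the intensity difference between adjacent pixels is
    computed; an edge is marked at the first pixel of the pair when the
    absolute difference exceeds ``threshold`` and strictly exceeds the
    absolute differences of the two flanking pairs along the same axis
    (one-dimensional non-maximum suppression).  Polarity is the sign of
    the difference.
    """
    arr = _validate_image(image)
    if threshold <= 0:
        raise ValueError("edge threshold must be positive")
    h, w = arr.shape
    out = np.zeros((N_EDGE_TYPES, h, w), dtype=bool)
    for axis, (dr, dc) in enumerate(AXES):
        # D(y) = I(y + d) - I(y) on the valid region, embedded at y.
        diff = np.zeros((h, w))
        rs = slice(0, h - dr) if dr else slice(None)
        cs = slice(0, w - dc) if dc > 0 else (slice(-dc, w) if dc < 0 else slice(None))
        # source slices for I(y + d)
        rs2 = slice(dr, h) if dr else slice(None)
        cs2 = slice(dc, w) if dc > 0 else (slice(0, w + dc) if dc < 0 else slice(None))
        diff[rs, cs] = arr[rs2, cs2] - arr[rs, cs]
        mag = np.abs(diff)
        # flanking pairs: shift the difference field by +/- d
        prev = np.zeros_like(mag)
        nxt = np.zeros_like(mag)
        prev[rs2, cs2] = mag[rs, cs]   # |D(y - d)| seen at y
        nxt[rs, cs] = mag[rs2, cs2]    # |D(y + d)| seen at y
        # strict on the forward flank, non-strict on the backward one, so a
        # two-pixel plateau of equal differences yields exactly one edge
        keep = (mag > threshold) & (mag >= prev) & (mag > nxt)
        out[edge_index(axis, +1)] = keep & (diff > 0)
        out[edge_index(axis, -1)] = keep & (diff < 0)
    return EdgeMap(arrays=out, threshold_used=float(threshold))


# ---------------------------------------------------------------------------
# Feature masks
# ---------------------------------------------------------------------------

@dataclass
class MaskArea:
    """One oriented band of elevated edge probability within a feature mask."""

    axis: int
    polarity: int
    offsets: np.ndarray        # (N, 2) int, relative to the test location
    attainable: int            # max count of a single digital edge line in the band
    min_frac: float = 0.25     # minimum fraction of attainable for the test


@dataclass
class FeatureMask:
    feature_type: str          # 'head' | 'body' | 'dbody'
    orientation: int           # 0..3
    areas: list[MaskArea]
    on_threshold: int
    register_offsets: np.ndarray = field(
        default_factory=lambda: np.zeros((1, 2), dtype=int))  # pixel offsets

    @property
    def max_count(self) -> int:
        return sum(a.attainable for a in self.areas)


def _unit(vec: tuple[int, int]) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    return v / np.hypot(*v)


def _band_offsets(orientation: int, center: np.ndarray,
                  half_len: float, half_wid: float) -> np.ndarray:
    """Integer offsets of a band centered at ``center``, elongated along the
    orientation's tangent and ``half_wid`` wide across it."""
    t = _unit(DIRS[orientation])
    n = np.array([-t[1], t[0]])
    reach = int(np.ceil(np.abs(center).max() + half_len + half_wid)) + 1
    rr, cc = np.mgrid[-reach:reach + 1, -reach:reach + 1]
    pr = rr - center[0]
    pc = cc - center[1]
    along = pr * t[0] + pc * t[1]
    across = pr * n[0] + pc * n[1]
    sel = (np.abs(along) <= half_len) & (np.abs(across) <= half_wid)
    return np.stack([rr[sel], cc[sel]], axis=1).astype(int)


def _attainable(orientation: int, half_len: float) -> int:
    """Pixels of a single digital edge line crossing the band lengthwise."""
    if orientation in (0, 2):
        return 2 * int(half_len) + 1
    return 2 * int(half_len / np.sqrt(2.0)) + 1


def build_masks(worm_width: float, threshold_frac: float = 0.55,
                head_threshold_frac: float = 0.7) -> list[FeatureMask]:
    """Construct the 12 feature masks (4 head, 4 body, 4 double-body).

    Body masks hold two inversely polarized edge bands one worm width apart;
    head masks add an inversely polarized inner pair (from the bright
    anterior core) at a quarter width around the axis; double-body masks
    place the outer bands two worm widths apart and, when fired, register
    body evidence at the centers of the two hypothesized body segments.
    The on-threshold is a fraction of the mask's maximum attainable edge
    count (one digital edge line per band); head masks use the higher
    ``head_threshold_frac`` so that outer edges alone can never account for
    a head detection.
    """
    w = float(worm_width)
    if w < 4:
        raise ValueError("worm_width must be at least 4 pixels")
    half_len = round(0.5 * w)           # band length = worm width
    half_wid = max(1, round(0.25 * w))  # band width 0.5 x width
    masks: list[FeatureMask] = []
    for o in range(4):
        axis = ORIENT_TO_AXIS[o]
        d = _unit(AXES[axis])
        att = _attainable(o, half_len)
        # diagonal bands are kept narrower: a long straight edge line of a
        # different orientation crossing the band must not reach threshold
        hw_o = half_wid if o in (0, 2) else max(1, round(0.125 * w))

        def area(dist: float, polarity: int, min_frac: float = 0.25) -> MaskArea:
            center = d * dist
            return MaskArea(axis=axis, polarity=polarity,
                            offsets=_band_offsets(o, center, half_len, hw_o),
                            attainable=att, min_frac=min_frac)

        outer = [area(-w / 2, -1), area(+w / 2, +1)]
        # the inner pair is weaker evidence (lower contrast core), so it only
        # needs a trace of support; the outer boundaries must both be seen
        inner = [area(-w / 4, +1, 0.1), area(+w / 4, -1, 0.1)]
        masks.append(FeatureMask(
            'body', o, outer,
            on_threshold=int(np.ceil(threshold_frac * 2 * att))))
        masks.append(FeatureMask(
            'head', o, outer + inner,
            on_threshold=int(np.ceil(head_threshold_frac * 4 * att))))
        reg = np.stack([np.rint(-d * w / 2), np.rint(d * w / 2)]).astype(int)
        masks.append(FeatureMask(
            'dbody', o, [area(-w, -1), area(+w, +1)],
            on_threshold=int(np.ceil(threshold_frac * 2 * att)),
            register_offsets=reg))
    return masks


# ---------------------------------------------------------------------------
# Feature detection on the coarse grid
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Binary feature arrays on the coarse grid.

    ``head``, ``body`` and ``dbody`` each have shape ``(4, Hh, Hw)`` indexed
    by orientation.  ``coarse_unit`` is the pixel size of one coarse cell.
    """

    head: np.ndarray
    body: np.ndarray
    dbody: np.ndarray
    coarse_unit: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.head.shape[1:]

    def cell_center(self, cell: tuple[int, int]) -> tuple[int, int]:
        u = self.coarse_unit
        return (cell[0] * u + u // 2, cell[1] * u + u // 2)

    def body_evidence(self) -> np.ndarray:
        """Body or double-body support, per orientation (used by the body
        stage of the coarse search)."""
        return self.body | self.dbody


def _area_kernel(offsets: np.ndarray) -> np.ndarray:
    """Odd-sized kernel centered on the test location, so that same-mode
    convolution with its flip computes ``count(y) = sum_off X(y + off)``."""
    reach = int(np.abs(offsets).max())
    k = np.zeros((2 * reach + 1, 2 * reach + 1))
    k[offsets[:, 0] + reach, offsets[:, 1] + reach] = 1.0
    return k


def detect_features(edges: EdgeMap, masks: list[FeatureMask],
                    coarse_unit: int, sharpen: bool = True) -> FeatureMap:
    """Run the likelihood-ratio count test for every mask at every coarse
    cell center and register fired features on the coarse grid.

    The count of matching edges in each band is computed by correlating the
    corresponding edge array with the band indicator; a feature fires where
    the summed count reaches the mask's on-threshold.
    """
    if coarse_unit < 1:
        raise ValueError("coarse_unit must be >= 1")
    h, w = edges.shape
    for m in masks:
        for a in m.areas:
            span = a.offsets.max(axis=0) - a.offsets.min(axis=0) + 1
            if span[0] > h or span[1] > w:
                raise ValueError("feature mask larger than image")
    gh, gw = int(np.ceil(h / coarse_unit)), int(np.ceil(w / coarse_unit))
    fmap = FeatureMap(
        head=np.zeros((4, gh, gw), dtype=bool),
        body=np.zeros((4, gh, gw), dtype=bool),
        dbody=np.zeros((4, gh, gw), dtype=bool),
        coarse_unit=int(coarse_unit),
    )
    # coarse cell centers in pixel coordinates
    cr = np.arange(gh) * coarse_unit + coarse_unit // 2
    cc = np.arange(gw) * coarse_unit + coarse_unit // 2
    cr = np.minimum(cr, h - 1)
    cc = np.minimum(cc, w - 1)

    count_cache: dict[tuple[int, int, bytes], np.ndarray] = {}
    for m in masks:
        total = np.zeros((gh, gw))
        support = np.ones((gh, gw), dtype=bool)
        for a in m.areas:
            key = (a.axis, a.polarity, a.offsets.tobytes())
            cnt = count_cache.get(key)
            if cnt is None:
                kern = _area_kernel(a.offsets)
                x = edges.get(a.axis, a.polarity).astype(float)
                # same-mode convolution with the flipped odd kernel is an
                # exact cross-correlation centered on the test pixel
                full = signal.fftconvolve(x, kern[::-1, ::-1], mode='same')
                cnt = np.rint(full)
                count_cache[key] = cnt
            here = cnt[np.ix_(cr, cc)]
            # saturate at one edge line per band: parallel duplicate lines
            # (e.g. from heavy blur) must not stand in for a missing band
            total += np.minimum(here, a.attainable)
            # ... and every band must hold its own minimum of evidence
            support &= here >= a.min_frac * a.attainable
        fired = (total >= m.on_threshold) & support
        if sharpen:
            # non-maximum suppression across the mask's perpendicular
            # direction: the count test peaks when centered on the segment
            # axis, and keeping only that crest makes feature chains one
            # cell wide (analogous to the pixel-level edge suppression)
            pdr, pdc = AXES[ORIENT_TO_AXIS[m.orientation]]
            prev = np.full((gh, gw), -1.0)
            nxt = np.full((gh, gw), -1.0)
            r0, r1 = max(0, pdr), min(gh, gh + pdr)
            c0, c1 = max(0, pdc), min(gw, gw + pdc)
            prev[r0:r1, c0:c1] = total[r0 - pdr:r1 - pdr, c0 - pdc:c1 - pdc]
            r0, r1 = max(0, -pdr), min(gh, gh - pdr)
            c0, c1 = max(0, -pdc), min(gw, gw - pdc)
            nxt[r0:r1, c0:c1] = total[r0 + pdr:r1 + pdr, c0 + pdc:c1 + pdc]
            fired &= (total >= prev) & (total > nxt)
        if m.feature_type == 'dbody':
            rr, ww = np.nonzero(fired)
            for off in m.register_offsets:
                tr = np.clip(((cr[rr] + off[0]) // coarse_unit), 0, gh - 1)
                tc = np.clip(((cc[ww] + off[1]) // coarse_unit), 0, gw - 1)
                fmap.dbody[m.orientation, tr, tc] = True
        elif m.feature_type == 'head':
            fmap.head[m.orientation] |= fired
        else:
            fmap.body[m.orientation] |= fired
    return fmap
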