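"""Synthetic worm postures, rendered frames, and behavior time series.

The generator emulates the imaging conditions the detector is designed for:
a single dark worm on a lighter, roughly uniform background, with a brighter
interior band in the anterior 15% of the body (the pharyngeal region, which
produces the inner edge pair that head features test for).  Photometric
perturbations cover digital contrast scalings of 0.5-1.5 and Gaussian blur
with sigma 2-3 px, plus additive Gaussian noise.

Postures are parametrized by curvature profiles over arc length built from
at most six smooth cosine basis functions, which keeps the posture ensemble
band-limited: straight, sinuous (crawling wave), omega (deep anterior bend
bringing the head close to the mid-body), spool (same-signed anterior and
posterior curvature winding more than a full turn), and figure-8 (opposite
end curvatures).  All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

FAMILIES = ("straight", "sinuous", "omega", "spool", "figure8", "random")

#: default mix of posture families for generated corpora
DEFAULT_MIX = {
    "straight": 0.10,
    "sinuous": 0.30,
    "omega": 0.20,
    "spool": 0.20,
    "figure8": 0.20,
}

#: biomechanical cap on curvature: minimal bend radius ~ one worm width
CURVATURE_CAP_WIDTHS = 1.0


@dataclass
class PostureSpec:
    """A worm posture: band-limited curvature plus pose and size."""

    curvature_coefficients: np.ndarray   # weights of cos((k-1) pi s), k=1..6
    length: float                        # px
    width: float                         # px
    position: tuple[float, float] = (0.0, 0.0)  # midline centroid (row, col)
    heading: float = 0.0                 # initial tangent angle, radians
    chirality: str = "ccw-ventral"
    family: str = "random"
    curvature_noise: np.ndarray | None = None  # per-sample additive curvature

    def midline(self, n: int = 200) -> np.ndarray:
        """Sample the midline at ``n`` equally spaced arc-length points,
        ordered tail (index 0) to head (index -1), in (row, col) pixels."""
        s = (np.arange(n) + 0.5) / n
        kappa = basis_curvature(self.curvature_coefficients, s)
        if self.curvature_noise is not None:
            noise = self.curvature_noise
            idx = np.minimum((s * len(noise)).astype(int), len(noise) - 1)
            kappa = kappa + noise[idx]
        ds = self.length / n
        psi = self.heading + np.concatenate(
            [[0.0], np.cumsum(kappa[:-1] + kappa[1:]) / 2 / n])
        pts = np.zeros((n, 2))
        steps = np.stack([np.sin(psi), np.cos(psi)], axis=1) * ds
        pts[1:] = np.cumsum(steps[:-1], axis=0)
        pts = pts - pts.mean(axis=0) + np.asarray(self.position)
        return pts


def basis_curvature(coeffs: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Curvature profile kappa(s) = sum_k c_k cos((k-1) pi s), in radians of
    total turning per unit normalized arc length."""
    coeffs = np.asarray(coeffs, dtype=float)
    out = np.zeros_like(s, dtype=float)
    for k, c in enumerate(coeffs):
        out += c * np.cos(k * np.pi * s)
    return out


def _max_curvature_px(spec: PostureSpec) -> float:
    s = np.linspace(0, 1, 400)
    kappa = np.abs(basis_curvature(spec.curvature_coefficients, s)) / spec.length
    return float(kappa.max())


def _check_cap(spec: PostureSpec) -> None:
    cap = 1.0 / (CURVATURE_CAP_WIDTHS * spec.width)
    if _max_curvature_px(spec) > cap + 1e-12:
        raise ValueError(
            f"curvature exceeds the biomechanical cap ({cap:.3g}/px)")


def _head_body_distance(midline: np.ndarray, exclusion: float = 0.15) -> float:
    """Distance from the head point to the nearest midline point more than
    ``exclusion`` of the arc length away from the head."""
    n = len(midline)
    head = midline[-1]
    cut = int((1 - exclusion) * n)
    d = np.hypot(*(midline[:cut] - head).T)
    return float(d.min())


def sample_posture(family: str, *, length: float = 100.0, width: float = 8.0,
                   seed: int = 0, noise_rel_power: float = 0.0) -> PostureSpec:
    """Draw one posture from the given family, deterministically per seed.

    ``noise_rel_power`` adds white curvature noise whose power is the given
    fraction of the band-limited signal power (used to stress the eigenmode
    analysis); it applies to the ``random`` family only.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown posture family {family!r}")
    rng = np.random.default_rng(seed)
    c = np.zeros(6)
    if family == "straight":
        pass
    elif family == "sinuous":
        # crawling wave: ~1.5 wavelengths along the body
        amp = rng.uniform(3.5, 5.5) * rng.choice([-1, 1])
        c[3] = amp                      # cos(3 pi s)
        c[1] = rng.normal(0, 0.4)
    elif family == "omega":
        # raised-cosine bump of curvature centered mid-body; the overall
        # scale is tuned so the head approaches the mid-body
        sign = rng.choice([-1, 1])
        base = np.zeros(6)
        base[0], base[2] = 0.5, -0.5    # 0.5 - 0.5 cos(2 pi s) >= 0
        base[1] = rng.normal(0, 0.05)
        spec = None
        for theta in np.linspace(4.5, 9.0, 19):
            trial = PostureSpec(sign * theta * base, length, width,
                                family="omega")
            if _head_body_distance(trial.midline()) < 0.05 * length:
                spec = trial
                break
        if spec is None:
            spec = trial
        c = spec.curvature_coefficients
    elif family == "spool":
        # monotone-radius spiral: winding > 2 pi with curvature growing
        # toward the head so successive whorls do not coincide
        sign = rng.choice([-1, 1])
        theta = rng.uniform(2.3, 2.9) * np.pi
        c[0] = sign * theta
        c[1] = -sign * theta * rng.uniform(0.35, 0.45)
    elif family == "figure8":
        sign = rng.choice([-1, 1])
        c[1] = sign * rng.uniform(13.0, 15.5)   # opposite-signed end lobes
    else:  # random: band-limited coiled ensemble
        sigma = np.array([2.5, 2.0, 1.6, 1.2, 1.0, 0.8])
        c = rng.normal(0, sigma)
    spec = PostureSpec(c, float(length), float(width),
                       heading=rng.uniform(0, 2 * np.pi), family=family)
    # enforce the curvature cap by uniform rescaling of the profile
    cap = 1.0 / (CURVATURE_CAP_WIDTHS * width)
    mx = _max_curvature_px(spec)
    if mx > cap:
        spec.curvature_coefficients = c * (cap / mx) * 0.999
    if family == "random" and noise_rel_power > 0:
        s = np.linspace(0, 1, 400)
        sig_power = np.mean(basis_curvature(spec.curvature_coefficients, s) ** 2)
        sd = np.sqrt(noise_rel_power * max(sig_power, 1e-12))
        spec.curvature_noise = rng.normal(0, sd, size=200)
    _check_cap(spec)
    return spec


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    posture: PostureSpec
    frame_shape: tuple[int, int] = (224, 224)
    background_level: float = 200.0
    body_level: float = 60.0
    head_core_level: float = 180.0
    contrast_scale: float = 1.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    midline: np.ndarray      # (21, 2) px, tail to head
    head: np.ndarray         # (2,) px
    tail: np.ndarray         # (2,) px
    length: float            # px
    body_mask: np.ndarray    # bool frame
    family: str = "random"


def _half_width_profile(s: np.ndarray, width: float) -> np.ndarray:
    """Tapered half-width: the tail (s=0) tapers sharply to a point, the
    head (s=1) is blunter and rounded."""
    h = np.full_like(s, width / 2.0)
    tail = s < 0.15
    h[tail] *= (s[tail] / 0.15) ** 0.8
    head = s > 0.92
    h[head] *= np.sqrt(np.clip(1 - ((s[head] - 0.92) / 0.08) ** 2, 0.0, 1.0))
    return h


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` points equally spaced in arc length."""
    pts = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate polyline with zero length")
    t = np.linspace(0, s[-1], n)
    return np.stack([np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])],
                    axis=1)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame and its exact (pre-perturbation) ground truth.

    A tapered tube of the posture's width is swept along the midline and
    filled at ``body_level``; the anterior 15% receives an interior band at
    ``head_core_level`` occupying the central half of the local width.
    Contrast scaling is applied about the background level, then blur and
    additive Gaussian noise.
    """
    h, w = spec.frame_shape
    post = spec.posture
    dense = post.midline(n=max(200, int(post.length)))
    margin = post.width / 2 + 2
    if (dense.min() < margin or dense[:, 0].max() > h - margin
            or dense[:, 1].max() > w - margin):
        raise ValueError("posture does not fit in the frame")
    n = len(dense)
    s_par = (np.arange(n) + 0.5) / n
    half_w = _half_width_profile(s_par, post.width)

    tree = cKDTree(dense)
    lo = np.floor(dense.min(axis=0) - margin).astype(int)
    hi = np.ceil(dense.max(axis=0) + margin).astype(int)
    rr, cc = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, idx = tree.query(pix, k=1)
    inside = dist <= half_w[idx]
    core = inside & (s_par[idx] >= 0.85) & (dist <= half_w[idx] * 0.5)

    img = np.full((h, w), spec.background_level, dtype=float)
    body_mask = np.zeros((h, w), dtype=bool)
    rs, cs = pix[:, 0].astype(int), pix[:, 1].astype(int)
    body_mask[rs[inside], cs[inside]] = True
    img[rs[inside], cs[inside]] = spec.body_level
    img[rs[core], cs[core]] = spec.head_core_level

    gt = GroundTruth(
        midline=resample_polyline(dense, 21),
        head=dense[-1].copy(), tail=dense[0].copy(),
        length=float(np.hypot(*np.diff(dense, axis=0).T).sum()),
        body_mask=body_mask, family=post.family,
    )

    img = spec.background_level + (img - spec.background_level) * spec.contrast_scale
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, None), gt


def generate_dataset(n: int, mix: dict[str, float] | None = None,
                     master_seed: int = 0, *, length: float = 100.0,
                     width: float = 8.0, frame_shape: tuple[int, int] = (224, 224),
                     perturb: bool = True) -> tuple[list[tuple[np.ndarray, GroundTruth]],
                                                    list[dict]]:
    """Generate a reproducible corpus of rendered frames with ground truth.

    Families are sampled from ``mix`` (default ``DEFAULT_MIX``).  With
    ``perturb`` on, each scene draws a contrast scale uniformly in
    [0.5, 1.5], a blur sigma from {0, 2, 3} and a small additive noise.
    Returns the scenes and a manifest of every scene's parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    fams = sorted(mix)
    probs = np.array([mix[f] for f in fams], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(master_seed)
    scenes: list[tuple[np.ndarray, GroundTruth]] = []
    manifest: list[dict] = []
    for i in range(n):
        fam = rng.choice(fams, p=probs)
        for attempt in range(20):
            seed = int(rng.integers(0, 2 ** 31 - 1))
            post = sample_posture(fam, length=length, width=width, seed=seed)
            post.position = (frame_shape[0] / 2, frame_shape[1] / 2)
            scene = SceneSpec(
                posture=post, frame_shape=frame_shape,
                contrast_scale=float(rng.uniform(0.5, 1.5)) if perturb else 1.0,
                blur_sigma=float(rng.choice([0.0, 2.0, 3.0])) if perturb else 0.0,
                noise_sd=2.0 if perturb else 0.0,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            try:
                img, gt = render_scene(scene)
                break
            except ValueError:
                continue
        else:  # pragma: no cover - frame is generously sized
            raise RuntimeError(f"could not fit a {fam} posture in the frame")
        scenes.append((img, gt))
        manifest.append({
            "frame_id": i, "family": fam, "seed": seed,
            "length": float(gt.length), "width": float(width),
            "contrast_scale": scene.contrast_scale,
            "blur_sigma": scene.blur_sigma, "noise_sd": scene.noise_sd,
            "noise_seed": scene.seed,
            "midline": gt.midline.tolist(),
        })
    return scenes, manifest


# ---------------------------------------------------------------------------
# Behavior simulation
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTruth:
    midlines: np.ndarray          # (T, 21, 2) px, tail to head
    states: list[str]             # per-frame ground-truth locomotion state
    anterior_coil: np.ndarray     # (T,) bool
    posterior_coil: np.ndarray    # (T,) bool
    fps: float


def _midline_from_bends(bends: np.ndarray, length: float,
                        origin=(0.0, 0.0), heading=0.0) -> np.ndarray:
    """Build a 21-point midline from 20 per-interval turning increments."""
    psi = heading + np.concatenate([[0.0], np.cumsum(bends)])
    step = length / 20.0
    pts = np.zeros((21, 2))
    pts[1:] = np.cumsum(np.stack([np.sin(psi), np.cos(psi)], axis=1) * step,
                        axis=0)[:20]
    return pts - pts.mean(axis=0) + np.asarray(origin)


def simulate_behavior(duration: float, fps: float = 10.0,
                      regime: str = "wildtype-like", *, length: float = 100.0,
                      seed: int = 0) -> BehaviorTruth:
    """Simulate a midline time series with ground-truth states and coils.

    Bends travel as a wave along the 20 body intervals; a positive phase
    velocity from head to tail marks forward locomotion.  Regimes:

    ``wildtype-like``
        mostly forward with occasional reversals and brief omega-like coils
        (coil flags on well under 5% of frames).
    ``static-coiler``
        bouts of dwelling locked into a frozen spool posture, with coil
        durations drawn from a Weibull distribution.
    ``loopy-mover``
        high-amplitude waves that repeatedly cross the coil threshold while
        directed locomotion continues.
    """
    t_frames = int(round(duration * fps))
    if t_frames < 100:
        raise ValueError("need at least 100 frames (duration * fps)")
    rng = np.random.default_rng(seed)
    j = np.arange(20) / 20.0
    freq = 0.5      # Hz, undulation frequency
    n_waves = 1.5

    states: list[str] = []
    midlines = np.zeros((t_frames, 21, 2))
    ant = np.zeros(t_frames, dtype=bool)
    post = np.zeros(t_frames, dtype=bool)

    if regime not in ("wildtype-like", "static-coiler", "loopy-mover"):
        raise ValueError(f"unknown regime {regime!r}")

    amp = {"wildtype-like": 0.28, "static-coiler": 0.25, "loopy-mover": 0.62}[regime]
    # schedule of (state, n_frames) bouts
    bouts: list[tuple[str, int]] = []
    total = 0
    while total < t_frames:
        if regime == "static-coiler" and bouts and bouts[-1][0] != "coil" \
                and rng.random() < 0.5:
            dur = max(5, int(rng.weibull(1.5) * 8.0 * fps))
            bouts.append(("coil", dur))
        elif regime == "wildtype-like" and bouts and bouts[-1][0] == "backward" \
                and rng.random() < 0.15:
            # brief omega-like coil at the end of a reversal
            bouts.append(("coil", max(3, int(0.7 * fps))))
        else:
            state = rng.choice(["forward", "backward", "dwell"],
                               p=[0.6, 0.25, 0.15])
            dur = max(5, int(rng.uniform(1.0, 4.0) * fps))
            bouts.append((state, dur))
        total += bouts[-1][1]

    spool = sample_posture("spool", length=length, width=8.0,
                           seed=seed + 1)
    spool_mid = resample_polyline(spool.midline(), 21)
    spool_bends = _bends_of(spool_mid)

    frame = 0
    phase = 0.0
    for state, dur in bouts:
        for _ in range(dur):
            if frame >= t_frames:
                break
            if state == "coil":
                bends = spool_bends + rng.normal(0, 0.015, 20)
                states.append("dwell")
                ant[frame] = True
                post[frame] = True
            else:
                if state == "forward":
                    phase += freq / fps
                elif state == "backward":
                    phase -= freq / fps
                bends = amp * np.sin(2 * np.pi * (phase + n_waves * j))
                bends += rng.normal(0, 0.01, 20)
                states.append(state)
                if regime == "loopy-mover":
                    bends *= 1.0 + 0.9 * np.sin(2 * np.pi * phase / 3.0) ** 2
            midlines[frame] = _midline_from_bends(bends, length)
            frame += 1
    # annotate loopy coils from geometry after the fact
    if regime == "loopy-mover":
        from .posture import detect_coils
        for k in range(t_frames):
            ann = detect_coils(midlines[k], midlines[k][-1], midlines[k][0])
            ant[k], post[k] = ann.anterior, ann.posterior
    return BehaviorTruth(midlines=midlines, states=states[:t_frames],
                         anterior_coil=ant, posterior_coil=post, fps=fps)


def _bends_of(midline: np.ndarray) -> np.ndarray:
    v = np.diff(midline, axis=0)
    ang = np.arctan2(v[:, 0], v[:, 1])
    d = np.diff(ang)
    return np.concatenate([[0.0], (d + np.pi) % (2 * np.pi) - np.pi])
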