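# nemapose

Single-frame detection of complex *C. elegans* postures, and the analytics
to quantify coiling phenotypes.

Standard worm trackers reconstruct the body midline by thresholding and
skeletonizing, which fails exactly where severe locomotion mutants live:
*coiled* (non-self-avoiding) postures, where the body touches or overlaps
itself. `nemapose` instead treats detection as maximum-a-posteriori
inference in a generative model of the image, using only a single frame —
no manual initialization, no error propagation between frames, and a
batch of frames is embarrassingly parallel.

**Who it is for:** researchers quantifying locomotion and coiling behavior
of single nematodes in grayscale video (one animal per frame, dark body on
a lighter background), and anyone who wants a fully synthetic,
ground-truthed benchmark for midline detectors.

## The model in brief

*Coarse stage.* Eight binary edge types `X_e(y)` (4 orientations x 2
polarities, adjacent-pixel differences with non-maximum suppression) are
aggregated into head/body/double-body features `X_f(z)` on a grid `H`
whose cell is a quarter worm width, by likelihood-ratio count tests of
oriented edge arrangements. A posture is a cell sequence
`theta = (theta_1 .. theta_n)` with at most 45-degree turns and no
revisits. Conditional on `theta`, the feature parallel to the local
direction appears at `theta_i` with probability `p_high`, at its two
orthogonal neighbors with `p_med`, and everywhere else with `p_low`; the
prior contributes `exp[-A (n - lambda)^2]` on the midline length. The MAP
sequence is found by a head-first candidate-tracked search that keeps all
instantiations within `DIFF` of the current best (one per endpoint and
arrival direction),

    DIFF = alpha { [log p_high + 2 log p_med - 3 log p_low]
                 - [log(1-p_high) + 2 log(1-p_med) - 3 log(1-p_low)] },
    alpha = 3.

*Fine stage.* The body boundary is a chain
`eta = (eta_0 .. eta_n .. eta_2n)` on the pixel grid — tail-left up to the
head tip and back to tail-right — restricted to corridors around the
offset coarse midline. Each segment expects one oriented, polarized edge
type with probability `p_obj` on the boundary vs `p_bg` elsewhere, plus a
prior `exp(-B sum_i |alpha_i - beta_i|)` on deviations from the predicted
segment orientations. The log-posterior is a sum over consecutive chain
points, so dynamic programming finds the exact global maximizer; midpoints
of opposite boundary points give the midline.

*Analytics.* The midline is resampled to 20 equal intervals; the 18
relative angles between next-nearest-neighbor intervals represent the
posture. On top of this: coil detection (an end within 5% of the midline
length of a distant body point), eigenworm PCA with spool classification
(`a1 * a2 > 1`), k-means posture clustering, locomotion states from bend
propagation, coil-event extraction with Weibull duration fits, and
transition-aligned summaries.

A synthetic generator renders ground-truthed scenes (straight, sinuous,
omega, spool, figure-8 and random band-limited postures; contrast 0.5-1.5,
blur sigma 2-3 px, additive noise) and behavior time series, so every
stage is testable without any recordings. See `docs/methods.md` for the
full account.

## Worked example

Render a blurred, low-contrast omega posture and detect it:

```python
import numpy as np
from nemapose import (RunConfig, SceneSpec, detect_coils, render_scene,
                      sample_posture)
from nemapose.cli import detect_frame
from nemapose.posture import midline_angles

post = sample_posture("omega", length=144, width=12, seed=13)
post.position = (160, 160)
img, truth = render_scene(SceneSpec(posture=post, frame_shape=(320, 320),
                                    contrast_scale=0.75, blur_sigma=2.0,
                                    noise_sd=2.0, seed=0))

rec = detect_frame(img, RunConfig())
mid = np.asarray(rec["midline"])
ann = detect_coils(mid, mid[-1], mid[0])
print("status:", rec["status"])
print("midline_length:", round(rec["midline_length"], 1),
      "true:", round(truth.length, 1))
print("anterior coil:", ann.anterior, " posterior coil:", ann.posterior)
print("posterior body angle (rad):",
      round(float(midline_angles(mid).angles[0]), 3))
```

prints

```
status: ok
midline_length: 148.6 true: 143.3
anterior coil: True  posterior coil: False
posterior body angle (rad): 0.3
```

The detected midline is within 4% of the true arc length despite the
posture being a closed loop at half contrast under 2 px blur, and the coil
classifier recognizes the omega's anterior coil from the detected midline
alone.

From the shell, the same pipeline is:

```
nemapose simulate --n 20 --seed 1 --out-dir frames/
nemapose detect frames/ --out detections.jsonl --workers 4
nemapose eval frames/manifest.json detections.jsonl --out report.json
nemapose analyze detections.jsonl --out-dir analysis/
```

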