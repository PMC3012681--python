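# Methods

## The detection model

A fixed camera films dark, slow objects on a light background. Write
`F_t(p) ∈ [0,1]` for the intensity of pixel `p` in frame `t` (0 = black).
FAST detection is

    M(p)   = mean_t F_t(p)                  (mean frame)
    R_t(p) = max(M(p) − F_t(p), 0)          (dark-object residual)
    mask_t = R_t > θ                        (strict threshold)

followed by connected-component labeling (8-adjacency by default),
inclusive size pruning to [2, 100] px, and unweighted centroids. The
residual is one-sided by design: the animals are darker than the
background, so brighter-than-average pixels carry no signal and clipping
them lets a single low threshold be used. Assumptions this rests on:

- the scene is static apart from the tracked animals (camera fixed,
  dish not bumped);
- an animal keeps moving on the scale of the movie, so its contribution
  to the mean frame is a faint ghost. A blob of contrast `c` that sits on
  a pixel for `k` of `N` frames leaves a ghost of depth `ck/N` there;
  detection needs `θ` above the ghost (satisfied whenever the animal
  spends ≲ θN/c frames per pixel; for `c = 0.4`, `θ = 0.028`, `N = 100`
  that is ~7 frames). The mean deliberately uses **all** frames,
  ghost included.
- the animal is *dark*: 0 = black, 1 = white throughout; color input is
  channel-averaged on load (monochrome-camera convention).

The plain-threshold baseline is `(1 − F_t) > θ_b` on the raw frame. Its
polarity is fixed the only way consistent with its known failure modes: a
high cutoff selects only very dark pixels and loses a faint larva, a low
cutoff floods with static edge noise. `θ_b` is scene-dependent by nature —
that is the weakness FAST removes — and defaults to 0.2, which on the
synthetic scenes sits between the background darkness (0.15) and a dyed
blob (0.55).

## Tracking

Per frame, all (active-track head, detection) pairs with Euclidean
distance strictly below `link_max_px` (default 10 px ≈ 3 mm) are accepted
greedily in order of increasing distance, ties broken by lower track id
then lower detection index — deterministic, and equal to optimal
assignment on non-adversarial scenes (verified against an independent
oracle in the tests). Unmatched detections seed new tracks; unmatched
tracks terminate. There is no gap bridging and no identity resolution
through track crossings: two animals that touch may swap labels, and a
lost animal restarts as a new track. Completeness — the fraction of
ground-truth frames covered by the single best track within a 5 px
tolerance — is the scoring criterion for edge scenarios.

## Kinematics

Tracks are smoothed per axis with a discrete Gaussian kernel, truncated at
4σ and renormalized where it overhangs the track ends (no invented
padding). σ defaults to 1 frame — the smallest width that visibly removes
single-frame centroid jitter at 3.75 fps; the value is a package choice,
fully configurable. σ = 0 is the identity. Instantaneous speed uses
forward differences on the smoothed track (n−1 values; central differences
available), scaled to mm/s by `mm_per_px · fps`. Speed histograms are
pooled across tracks and normalized to unit mass.

With centroid jitter of sd 0.25 px and 0.3 mm/px, the default smoothing
displaces points by a Rayleigh-distributed amount with mode well under the
0.67 px (200 µm) mark, which is why ≈ 99% of per-point displacements fall
below 200 µm in the acceptance computation (100 straight tracks × 100
points).

## The synthetic generator

`render` draws, per frame: a uniform background (0.85), a static dish-edge
annulus at intensity 0.35 (default thickness 12 px ≈ 3.6 mm of wall +
meniscus), translucent moving discs, a global multiplicative flicker gain,
then iid Gaussian pixel noise (sd 0.01), clipped to [0,1]. Defaults are
640×480 at 3.75 fps, 0.3 mm/px; a given scene + seed renders
bit-identically.

**Blobs are translucent, not painted:** pixels behind a blob are scaled by
`1 − contrast/background`, so over the plain background the blob sits
exactly `contrast` below it (dyed 0.4, undyed 0.05), while over the darker
ring it darkens the ring proportionally. This is the transmitted-light
physics of an absorbing animal, and it produces the dye dependence the
pipeline is built around: an undyed blob's residual over the ring is
0.35·(0.05/0.85) ≈ 0.021 < θ, so even FAST loses it at the dish edge,
while a dyed blob's 0.35·(0.4/0.85) ≈ 0.165 stays far above threshold.

**Flicker** is a whole-field gain `1 + A·sin(2π(2f_mains + δ)·t/fps)` with
`A = 0.03`, `f_mains = 60 Hz`, detune `δ = 0.1 Hz`: the light output
oscillates at twice the mains frequency, and the small mismatch with the
camera clock aliases into a slow 0.1 Hz beat (37.5 frames per period at
3.75 fps). Per-pixel flicker (e.g. sensor PRNU) is not modeled.
`flicker_normalize` undoes it exactly for a multiplicative global gain:
each frame is scaled to the mean of the per-frame means. Note the
interaction of defaults: the flicker envelope on the background is
0.85·0.03 ≈ 0.0255, just below θ = 0.028 — with pixel noise on top, frames
near a beat minimum speckle heavily. The edge-crossing scenario therefore
defaults flicker **off** so it isolates the static-edge failure mode;
flicker robustness is exercised in dedicated scenes with normalization on.

**What the generator does not emulate** — and hence what passing tests do
not show about real movies: peristaltic shape change (blobs are rigid
discs; real centroids wobble with body bending), heterogeneous
backgrounds, shadows and reflections, animals touching or crossing,
larvae pausing for long stretches (which deepens the mean-frame ghost),
and camera vignetting. Centroid accuracy and the dyed/undyed contrast
regimes transfer; absolute speed distributions of real larvae do not.

## Numerical choices and degenerate inputs

- Thresholds are strict (`>`), so an exactly-uniform residual yields an
  empty mask; pruning bounds are inclusive.
- Subtraction clips negatives at 0; all intensities stay in [0,1].
- Saving quantizes to the 8-bit grid (round-trip error ≤ 1/255; exact for
  values already on the grid).
- Empty movies, mixed frame sizes, zero-mean frames (flicker
  normalization), inverted prune bounds, non-positive cutoffs and
  malformed track CSVs raise typed errors; CSV parse errors carry the
  1-based line number.
- A track shorter than 2 points has an empty speed series and zero
  duration.

## Problem sizes used in the checks

The test suite runs edge-crossing scenes at 320×240 × 60 frames and the
library demo at the full 640×480 when invoked manually; smoothing
statistics use 100 tracks × 100 points (10⁴ pooled displacements); the
labeling oracle comparison uses 100 random 32×32 masks per connectivity;
linking equivalence uses 30 random multi-frame scenes with ≤ 4 detections
per frame. These sizes are the package's own choice of a fast,
statistically stable regression suite; all scenario conclusions are
unchanged at full frame size.
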