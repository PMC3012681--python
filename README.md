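# fastrack

Tracking a crawling *Drosophila* larva in a fixed-camera movie is hard for
the oldest reason in image analysis: the animal is nearly translucent, so
any global binary threshold dark enough to catch it also catches every
static dark object in the dish — above all the high-contrast dish edge —
and any threshold clean enough to reject the edge loses the larva.

`fastrack` implements **FAST** (Frame Averaging followed by Subtraction
then Thresholding), which removes every static object before thresholding:

1. compute the mean frame `M = (1/N) Σ_t F_t` over the whole movie;
2. for each frame form the dark-object residual `R_t = max(M − F_t, 0)`
   (static content cancels; only pixels *darker than their own time
   average* — the moving animal — survive);
3. binarize `R_t > θ` with a single fixed, very low threshold
   (`θ = 0.028` on a [0, 1] intensity scale) that works across movies;
4. label connected components, prune clusters outside 2–100 px, and take
   unweighted centroids;
5. link centroids frame-to-frame, nearest pairs first, joining only when
   the jump is `< 10 px` (~3 mm at 0.3 mm/px, 3.75 fps); unmatched
   detections start new tracks, unmatched tracks end;
6. Gaussian-smooth each track (σ = 1 frame) and read off instantaneous
   speed `v_i = ‖p_{i+1} − p_i‖ · s · f` in mm/s (pixel pitch `s`,
   frame rate `f`).

The package also ships the plain-threshold baseline for comparison, a
flicker-normalization step for movies with a strong mains/camera beat, and
a **synthetic movie generator** with exact ground truth (dark blob over
light background, static dish-edge ring, dyed vs. undyed blob contrast,
AC-flicker beat, pixel noise), so every claim above is testable without
real video. See `docs/methods.md` for the model details and limitations.

## Worked example

Generate a dyed larva crossing the dish edge, track it, compare FAST with
the plain-threshold baseline, and extract speeds:

```sh
fastrack synth --scenario dyed-edge --out-dir demo_synth \
    --n-frames 60 --width 320 --height 240 --seed 42
fastrack track demo_synth/movie.tif --out-dir demo_out
fastrack compare demo_synth/movie.tif --truth demo_synth/truth.csv --out-dir demo_cmp
fastrack stats demo_out/tracks.csv --out-dir demo_stats
```

prints

```
dyed-edge: 60 frames -> demo_synth/movie.tif
96 tracks from 60 frames (mean duration 0.2 s) -> demo_out
fast: 155 objects / 96 tracks; fast completeness 1.00; baseline completeness 0.23
1 tracks, pooled mean speed 0.747 mm/s (59 steps) -> demo_stats/speed_histogram.csv
```

Reading those numbers: FAST recovers the blob's track in **every** frame
(completeness 1.00), including the frames where it overlaps the dish-edge
ring; the baseline covers only 23% of the ground-truth frames because the
blob merges with the ring and the merged cluster is pruned as oversized.
Of the 96 FAST tracks, one is the larva and the rest are one-or-two-point
speckle tracks from pixel noise near the low threshold — only the larval
track survives into the speed statistics (1 track with ≥ 2 smoothed
points), whose pooled mean of 0.747 mm/s recovers the 0.76 mm/s ground
truth within 2%. Every run writes the resolved configuration
(`config_used.txt`) next to its outputs, so it can be reproduced exactly.

The same functionality is available as a library:

```python
import fastrack as ft

scene = ft.edge_crossing_scene(contrast=0.4, n_frames=60, seed=42)
movie, truth = ft.render(scene)
cfg = ft.PipelineConfig()                       # θ=0.028, 2–100 px, <10 px
tracks = ft.link(ft.detect(movie, cfg, "fast"), cfg.link_max_px)
```

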