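import numpy as np
import pytest

import fastrack as ft


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def quiet_scene(contrast=0.4, n_frames=40, width=160, height=120, seed=7,
                speed_mm_s=0.76, noise_sd=0.002):
    """A low-noise, flicker-free scene with one straight-moving blob.

    Noise at sd 0.002 sits 14 sigma below the FAST threshold, so the only
    detectable object is the blob — used where a test needs exactly one
    clean track.
    """
    step = speed_mm_s / (ft.io_video.DEFAULT_FPS * ft.io_video.DEFAULT_MM_PER_PX)
    path = ft.straight_path(n_frames, (20.0, height / 2.0), step_px=step)
    return ft.SynthScene(
        width=width, height=height, n_frames=n_frames,
        blobs=[ft.BlobSpec(path=path, contrast=contrast)],
        flicker=None, noise_sd=noise_sd, seed=seed,
    )


@pytest.fixture(scope="session")
def dyed_edge_results():
    """Detection + linking for the dyed edge-crossing scene, both methods."""
    return _edge_results(contrast=0.4)


@pytest.fixture(scope="session")
def undyed_edge_results():
    """Detection + linking for the undyed edge-crossing scene, both methods."""
    return _edge_results(contrast=0.05)


def _edge_results(contrast):
    scene = ft.edge_crossing_scene(
        contrast=contrast, n_frames=60, width=320, height=240, seed=11
    )
    movie, truth = ft.render(scene)
    cfg = ft.PipelineConfig()
    out = {"scene": scene, "movie": movie, "truth": truth, "config": cfg}
    truth_pts = [(int(f), float(x), float(y)) for f, x, y in truth.paths[0]]
    out["truth_pts"] = truth_pts
    for method in ("fast", "baseline"):
        ts = ft.link(ft.detect(movie, cfg, method), cfg.link_max_px)
        out[method] = ts
        out[f"{method}_completeness"] = ft.track_completeness(ts, truth_pts)
    return out
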