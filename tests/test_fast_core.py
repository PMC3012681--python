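import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fastrack as ft
from fastrack.errors import (
    DegenerateFrameError,
    DimensionError,
    EmptyInputError,
    ParameterError,
)

from conftest import quiet_scene


def movie_of(frames, **kw):
    return ft.Movie(np.asarray(frames, dtype=float), **kw)


class TestAverageFrame:
    def test_mean_of_identical_frames_is_that_frame(self, rng):
        f = rng.random((6, 8))
        assert np.allclose(ft.average_frame(movie_of([f] * 5)), f)

    def test_mean_of_two_uniform_frames(self):
        m = movie_of([np.full((4, 4), 0.2), np.full((4, 4), 0.6)])
        assert np.allclose(ft.average_frame(m), 0.4)

    def test_matches_naive_accumulation_oracle(self, rng):
        frames = rng.random((50, 10, 12))
        acc = np.zeros((10, 12))
        for f in frames:  # independent per-pixel accumulation
            acc += f
        assert np.max(np.abs(ft.average_frame(movie_of(frames)) - acc / 50)) < 1e-9

    def test_empty_movie_raises(self):
        with pytest.raises(EmptyInputError):
            ft.average_frame(movie_of(np.zeros((0, 4, 4))))


class TestSubtract:
    def test_static_scene_nulls_out(self, rng):
        f = rng.random((5, 5))
        assert np.all(ft.subtract(f, f) == 0.0)

    def test_darker_pixel_gives_positive_residual(self):
        mean = np.full((3, 3), 0.5)
        frame = mean.copy()
        frame[1, 1] = 0.2
        res = ft.subtract(mean, frame)
        assert res[1, 1] == pytest.approx(0.3)
        assert np.all(np.delete(res.ravel(), 4) == 0.0)

    def test_brighter_pixels_clip_to_zero(self):
        assert np.all(ft.subtract(np.full((2, 2), 0.3), np.full((2, 2), 0.8)) == 0.0)

    def test_residual_support_is_the_dark_patch(self, rng):
        bg = rng.random((10, 10)) * 0.2 + 0.7
        frames = [bg.copy() for _ in range(20)]
        dark = bg.copy()
        dark[4:7, 4:7] -= 0.4  # one frame with a dark 3x3 patch
        frames.append(dark)
        mean = ft.average_frame(movie_of(frames))
        res = ft.subtract(mean, dark)
        patch = np.zeros((10, 10), bool)
        patch[4:7, 4:7] = True
        # residual concentrated in the patch; only ghost leakage elsewhere
        assert np.all(res[patch] > 0.3)
        assert np.all(res[~patch] < 0.4 / 21 + 1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            ft.subtract(np.zeros((3, 3)), np.zeros((4, 3)))


class TestThresholds:
    def test_zero_residual_gives_empty_mask(self):
        assert not ft.threshold_mask(np.zeros((4, 4)), 0.028).any()

    def test_single_hot_pixel(self):
        res = np.zeros((4, 4))
        res[2, 1] = 0.3
        mask = ft.threshold_mask(res, 0.028)
        assert mask.sum() == 1 and mask[2, 1]

    def test_mask_size_non_increasing_in_threshold(self, rng):
        res = rng.random((32, 32))
        counts = [ft.threshold_mask(res, t).sum() for t in np.linspace(0.01, 0.99, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_threshold_is_strict(self):
        res = np.full((2, 2), 0.25)
        assert not ft.threshold_mask(res, 0.25).any()

    def test_out_of_range_threshold_raises(self):
        with pytest.raises(ParameterError):
            ft.threshold_mask(np.zeros((2, 2)), 0.0)

    def test_baseline_all_white_is_empty(self):
        assert not ft.baseline_mask(np.ones((4, 4)), 0.5).any()

    def test_baseline_selects_dark_pixel(self):
        frame = np.ones((4, 4))
        frame[1, 3] = 0.0
        mask = ft.baseline_mask(frame, 0.09)
        assert mask.sum() == 1 and mask[1, 3]

    def test_baseline_detecting_blob_also_marks_ring(self):
        scene = quiet_scene(contrast=0.4, n_frames=5)
        scene.ring = ft.RingSpec(center=(80, 60), radius_px=40)
        movie, truth = ft.render(scene)
        mask = ft.baseline_mask(movie.frames[0], 0.2)
        x, y = truth.paths[0][0][1:]
        assert mask[int(y), int(x)]  # blob detected ...
        assert (mask & truth.static_pixels).sum() > 0  # ... and so is the ring


class TestFlickerNormalize:
    def test_flicker_free_movie_unchanged(self, rng):
        movie = movie_of(np.repeat(rng.random((1, 6, 6)) * 0.5 + 0.25, 4, axis=0))
        out = ft.flicker_normalize(movie)
        assert np.max(np.abs(out.frames - movie.frames)) < 1e-9

    def test_two_uniform_frames_meet_at_mean_of_means(self):
        out = ft.flicker_normalize(
            movie_of([np.full((3, 3), 0.4), np.full((3, 3), 0.6)])
        )
        assert np.allclose(out.frames, 0.5)

    def test_sinusoidal_gain_removed(self, rng):
        base = rng.random((8, 8)) * 0.3 + 0.4
        gains = 1 + 0.05 * np.sin(np.linspace(0, 7, 30))
        movie = movie_of([base * g for g in gains])
        out = ft.flicker_normalize(movie)
        means = out.frames.mean(axis=(1, 2))
        assert np.max(np.abs(means - means[0])) < 1e-9

    def test_zero_mean_frame_raises(self):
        with pytest.raises(DegenerateFrameError):
            ft.flicker_normalize(movie_of([np.full((3, 3), 0.5), np.zeros((3, 3))]))


def flood_fill_label(mask, connectivity):
    """Brute-force BFS labeling, independent of the library path."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, bool)
    components = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            queue, comp = [(sy, sx)], []
            seen[sy, sx] = True
            while queue:
                y, x = queue.pop()
                comp.append((y, x))
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            components.append(frozenset(comp))
    return components


class TestLabelClusters:
    def test_empty_mask_gives_no_clusters(self):
        assert ft.label_clusters(np.zeros((5, 5), bool)) == []

    def test_diagonal_pair_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(ft.label_clusters(mask, connectivity=8)) == 1
        assert len(ft.label_clusters(mask, connectivity=4)) == 2

    def test_rectangle_centroid_is_its_center(self):
        mask = np.zeros((10, 12), bool)
        mask[2:7, 3:9] = True  # rows 2..6, cols 3..8
        (c,) = ft.label_clusters(mask)
        assert c.pixel_count == 30
        assert c.centroid == pytest.approx((5.5, 4.0))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(100):
            mask = rng.random((32, 32)) < 0.3
            got = ft.label_clusters(mask, connectivity)
            expected = flood_fill_label(mask, connectivity)
            # identical partitions iff same number of components with the
            # same (size, centroid) multiset
            assert len(got) == len(expected)
            exp_stats = sorted(
                (len(c),
                 round(sum(x for _, x in c) / len(c), 9),
                 round(sum(y for y, _ in c) / len(c), 9))
                for c in expected
            )
            got_stats = sorted(
                (c.pixel_count, round(c.centroid[0], 9), round(c.centroid[1], 9))
                for c in got
            )
            assert got_stats == exp_stats


class TestPruneClusters:
    def _clusters(self, sizes):
        return [ft.Cluster(i + 1, s, (0.0, 0.0)) for i, s in enumerate(sizes)]

    def test_bounds_are_inclusive(self):
        kept = ft.prune_clusters(self._clusters([1, 2, 100, 101]), 2, 100)
        assert sorted(c.pixel_count for c in kept) == [2, 100]

    def test_empty_input(self):
        assert ft.prune_clusters([], 2, 100) == []

    def test_wide_bounds_are_identity(self):
        cs = self._clusters([1, 7, 300])
        assert ft.prune_clusters(cs, 1, 10**9) == cs

    def test_inverted_bounds_raise(self):
        with pytest.raises(ParameterError):
            ft.prune_clusters([], 5, 2)

    @settings(derandomize=True, max_examples=60)
    @given(
        sizes=st.lists(st.integers(1, 300), max_size=25),
        lo=st.integers(1, 50),
        span=st.integers(0, 250),
    )
    def test_pruning_keeps_exactly_the_inclusive_range(self, sizes, lo, span):
        hi = lo + span
        kept = ft.prune_clusters(self._clusters(sizes), lo, hi)
        assert [c.pixel_count for c in kept] == [s for s in sizes if lo <= s <= hi]

    @settings(derandomize=True, max_examples=60)
    @given(
        values=st.lists(
            st.floats(0.0, 1.0, allow_nan=False, width=32), min_size=1, max_size=64
        ),
        t1=st.floats(0.001, 0.999, allow_nan=False),
        t2=st.floats(0.001, 0.999, allow_nan=False),
    )
    def test_mask_counts_monotone_for_any_threshold_pair(self, values, t1, t2):
        residual = np.array(values, dtype=np.float64)
        lo, hi = sorted((t1, t2))
        assert ft.threshold_mask(residual, hi).sum() <= ft.threshold_mask(
            residual, lo
        ).sum()


class TestDetect:
    def test_static_movie_yields_no_fast_detections(self, rng):
        frame = rng.random((20, 20)) * 0.3 + 0.5
        movie = movie_of(np.repeat(frame[None], 10, axis=0))
        dets = ft.detect(movie, ft.PipelineConfig(), "fast")
        assert all(len(d) == 0 for d in dets)

    def test_dyed_blob_detected_near_truth_in_every_frame(self):
        movie, truth = ft.render(quiet_scene(contrast=0.4))
        dets = ft.detect(movie, ft.PipelineConfig(), "fast")
        hits = 0
        for (f, tx, ty), frame_dets in zip(truth.paths[0], dets):
            assert len(frame_dets) >= 1
            d = min(
                np.hypot(c.centroid[0] - tx, c.centroid[1] - ty)
                for c in frame_dets
            )
            hits += d <= 2.0
        assert hits / movie.n_frames >= 0.95

    def test_baseline_keeps_static_ring_clusters(self):
        scene = quiet_scene(contrast=0.4, n_frames=6)
        scene.ring = ft.RingSpec(center=(80, 60), radius_px=40)
        movie, truth = ft.render(scene)
        # bounds wide enough that the large ring component is not pruned
        cfg = ft.PipelineConfig(max_cluster_px=10**6)
        for frame_dets in ft.detect(movie, cfg, "baseline"):
            assert any(c.pixel_count > 100 for c in frame_dets)

    def test_flicker_invariance_with_normalization(self):
        scene = quiet_scene(contrast=0.4, n_frames=30, noise_sd=0.0)
        plain, _ = ft.render(scene)
        scene.flicker = ft.FlickerSpec()
        flickery, _ = ft.render(scene)
        cfg = ft.PipelineConfig(flicker_normalize=True)
        dets_plain = ft.detect(plain, cfg, "fast")
        dets_flick = ft.detect(flickery, cfg, "fast")
        for dp, df in zip(dets_plain, dets_flick):
            assert len(dp) == len(df) == 1
            assert np.hypot(
                dp[0].centroid[0] - df[0].centroid[0],
                dp[0].centroid[1] - df[0].centroid[1],
            ) <= 0.5

    def test_unknown_method_raises(self):
        with pytest.raises(ParameterError):
            ft.detect(movie_of(np.zeros((1, 4, 4))), ft.PipelineConfig(), "magic")


class TestPipelineConfig:
    def test_defaults_match_published_constants(self):
        cfg = ft.PipelineConfig()
        assert cfg.fast_threshold == 0.028
        assert (cfg.min_cluster_px, cfg.max_cluster_px) == (2, 100)
        assert cfg.link_max_px == 10.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fast_threshold": 0.0},
            {"fast_threshold": 1.0},
            {"min_cluster_px": 0},
            {"min_cluster_px": 50, "max_cluster_px": 10},
            {"link_max_px": -1.0},
            {"connectivity": 6},
            {"smoothing_sigma_frames": -0.5},
        ],
    )
    def test_invalid_values_raise(self, kwargs):
        with pytest.raises(ParameterError):
            ft.PipelineConfig(**kwargs)

    def test_file_roundtrip(self, tmp_path):
        cfg = ft.PipelineConfig(fast_threshold=0.05, connectivity=4,
                                flicker_normalize=True)
        cfg.to_file(tmp_path / "cfg.txt")
        assert ft.PipelineConfig.from_file(tmp_path / "cfg.txt") == cfg

    def test_unknown_key_raises(self, tmp_path):
        (tmp_path / "cfg.txt").write_text("not_a_key=1\n")
        with pytest.raises(ParameterError):
            ft.PipelineConfig.from_file(tmp_path / "cfg.txt")
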