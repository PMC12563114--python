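"""Histogram, kneedle elbow, thresholding, and mask-pruning behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polaroi import cleaner, synth
from polaroi.cleaner import (
    binarize,
    clean,
    compute_threshold,
    find_mode,
    intensity_histogram,
    kneedle,
    prune_noise,
)
from polaroi.errors import DegenerateHistogramError, EmptyImageError, EmptyMaskError

from conftest import jaccard


class TestHistogram:
    def test_zero_pixels_excluded(self):
        frame = np.array([[0, 0, 5], [5, 5, 0]], dtype=np.uint8)
        hist = intensity_histogram(frame)
        assert hist.counts.sum() == 3
        assert hist.counts[hist.bin_centers == 5] == 3

    def test_single_bin_holds_all_nonzero(self):
        frame = np.array([[0.0, 3.5, 7.0, 9.9]])
        hist = intensity_histogram(frame, n_bins=1)
        assert len(hist.counts) == 1 and hist.counts[0] == 3

    def test_all_zero_frame_rejected(self):
        with pytest.raises(EmptyImageError):
            intensity_histogram(np.zeros((4, 4)))

    def test_integer_images_get_unit_bins(self):
        frame = np.array([[1, 3, 3, 7]], dtype=np.int32)
        hist = intensity_histogram(frame)
        assert np.array_equal(hist.bin_centers, np.arange(1, 8))
        assert hist.counts.sum() == 4

    def test_counts_sum_equals_nonzero_pixels_float(self):
        rng = np.random.default_rng(0)
        frame = rng.random((32, 32)) * 50
        hist = intensity_histogram(frame)
        assert hist.counts.sum() == (frame > 0).sum()


class TestFindMode:
    def test_maximal_count_wins(self):
        hist = cleaner.Histogram(np.array([10.0, 20.0, 30.0]), np.array([1, 9, 3]))
        assert find_mode(hist) == 20.0

    def test_ties_break_toward_low_intensity(self):
        hist = cleaner.Histogram(np.array([10.0, 20.0]), np.array([5, 5]))
        assert find_mode(hist) == 10.0


class TestKneedle:
    def test_piecewise_linear_knee(self):
        # brute-force max of the normalized difference curve lies at x=1
        xs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        ys = np.array([10.0, 1.0, 0.9, 0.8, 0.7])
        elbow = kneedle(xs, ys)
        assert elbow.x == 1.0 and elbow.y == 1.0

    def test_straight_line_returns_first_point(self):
        # the difference curve is identically zero; the first index wins
        xs = np.arange(5.0)
        ys = 10.0 - 2.0 * xs
        assert kneedle(xs, ys).x == xs[0]

    def test_agrees_with_chord_distance_oracle(self):
        # for a convex decreasing curve the normalized difference is a scaled
        # perpendicular distance from the endpoint chord, so argmaxes agree
        xs = np.arange(1.0, 10.0)
        ys = 1.0 / xs
        x_n = (xs - xs[0]) / (xs[-1] - xs[0])
        y_n = (ys - ys.min()) / (ys.max() - ys.min())
        chord_dist = np.abs(x_n + y_n - 1.0) / np.sqrt(2.0)
        assert kneedle(xs, ys).x == xs[np.argmax(chord_dist)]

    @pytest.mark.parametrize(
        "xs, ys",
        [
            ([0.0, 1.0], [1.0, 0.0]),
            ([0.0, 1.0, 1.0], [3.0, 2.0, 1.0]),
            ([2.0, 1.0, 3.0], [3.0, 2.0, 1.0]),
        ],
    )
    def test_invalid_curves_rejected(self, xs, ys):
        with pytest.raises(ValueError):
            kneedle(np.asarray(xs), np.asarray(ys))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=3, max_value=100),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_bruteforce_on_random_convex_curves(self, n, seed):
        rng = np.random.default_rng(seed)
        xs = np.cumsum(rng.uniform(0.1, 1.0, size=n))
        slopes = -np.sort(rng.uniform(0.05, 3.0, size=n - 1))[::-1]  # increasing
        ys = np.concatenate([[0.0], np.cumsum(slopes * np.diff(xs))]) + 10.0
        elbow = kneedle(xs, ys)
        # independent, loop-based normalized-difference maximization
        best_i, best_d = 0, -np.inf
        for i in range(n):
            xn = (xs[i] - xs[0]) / (xs[-1] - xs[0])
            yn = (ys[i] - ys.min()) / (ys.max() - ys.min())
            d = (1 - yn) - xn
            if d > best_d:
                best_i, best_d = i, d
        assert elbow.x == xs[best_i]


class TestThreshold:
    def test_separates_two_valued_image(self):
        rng = np.random.default_rng(1)
        values = np.where(rng.random(4096) < 0.95, 20, 80).astype(np.int32)
        values[:10] = 50  # one intermediate bin
        frame = values.reshape(64, 64)
        thr = compute_threshold(frame)
        assert 20 < thr <= 80

    def test_two_gaussian_misclassification_below_one_percent(self):
        img, truth = synth.two_gaussian_image(seed=11)
        thr = compute_threshold(img)
        assert (binarize(img, thr) != truth).mean() <= 0.01
        # threshold sits in the no-man's-land between the populations
        assert 20 + 2.33 * 2 < thr < 80 - 2.33 * 5

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            compute_threshold(np.full((8, 8), 7, dtype=np.uint8))

    def test_scale_invariance_up_to_binning(self):
        img, _ = synth.two_gaussian_image(seed=3)
        thr = compute_threshold(img)
        a, b = 3.0, 10.0
        scaled = np.where(img > 0, a * img + b, 0.0)
        thr2 = compute_threshold(scaled)
        bin_width = scaled.max() / 256
        assert abs(thr2 - (a * thr + b)) <= 3 * bin_width


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        frame = np.array([[1.0, 5.0, 9.0]])
        assert binarize(frame, 5.0).tolist() == [[0, 0, 1]]

    def test_extreme_thresholds(self):
        frame = np.array([[1.0, 5.0, 9.0]])
        assert binarize(frame, 0.5).all()
        assert not binarize(frame, 9.0).any()


class TestPrune:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        assert prune_noise(mask).sum() == 0

    def test_domino_removed(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2:4] = 1
        assert prune_noise(mask).sum() == 0

    def test_solid_block_preserved(self):
        # every pixel of a 3x3 block has >= 3 foreground neighbors
        # (corners have exactly 3), so the block is a fixed point
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        assert np.array_equal(prune_noise(mask), mask)

    def test_exhaustive_center_rule(self):
        # all 512 center+neighborhood configurations against the >=3-of-8 rule
        for config in range(512):
            bits = [(config >> k) & 1 for k in range(9)]
            mask = np.array(bits, dtype=np.uint8).reshape(3, 3)
            out = prune_noise(mask)
            expected = mask[1, 1] == 1 and (mask.sum() - mask[1, 1]) >= 3
            assert out[1, 1] == int(expected)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_never_adds_pixels_and_reaches_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((12, 12)) < 0.4).astype(np.uint8)
        current = mask
        for _ in range(mask.size):
            nxt = prune_noise(current)
            assert set(np.unique(nxt)) <= {0, 1}
            assert nxt.sum() <= current.sum()
            assert not (nxt & ~current).any()
            if np.array_equal(nxt, current):
                break
            current = nxt
        assert np.array_equal(prune_noise(current), current)


class TestClean:
    def test_recovers_cell_despite_salt_noise(self, quiet_cell_frame):
        stack, truth = quiet_cell_frame
        frame = stack.frames[0].copy()
        rng = np.random.default_rng(2)
        salt = rng.random(frame.shape) < 0.01
        frame[salt] = 90.0
        mask = clean(frame, max_iterations=2).mask
        cell = (truth.soma_mask | truth.process_mask).astype(bool)
        assert jaccard(mask, cell) >= 0.9

    def test_zero_iterations_is_raw_binarization(self, quiet_cell_frame):
        stack, _ = quiet_cell_frame
        frame = stack.frames[0]
        result = clean(frame, max_iterations=0)
        assert np.array_equal(result.mask, binarize(frame, result.threshold))

    def test_idempotent_once_converged(self, quiet_cell_frame):
        stack, _ = quiet_cell_frame
        frame = stack.frames[0]
        first = clean(frame, max_iterations=50).mask
        again = clean(frame, max_iterations=50).mask
        assert np.array_equal(first, again)
        assert np.array_equal(prune_noise(first), first)

    def test_interactive_prompt_loop(self, quiet_cell_frame):
        stack, _ = quiet_cell_frame
        answers = iter(["y", "n"])
        shown = []
        result = clean(
            stack.frames[0],
            interactive=True,
            prompt=lambda msg: next(answers),
            display=shown.append,
        )
        assert len(result.removed_per_pass) == 1
        assert len(shown) == 2

    def test_manual_threshold_respected(self):
        frame = np.array([[1.0, 10.0, 10.0], [10.0, 10.0, 1.0]])
        result = clean(frame, max_iterations=0, manual_threshold=5.0)
        assert result.threshold == 5.0
        assert result.mask.sum() == 4

    def test_total_erasure_is_an_error(self):
        frame = np.ones((9, 9))
        frame[2, 2] = frame[6, 6] = 100.0  # isolated bright pixels only
        with pytest.raises(EmptyMaskError):
            clean(frame, max_iterations=2, manual_threshold=50.0)
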