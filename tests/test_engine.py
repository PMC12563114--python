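"""Per-frame driver: measurement, motion detection, relocation, determinism."""

import itertools

import numpy as np
import pytest

from polaroi import engine, orient, synth, tiffio
from polaroi.engine import RunConfig, measure_frame, motion_check, run, signed_rank_test
from polaroi.errors import LayoutError


class TestMeasure:
    def test_constant_frame_means(self, deiters_layout):
        shape = deiters_layout.rotated_shape
        process, somas, background = measure_frame(np.full(shape, 7.0), deiters_layout)
        assert process == 7.0 and background == 7.0
        assert all(s == 7.0 for s in somas)

    def test_single_hot_roi(self, deiters_layout):
        shape = deiters_layout.rotated_shape
        frame = np.zeros(shape)
        roi = deiters_layout.process_roi
        frame[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width] = 10.0
        process, somas, background = measure_frame(frame, deiters_layout)
        assert process == 10.0 and background == 0.0 and all(s == 0.0 for s in somas)

    def test_roi_outside_frame_is_an_error(self, deiters_layout):
        small = np.zeros((10, 10))
        with pytest.raises(LayoutError):
            measure_frame(small, deiters_layout)

    def test_synthetic_means_match_truth(self, deiters_movie, deiters_layout):
        stack, truth = deiters_movie
        rotated = orient.rotate_frame(
            stack.frames[0], deiters_layout.orientation.angle_deg
        )
        process, _, background = measure_frame(rotated, deiters_layout)
        n = deiters_layout.process_roi.height * deiters_layout.process_roi.width
        se = truth.spec.noise_sd / np.sqrt(n)
        # interpolation mixes a little background into edge pixels, so allow
        # a small systematic undershoot on top of the noise SE
        assert process == pytest.approx(truth.process_mean[0], abs=0.05 * truth.process_mean[0] + 2 * se)
        assert background == pytest.approx(truth.spec.background_level, abs=5 * se)


class TestSignedRank:
    def test_matches_full_enumeration(self):
        # exact branch against brute force over all 2^n sign assignments
        rng = np.random.default_rng(7)
        for n in (4, 6, 8, 10):
            d = rng.normal(0.3, 1.0, n)
            stat, p = signed_rank_test(d)
            ranks = np.argsort(np.argsort(np.abs(d))) + 1
            w_obs = ranks[d > 0].sum()
            ws = np.array(
                [
                    sum(r for r, s in zip(ranks, signs) if s)
                    for signs in itertools.product([0, 1], repeat=n)
                ]
            )
            expected = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
            assert stat == min(w_obs, ranks.sum() - w_obs)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_all_zero_differences_are_degenerate(self):
        assert signed_rank_test(np.zeros(10)) == (0.0, 1.0)


class TestMotionCheck:
    def test_maximal_separation_is_not_drift(self, deiters_layout):
        frame = np.full(deiters_layout.rotated_shape, 10.0)
        for roi in deiters_layout.cell_rois():
            frame[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width] = 100.0
        assert motion_check(frame, deiters_layout, alpha=0.001) is False

    def test_cell_identical_to_background_is_drift(self, deiters_layout):
        frame = np.full(deiters_layout.rotated_shape, 10.0)
        assert motion_check(frame, deiters_layout, alpha=0.05) is True

    def test_null_detection_rate_matches_level(self):
        # cell ROIs sampling the background distribution: the test should
        # declare drift (p >= alpha) in about 1 - alpha of frames
        rng = np.random.default_rng(42)
        hits = 0
        n_trials = 1000
        for _ in range(n_trials):
            diffs = rng.normal(0.0, 3.0, 120) - rng.normal(0.0, 3.0, 120)
            _, p = signed_rank_test(diffs)
            hits += p >= 0.05
        assert hits / n_trials >= 0.94


class TestRun:
    def test_single_frame_stack(self, quiet_cell_frame):
        stack, _ = quiet_cell_frame
        result = run(stack, RunConfig())
        assert len(result.table) == 1
        assert not bool(result.table.relocated.iloc[0])

    def test_no_drift_run_builds_layout_once(self, deiters_run, deiters_movie):
        stack, _ = deiters_movie
        table = deiters_run.table
        assert len(table) == stack.n_frames
        assert not table.relocated.any()
        layout_events = [e for e in deiters_run.events if e["event"] == "layout"]
        assert len(layout_events) == 1
        assert len(deiters_run.layouts) == 1

    def test_times_come_from_metadata(self, deiters_run, deiters_movie):
        stack, _ = deiters_movie
        assert np.array_equal(deiters_run.table.time_s.to_numpy(), stack.times_s)

    def test_relocated_only_on_check_cadence(self, drift_movie):
        stack, _ = drift_movie
        result = run(stack, RunConfig(alpha=0.05, check_every=5))
        flagged = result.table.index[result.table.relocated].tolist()
        assert flagged and all(f % 5 == 0 for f in flagged)

    def test_deterministic_tables(self, deiters_movie, tmp_path):
        stack, _ = deiters_movie
        paths = []
        for i in range(2):
            result = run(stack, RunConfig())
            p = tmp_path / f"run{i}.csv"
            tiffio.write_results(result.table, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestRelocation:
    def test_step_drift_triggers_prompt_relocation(self, drift_movie):
        stack, _ = drift_movie
        result = run(stack, RunConfig(alpha=0.05, check_every=5))
        frames = [e["frame"] for e in result.events if e["event"] == "relocation"]
        assert frames and frames[0] in (20, 25)
        # size and shape preserved across relocation
        dims = {lay.template_dims for lay in result.layouts}
        assert len(dims) == 1

    def test_relocation_restores_baseline(self, drift_movie):
        stack, _ = drift_movie
        result = run(stack, RunConfig(alpha=0.05, check_every=5))
        table = result.table
        pre = table.roi_process.iloc[5:20].mean()
        post = table.roi_process.iloc[26:].mean()
        assert abs(post - pre) / pre <= 0.10
        # the frozen (uncorrected) layout keeps sampling background instead
        frozen_layout = result.layouts[0]
        frozen = []
        for idx in range(25, stack.n_frames):
            rotated = orient.rotate_frame(
                stack.frames[idx], frozen_layout.orientation.angle_deg
            )
            p, _, _ = measure_frame(rotated, frozen_layout)
            frozen.append(p)
        assert (pre - np.mean(frozen)) / pre > 0.5

    def test_relocation_counts_weakly_increase_with_alpha(self, drift_movie):
        stack, _ = drift_movie
        counts = {}
        for alpha in (0.001, 0.05):
            result = run(stack, RunConfig(alpha=alpha, check_every=5))
            counts[alpha] = int(result.table.relocated.sum())
        assert counts[0.001] <= counts[0.05]

    def test_failed_relocation_keeps_stale_layout(self, drift_movie, monkeypatch):
        stack, _ = drift_movie
        from polaroi import roimaker

        original = roimaker.build_layout
        calls = {"n": 0}

        def flaky(frame, **kwargs):
            calls["n"] += 1
            if kwargs.get("template_dims") is not None:
                raise LayoutError("cell lost")
            return original(frame, **kwargs)

        monkeypatch.setattr(engine.roimaker, "build_layout", flaky)
        result = run(stack, RunConfig(alpha=0.05, check_every=5))
        assert len(result.table) == stack.n_frames
        assert not result.table.relocated.any()
        assert any(e["event"] == "relocation_failed" for e in result.events)


class TestRunConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(alpha=1.5)
        with pytest.raises(ValueError):
            RunConfig(check_every=0)
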