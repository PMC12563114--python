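"""Per-frame driver: rotate, measure, detect drift, relocate, tabulate.

Almost everything expensive happens once, on the first frame: segmentation,
orientation and ROI placement. Every frame is then rotated by the saved angle
and the mean intensity inside each rectangle is recorded. On every k-th frame
(default every 5th) a Wilcoxon signed-rank test compares the pixels of the
cell ROIs — paired positionally with the background ROI's pixels — against
the background. While the cell sits under its ROIs this difference is wildly
significant; when the preparation drifts, the ROIs end up sampling
background, significance is LOST, and the loss (p >= alpha) is the trigger to
re-detect the cell and re-place the ROIs with unchanged size and shape. Note
the inverted idiom: non-significance means drift.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import orient, roimaker
from .errors import LayoutError, PolaroiError
from .roimaker import RoiLayout
from .tiffio import ImageStack

logger = logging.getLogger(__name__)

#: sample-size cutoff between the exact signed-rank null and the normal
#: approximation with continuity correction
EXACT_MAX_N = 25


@dataclass
class RunConfig:
    """User-facing knobs of an analysis run.

    alpha is the significance level of the motion check (Fig-5-style runs in
    the source experiments used 0.05 and 0.001); check_every its cadence in
    frames. Smaller alpha relocates less eagerly.
    """

    alpha: float = 0.05
    check_every: int = 5
    max_clean_iterations: int = 2
    interactive: bool = False
    n_bins: int | None = None
    manual_threshold: float | None = None
    manual_angle_deg: float | None = None
    smoothing_window: int = 5
    min_peak_separation: int = 10
    seed: int | None = None  # synth only; the analysis path has no randomness

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")

    def layout_kwargs(self) -> dict:
        return dict(
            max_clean_iterations=self.max_clean_iterations,
            n_bins=self.n_bins,
            manual_threshold=self.manual_threshold,
            manual_angle_deg=self.manual_angle_deg,
            smoothing_window=self.smoothing_window,
            min_peak_separation=self.min_peak_separation,
            interactive=self.interactive,
        )


# ---------------------------------------------------------------------------
# measurement and motion check


def measure_frame(
    frame: np.ndarray, layout: RoiLayout
) -> tuple[float, list[float], float]:
    """Arithmetic mean of raw intensities inside each ROI of a rotated frame."""
    for roi in layout.all_rois():
        if not roi.within(frame.shape):
            raise LayoutError(f"{roi.role} ROI outside the rotated frame")
    process = float(layout.process_roi.pixels(frame).mean())
    somas = [float(r.pixels(frame).mean()) for r in layout.soma_rois]
    background = float(layout.background_roi.pixels(frame).mean())
    return process, somas, background


def signed_rank_test(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired differences.

    Zero differences are dropped. With n <= 25 the exact null distribution is
    used; beyond that, the normal approximation with continuity correction.
    All-zero differences are fully degenerate (the paired samples are
    identical) and reported as (0, p=1).
    """
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= EXACT_MAX_N else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def motion_check(
    frame: np.ndarray,
    layout: RoiLayout,
    alpha: float,
    return_detail: bool = False,
):
    """Has the cell drifted out of its ROIs? (drifted = p >= alpha.)

    The pixels of every cell ROI (process + each soma) are paired
    positionally with the background ROI's pixels — all ROIs share one shape,
    which is what makes the pairing well defined — and the pooled pairwise
    differences go into a single two-sided signed-rank test: one decision per
    checked frame. Per-ROI p-values are computed alongside for diagnostics.
    """
    bg = layout.background_roi.pixels(frame).ravel()
    pooled = []
    per_roi_p = {}
    for roi in layout.cell_rois():
        diffs = roi.pixels(frame).ravel() - bg
        pooled.append(diffs)
        _, p_roi = signed_rank_test(diffs)
        per_roi_p[f"{roi.role}_{roi.order}" if roi.role == "soma" else roi.role] = p_roi
    _, p = signed_rank_test(np.concatenate(pooled))
    drifted = bool(p >= alpha)
    if return_detail:
        return drifted, p, per_roi_p
    return drifted


def relocate(
    frame: np.ndarray,
    old_layout: RoiLayout,
    config: RunConfig,
    frame_index: int,
) -> RoiLayout | None:
    """Re-detect the cell on the current (raw) frame, keeping the ROI shape.

    Re-runs cleaning, orientation, process location and tiling, but forces
    the template (height, width) from the old layout so size and shape stay
    as previously defined. Returns None when re-segmentation fails (cell
    lost); the caller keeps the stale layout and continues — partial data
    beats none on a long recording.
    """
    try:
        return roimaker.build_layout(
            frame,
            template_dims=old_layout.template_dims,
            valid_from_frame=frame_index,
            **config.layout_kwargs(),
        )
    except PolaroiError as exc:
        logger.warning("relocation failed at frame %d: %s", frame_index, exc)
        return None


# ---------------------------------------------------------------------------
# the run loop


@dataclass
class RunResult:
    """Trace table plus the layout history and the structured event log."""

    table: pd.DataFrame
    layouts: list[RoiLayout]
    events: list[dict] = field(default_factory=list)

    @property
    def layout(self) -> RoiLayout:
        return self.layouts[-1]

    def run_log(self, config: RunConfig | None = None) -> dict:
        log = {
            "events": self.events,
            "layouts": [lay.to_dict() for lay in self.layouts],
        }
        if config is not None:
            log["config"] = asdict(config)
        return log


def run(stack: ImageStack, config: RunConfig | None = None) -> RunResult:
    """Analyze a stack: one row of ROI means per frame.

    Frame 0 defines the layout. Every frame is rotated by the saved angle and
    measured. On frames where ``index % check_every == 0`` (index > 0) the
    motion check runs first; on drift the ROIs are relocated (same template)
    before measuring, and the row's ``relocated`` flag is set. The analysis
    path is fully deterministic: identical stack + config give a bit-identical
    table.
    """
    config = config or RunConfig()
    layout = roimaker.build_layout(stack.frames[0], **config.layout_kwargs())
    events: list[dict] = [
        {"stage": "roimaker", "frame": 0, "event": "layout",
         "angle_deg": layout.orientation.angle_deg, "threshold": layout.threshold,
         "n_soma_rois": len(layout.soma_rois)}
    ]
    layouts = [layout]
    times = stack.frame_times()
    rows: list[dict] = []
    max_soma = len(layout.soma_rois)
    for idx in range(stack.n_frames):
        frame = stack.frames[idx]
        rotated = orient.rotate_frame(frame, layout.orientation.angle_deg)
        relocated = False
        if idx > 0 and idx % config.check_every == 0:
            drifted, p, per_roi = motion_check(
                rotated, layout, config.alpha, return_detail=True
            )
            events.append(
                {"stage": "engine", "frame": idx, "event": "motion_check",
                 "p": p, "drifted": drifted, "per_roi_p": per_roi}
            )
            if drifted:
                new_layout = relocate(frame, layout, config, idx)
                if new_layout is not None:
                    layout = new_layout
                    layouts.append(layout)
                    relocated = True
                    rotated = orient.rotate_frame(frame, layout.orientation.angle_deg)
                    max_soma = max(max_soma, len(layout.soma_rois))
                    events.append(
                        {"stage": "engine", "frame": idx, "event": "relocation",
                         "angle_deg": layout.orientation.angle_deg,
                         "n_soma_rois": len(layout.soma_rois)}
                    )
                else:
                    events.append(
                        {"stage": "engine", "frame": idx,
                         "event": "relocation_failed"}
                    )
        process, somas, background = measure_frame(rotated, layout)
        row = {"frame": idx, "time_s": float(times[idx]), "roi_process": process}
        for i, value in enumerate(somas, start=1):
            row[f"roi_soma_{i}"] = value
        row["roi_background"] = background
        row["relocated"] = relocated
        rows.append(row)
    columns = (
        ["frame", "time_s", "roi_process"]
        + [f"roi_soma_{i}" for i in range(1, max_soma + 1)]
        + ["roi_background", "relocated"]
    )
    table = pd.DataFrame(rows, columns=columns)
    return RunResult(table=table, layouts=layouts, events=events)
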