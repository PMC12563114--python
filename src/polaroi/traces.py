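"""Trace post-processing: background correction, dF/F0, transient statistics.

The per-ROI mean traces from the engine are background-corrected by
subtracting the background ROI's trace frame by frame, normalized as
``dF/F0 = (F_t - F0) / F0`` with ``F0`` the mean over a baseline window, and
summarized per transient by the maximal amplitude and the response width —
the time between the 50%-of-maximum crossings on the rising and falling
phases, linearly interpolated between samples. Non-uniform sampling is
supported throughout (recordings often run fast during responses and slow in
between).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Transient:
    """Summary of one evoked response on a dF/F0 trace."""

    amplitude: float  # max dF/F0, dimensionless
    t_peak_s: float
    width_s: float | None  # None when the trace never recrosses half-max
    rise_cross_s: float | None = None
    fall_cross_s: float | None = None

    @property
    def width_missing(self) -> bool:
        return self.width_s is None


def background_correct(cell_trace: np.ndarray, bg_trace: np.ndarray) -> np.ndarray:
    """Pointwise ``F_cell(t) - F_bg(t)``."""
    cell = np.asarray(cell_trace, dtype=np.float64)
    bg = np.asarray(bg_trace, dtype=np.float64)
    if cell.shape != bg.shape:
        raise ValueError("cell and background traces differ in length")
    return cell - bg


def dff0(
    trace: np.ndarray, baseline_window: tuple[int, int] | None = None
) -> np.ndarray:
    """Relative fluorescence change ``(F_t - F0) / F0``.

    ``baseline_window`` is a half-open frame-index range ``(start, stop)``
    over which ``F0`` is averaged; by default the first 10% of frames (at
    least one) — a stand-in for the pre-stimulus baseline period when no
    stimulus marker is available.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if baseline_window is None:
        baseline_window = (0, max(1, trace.size // 10))
    start, stop = baseline_window
    window = trace[start:stop]
    if window.size == 0:
        raise ValueError("baseline window is empty")
    f0 = float(window.mean())
    if f0 == 0.0:
        raise ZeroDivisionError("zero baseline; check background correction")
    return (trace - f0) / f0


def _cross_time(t0, y0, t1, y1, level) -> float:
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return float(t0)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def transient_stats(
    dff: np.ndarray,
    times_s: np.ndarray | None = None,
    smooth_window: int = 1,
) -> Transient:
    """Amplitude and 50%-width of the dominant transient.

    The amplitude is the raw trace maximum (an optional moving-average
    pre-smoother, off by default, is available for noisy traces — it affects
    only peak localisation and crossings, not the philosophy). The rising
    crossing interpolates linearly between the last sample below half-max
    before the peak and the next sample at or above it; the falling crossing
    mirrors this after the peak. If either phase never crosses half-max
    (e.g. a plateau that never decays), the width is reported missing while
    the amplitude stands.
    """
    y = np.asarray(dff, dtype=np.float64)
    if times_s is None:
        t = np.arange(y.size, dtype=np.float64)
    else:
        t = np.asarray(times_s, dtype=np.float64)
        if t.shape != y.shape:
            raise ValueError("times and trace differ in length")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    if y.size == 0 or y.max() <= 0:
        raise ValueError("trace has no strictly positive maximum")
    peak = int(np.argmax(y))
    amplitude = float(y[peak])
    half = amplitude / 2.0
    rise = None
    for i in range(peak - 1, -1, -1):
        if y[i] < half:
            rise = _cross_time(t[i], y[i], t[i + 1], y[i + 1], half)
            break
    fall = None
    for i in range(peak + 1, y.size):
        if y[i] < half:
            fall = _cross_time(t[i - 1], y[i - 1], t[i], y[i], half)
            break
    width = None if (rise is None or fall is None) else float(fall - rise)
    return Transient(
        amplitude=amplitude,
        t_peak_s=float(t[peak]),
        width_s=width,
        rise_cross_s=rise,
        fall_cross_s=fall,
    )


def transients_from_table(
    table: pd.DataFrame,
    baseline_window: tuple[int, int] | None = None,
    smooth_window: int = 1,
) -> pd.DataFrame:
    """Per-ROI transient summary from an engine results table.

    Each cell-ROI column is background-corrected with the ``roi_background``
    column, normalized to dF/F0 over the baseline window, and summarized.
    Output columns: roi, amplitude, width_s, t_peak_s, width_missing.
    """
    bg = table["roi_background"].to_numpy()
    times = table["time_s"].to_numpy()
    records = []
    roi_cols = ["roi_process"] + [
        c for c in table.columns if c.startswith("roi_soma_")
    ]
    for col in roi_cols:
        corrected = background_correct(table[col].to_numpy(), bg)
        norm = dff0(corrected, baseline_window)
        tr = transient_stats(norm, times, smooth_window=smooth_window)
        records.append(
            {
                "roi": col.removeprefix("roi_"),
                "amplitude": tr.amplitude,
                "width_s": np.nan if tr.width_s is None else tr.width_s,
                "t_peak_s": tr.t_peak_s,
                "width_missing": tr.width_missing,
            }
        )
    return pd.DataFrame.from_records(records)
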