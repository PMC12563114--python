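"""Reading and writing of image stacks, results tables and ROI overlays.

The pipeline's input is a grayscale multipage TIFF, one page per time point,
holding exactly one labeled cell. Per-page acquisition times are picked up
from metadata when present; otherwise downstream code falls back to the frame
index as the time axis.

Coordinate convention (used throughout the package): 0-based, row-major,
origin at the top-left; rectangles are half-open
``[top, top + height) x [left, left + width)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

logger = logging.getLogger(__name__)

#: metadata key used for per-page acquisition times written by this package
TIMES_KEY = "times_s"


@dataclass
class ImageStack:
    """An ordered sequence of equally shaped 2-D intensity frames.

    Intensities are promoted to float64 on load but keep their native scale
    (no rescaling to [0, 1]); the histogram/threshold logic downstream is
    scale-free.
    """

    frames: np.ndarray  # (n_frames, n_rows, n_cols), float64, >= 0
    times_s: np.ndarray | None = None  # per-frame seconds, or None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("stack must hold at least one 2-D frame")
        if np.any(self.frames < 0):
            raise FormatError("negative intensities are not supported")
        if self.times_s is not None:
            self.times_s = np.asarray(self.times_s, dtype=np.float64)
            if self.times_s.shape != (self.n_frames,):
                raise FormatError("times_s length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) shared by every frame."""
        return self.frames.shape[1:]

    def frame_times(self) -> np.ndarray:
        """Times in seconds, falling back to the frame index."""
        if self.times_s is not None:
            return self.times_s
        return np.arange(self.n_frames, dtype=np.float64)


def read_stack(path: str | Path) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Per-page timestamps are recovered from the stack-level ``times_s``
    metadata entry (written by :func:`write_stack`) or, failing that, from
    per-page ``DateTime`` tags (converted to seconds relative to the first
    page). Without either, ``times_s`` is ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) == 0:
                raise FormatError(f"{path}: TIFF has zero pages")
            shapes = {p.shape for p in tif.pages}
            if len(shapes) != 1:
                raise FormatError(f"{path}: pages have inconsistent shapes {shapes}")
            data = tif.asarray()
            times = _extract_times(tif)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any tifffile failure
        raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if data.ndim not in (2, 3):
        raise FormatError(f"{path}: expected grayscale pages, got shape {data.shape}")
    return ImageStack(frames=data, times_s=times)


def _extract_times(tif: tifffile.TiffFile) -> np.ndarray | None:
    meta = tif.shaped_metadata
    if meta:
        times = meta[0].get(TIMES_KEY)
        if times is not None:
            return np.asarray(times, dtype=np.float64)
    # fall back to per-page DateTime tags ("YYYY:MM:DD HH:MM:SS")
    stamps = []
    for page in tif.pages:
        tag = page.tags.get("DateTime")
        if tag is None:
            return None
        stamps.append(tag.value)
    try:
        import datetime as _dt

        parsed = [_dt.datetime.strptime(s, "%Y:%m:%d %H:%M:%S") for s in stamps]
    except ValueError:
        return None
    t0 = parsed[0]
    return np.array([(t - t0).total_seconds() for t in parsed])


def write_stack(stack: ImageStack, path: str | Path, dtype=np.float32) -> None:
    """Write a stack as a multipage TIFF, embedding times in the metadata."""
    meta = {}
    if stack.times_s is not None:
        meta[TIMES_KEY] = [float(t) for t in stack.times_s]
    # explicit photometric keeps 3-frame stacks from being stored as RGB
    tifffile.imwrite(
        Path(path), stack.frames.astype(dtype), metadata=meta,
        photometric="minisblack",
    )


# ---------------------------------------------------------------------------
# results table


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-frame trace table as a UTF-8 comma-separated CSV.

    Column layout: ``frame,time_s,roi_process,roi_soma_1..m,roi_background,
    relocated``. Round-tripping through :func:`read_results` reproduces the
    integer/boolean columns bit-exactly and the reals to full printed
    precision.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(Path(path), index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if "relocated" in df.columns:
        df["relocated"] = df["relocated"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# overlays

_ROLE_COLORS = {"process": "red", "soma": "lime", "background": "deepskyblue"}


def write_overlay(frame: np.ndarray, layout, path: str | Path) -> None:
    """Render ROI outlines on top of the original (unrotated) frame as a PNG.

    The layout's rectangles live in rotated coordinates; each rectangle's
    corners are mapped back through the inverse of the saved rotation, so on
    the original image they appear as tilted quadrilaterals. Rectangles that
    fall partly outside the frame are clipped by the canvas with a logged
    warning.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    from .orient import inverse_map_points

    frame = np.asarray(frame, dtype=np.float64)
    angle = layout.orientation.angle_deg
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(frame, cmap="gray", interpolation="nearest")
    for roi in layout.all_rois():
        corners_rc = np.array(
            [
                [roi.top, roi.left],
                [roi.top, roi.left + roi.width],
                [roi.top + roi.height, roi.left + roi.width],
                [roi.top + roi.height, roi.left],
            ],
            dtype=np.float64,
        )
        mapped = inverse_map_points(corners_rc, frame.shape, angle)
        if (mapped < -0.5).any() or (mapped[:, 0] > frame.shape[0] - 0.5).any() or (
            mapped[:, 1] > frame.shape[1] - 0.5
        ).any():
            logger.warning("ROI %s/%s clipped at the frame border", roi.role, roi.order)
        ax.add_patch(
            Polygon(
                mapped[:, ::-1],  # matplotlib wants (x, y) = (col, row)
                closed=True,
                fill=False,
                edgecolor=_ROLE_COLORS.get(roi.role, "yellow"),
                linewidth=1.5,
            )
        )
    ax.set_axis_off()
    fig.savefig(Path(path), bbox_inches="tight", dpi=150)
    plt.close(fig)


def write_run_log(log: dict, path: str | Path) -> None:
    """Persist the machine-readable run log (config, layout, events) as JSON."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
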