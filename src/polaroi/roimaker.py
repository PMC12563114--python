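"""ROI placement on the rotated, cleaned first-frame mask.

One rectangle is sized from the process (the thin apical compartment, to the
right after orientation); identically sized rectangles are then tiled right
to left along the soma midline — as many as fit between the apical and basal
ends — and one more is parked on clean background far from the cell, for
reference. Identical dimensions everywhere keep the per-ROI means comparable
and make the positional pixel pairing of the motion check well defined.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cleaner, orient
from .errors import LayoutError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle, half-open [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int
    role: str  # process | soma | background
    order: int = 0  # soma ROIs numbered 1..m, apical (right) to basal (left)

    def pixels(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.top : self.top + self.height, self.left : self.left + self.width]

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            self.top >= 0
            and self.left >= 0
            and self.top + self.height <= shape[0]
            and self.left + self.width <= shape[1]
        )

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "left": self.left,
            "height": self.height,
            "width": self.width,
            "role": self.role,
            "order": self.order,
        }


@dataclass
class RoiLayout:
    """The saved rotation plus the ordered ROI set valid from a frame onward."""

    orientation: orient.Orientation
    process_roi: Roi
    soma_rois: list[Roi]
    background_roi: Roi
    valid_from_frame: int = 0
    rotated_shape: tuple[int, int] | None = None
    threshold: float | None = None
    process_span: tuple[int, int] | None = None  # inclusive columns, rotated coords
    soma_span: tuple[int, int] | None = None  # inclusive columns, rotated coords

    def all_rois(self) -> list[Roi]:
        return [self.process_roi, *self.soma_rois, self.background_roi]

    def cell_rois(self) -> list[Roi]:
        return [self.process_roi, *self.soma_rois]

    @property
    def template_dims(self) -> tuple[int, int]:
        return (self.process_roi.height, self.process_roi.width)

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation.to_dict(),
            "process_roi": self.process_roi.to_dict(),
            "soma_rois": [r.to_dict() for r in self.soma_rois],
            "background_roi": self.background_roi.to_dict(),
            "valid_from_frame": self.valid_from_frame,
            "rotated_shape": list(self.rotated_shape) if self.rotated_shape else None,
            "threshold": self.threshold,
            "process_span": list(self.process_span) if self.process_span else None,
            "soma_span": list(self.soma_span) if self.soma_span else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiLayout":
        return cls(
            orientation=orient.Orientation(**d["orientation"]),
            process_roi=Roi(**d["process_roi"]),
            soma_rois=[Roi(**r) for r in d["soma_rois"]],
            background_roi=Roi(**d["background_roi"]),
            valid_from_frame=d.get("valid_from_frame", 0),
            rotated_shape=tuple(d["rotated_shape"]) if d.get("rotated_shape") else None,
            threshold=d.get("threshold"),
            process_span=tuple(d["process_span"]) if d.get("process_span") else None,
            soma_span=tuple(d["soma_span"]) if d.get("soma_span") else None,
        )


def save_layout(layout: RoiLayout, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(layout.to_dict(), fh, indent=2)


def load_layout(path: str | Path) -> RoiLayout:
    with open(Path(path), encoding="utf-8") as fh:
        return RoiLayout.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# placement primitives


def locate_process(
    profile: np.ndarray, maxima: list[tuple[int, float]]
) -> tuple[int, int, int]:
    """Split the profile at the soma/process intensity gap.

    Between the two profile maxima (soma left, process right after
    orientation) the boundary column is the argmin of the raw profile
    strictly between them — the "intensity gap" — with ties going to the
    leftmost column so more soma is retained for tiling. If there is no dip
    (interior minimum is no lower than either maximum), the midpoint between
    the maxima is used and logged as low confidence. Returns
    ``(boundary_col, proc_left, proc_right)`` with the process span running
    from ``boundary_col + 1`` to the rightmost nonzero-profile column.
    """
    profile = np.asarray(profile)
    if len(maxima) != 2:
        raise LayoutError("locate_process needs exactly two profile maxima")
    (c1, _), (c2, _) = sorted(maxima)
    interior = profile[c1 + 1 : c2]
    if interior.size == 0:
        boundary = (c1 + c2) // 2
        logger.warning("no columns between maxima; midpoint boundary %d", boundary)
    else:
        lowest = interior.min()
        if lowest >= min(profile[c1], profile[c2]):
            boundary = (c1 + c2) // 2
            logger.warning(
                "flat profile between maxima; low-confidence midpoint boundary %d",
                boundary,
            )
        else:
            boundary = c1 + 1 + int(np.argmin(interior))
    nonzero = np.nonzero(profile)[0]
    proc_right = int(nonzero[-1])
    proc_left = int(boundary) + 1
    if proc_left > proc_right:
        raise LayoutError("no process columns right of the boundary")
    return int(boundary), proc_left, proc_right


def make_process_roi(mask: np.ndarray, proc_span: tuple[int, int]) -> Roi:
    """Bounding box of foreground inside the process columns (the template)."""
    left_col, right_col = proc_span
    sub = np.asarray(mask)[:, left_col : right_col + 1]
    rows, cols = np.nonzero(sub)
    if rows.size == 0:
        raise LayoutError("no foreground pixels in the process span")
    roi = Roi(
        top=int(rows.min()),
        left=left_col + int(cols.min()),
        height=int(rows.max() - rows.min() + 1),
        width=int(cols.max() - cols.min() + 1),
        role="process",
    )
    if roi.height == 1 and roi.width == 1:
        logger.warning("process ROI is a single pixel")
    return roi


def soma_midline(mask: np.ndarray, soma_columns: np.ndarray) -> dict[int, int]:
    """Midline row per soma column: mean foreground row, rounded half-up.

    Columns with no foreground are skipped.
    """
    mask = np.asarray(mask)
    midline: dict[int, int] = {}
    for col in np.asarray(soma_columns, dtype=int):
        rows = np.nonzero(mask[:, col])[0]
        if rows.size:
            midline[int(col)] = int(math.floor(rows.mean() + 0.5))
    return midline


def tile_soma_rois(
    mask: np.ndarray, template_dims: tuple[int, int], boundary_col: int
) -> list[Roi]:
    """Tile template-sized rectangles right-to-left along the soma midline.

    Starting at the soma's rightmost (apical) foreground column and stepping
    left by the template width, each rectangle is centered vertically on the
    midline row at its center column. Tiling stops when the next rectangle
    would cross the soma's leftmost foreground column or leave the frame, so
    the count is the number of process-sized spans that fit along the soma.
    """
    mask = np.asarray(mask)
    h, w = int(template_dims[0]), int(template_dims[1])
    if h < 1 or w < 1:
        raise LayoutError("template dimensions must be >= 1")
    soma_cols = np.nonzero(column_profile_upto(mask, boundary_col))[0]
    if soma_cols.size == 0:
        raise LayoutError("no soma foreground left of the boundary")
    left_limit, right_limit = int(soma_cols[0]), int(soma_cols[-1])
    midline = soma_midline(mask, soma_cols)
    mid_cols = np.array(sorted(midline))
    rois: list[Roi] = []
    order = 1
    right_edge = right_limit
    while True:
        left = right_edge - w + 1
        if left < left_limit:
            break
        center_col = left + (w - 1) // 2
        nearest = int(mid_cols[np.argmin(np.abs(mid_cols - center_col))])
        top = midline[nearest] - h // 2
        if top < 0 or top + h > mask.shape[0]:
            break
        rois.append(Roi(top=top, left=left, height=h, width=w, role="soma", order=order))
        order += 1
        right_edge -= w
    if not rois:
        raise LayoutError("soma shorter than process ROI")
    return rois


def column_profile_upto(mask: np.ndarray, boundary_col: int) -> np.ndarray:
    """Column profile restricted to columns at or left of the boundary."""
    profile = np.asarray(mask, dtype=np.int64).sum(axis=0)
    out = np.zeros_like(profile)
    out[: boundary_col + 1] = profile[: boundary_col + 1]
    return out


def place_background_roi(
    mask: np.ndarray,
    template_dims: tuple[int, int],
    allowed: np.ndarray | None = None,
) -> Roi:
    """Template-sized all-background rectangle far from the cell.

    Every possible window position is scored by its Chebyshev distance from
    the foreground bounding box (integral-image window sums make the scan
    cheap); the farthest clean window wins, which lands in a frame corner
    whenever one is clean. ``allowed`` (optional boolean mask) restricts the
    search to usable pixels — on a rotated canvas, those with support in the
    original frame. Raises if no window is free of foreground.
    """
    mask = np.asarray(mask, dtype=np.uint8)
    h, w = int(template_dims[0]), int(template_dims[1])
    n_rows, n_cols = mask.shape
    if h > n_rows or w > n_cols:
        raise LayoutError("template larger than the frame")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise LayoutError("empty mask; nothing to stay away from")
    bb_top, bb_bottom = int(rows.min()), int(rows.max())
    bb_left, bb_right = int(cols.min()), int(cols.max())
    blocked = mask.astype(bool)
    if allowed is not None:
        blocked |= ~np.asarray(allowed, dtype=bool)
    integral = np.zeros((n_rows + 1, n_cols + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(blocked, axis=0), axis=1)
    sums = (
        integral[h:, w:]
        - integral[:-h, w:]
        - integral[h:, :-w]
        + integral[:-h, :-w]
    )  # sums[i, j] = foreground count of window with top-left (i, j)
    tops = np.arange(n_rows - h + 1)[:, None]
    lefts = np.arange(n_cols - w + 1)[None, :]
    v_gap = np.maximum(0, np.maximum(bb_top - (tops + h), tops - bb_bottom - 1))
    h_gap = np.maximum(0, np.maximum(bb_left - (lefts + w), lefts - bb_right - 1))
    dist = np.maximum(v_gap, h_gap).astype(np.float64)
    dist[sums > 0] = -1.0
    best = int(np.argmax(dist))
    if dist.flat[best] < 0:
        raise LayoutError("no clean background region")
    top, left = np.unravel_index(best, dist.shape)
    return Roi(top=int(top), left=int(left), height=h, width=w, role="background")


# ---------------------------------------------------------------------------
# composition


def build_layout(
    first_frame: np.ndarray,
    max_clean_iterations: int = 2,
    n_bins: int | None = None,
    manual_threshold: float | None = None,
    manual_angle_deg: float | None = None,
    smoothing_window: int = 5,
    min_peak_separation: int = 10,
    template_dims: tuple[int, int] | None = None,
    valid_from_frame: int = 0,
    interactive: bool = False,
    prompt=None,
) -> RoiLayout:
    """Full first-frame chain: clean → orient → locate process → tile → background.

    With ``manual_angle_deg`` the axis fit is skipped (semi-automatic use);
    the flip check and everything downstream run unchanged. With
    ``template_dims`` the ROI size is forced instead of taken from the
    process bounding box — used when relocating after drift, where size and
    shape must stay as previously defined. All rectangles live in the rotated
    frame's coordinates; the rotation itself is saved in the layout.
    """
    result = cleaner.clean(
        first_frame,
        max_iterations=max_clean_iterations,
        interactive=interactive,
        n_bins=n_bins,
        manual_threshold=manual_threshold,
        prompt=prompt,
    )
    mask = result.mask
    base_angle = manual_angle_deg if manual_angle_deg is not None else orient.fit_axis(mask)
    orientation = orient.resolve_orientation(
        mask,
        base_angle,
        min_separation=min_peak_separation,
        smoothing_window=smoothing_window,
    )
    rmask = orient.rotate_mask(mask, orientation.angle_deg)
    profile = orient.column_profile(rmask)
    maxima = orient.find_local_maxima(
        profile, min_separation=min_peak_separation, smoothing_window=smoothing_window
    )
    if len(maxima) < 2:
        raise LayoutError("profile maxima vanished after rotation")
    boundary, proc_left, proc_right = locate_process(profile, maxima)
    process_roi = make_process_roi(rmask, (proc_left, proc_right))
    if template_dims is not None:
        h, w = int(template_dims[0]), int(template_dims[1])
        # keep the forced size, anchored at the process's apical (right) edge
        right = process_roi.left + process_roi.width
        center = process_roi.top + process_roi.height // 2
        top = min(max(center - h // 2, 0), rmask.shape[0] - h)
        left = min(max(right - w, 0), rmask.shape[1] - w)
        process_roi = Roi(top=int(top), left=int(left), height=h, width=w, role="process")
    soma_rois = tile_soma_rois(rmask, (process_roi.height, process_roi.width), boundary)
    # the rotated canvas has unsupported corners (no source pixels); the
    # background ROI must sample real background, so restrict the search to
    # fully supported pixels
    support = (
        orient.rotate_frame(
            np.ones_like(np.asarray(first_frame, dtype=np.float64)),
            orientation.angle_deg,
        )
        >= 0.999
    )
    background_roi = place_background_roi(
        rmask, (process_roi.height, process_roi.width), allowed=support
    )
    soma_cols = np.nonzero(column_profile_upto(rmask, boundary))[0]
    layout = RoiLayout(
        orientation=orientation,
        process_roi=process_roi,
        soma_rois=soma_rois,
        background_roi=background_roi,
        valid_from_frame=valid_from_frame,
        rotated_shape=rmask.shape,
        threshold=result.threshold,
        process_span=(proc_left, proc_right),
        soma_span=(int(soma_cols[0]), int(soma_cols[-1])),
    )
    for roi in layout.all_rois():
        if not roi.within(rmask.shape):
            raise LayoutError(f"{roi.role} ROI leaves the rotated frame")
    return layout
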