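"""Cell orientation: axis estimation, rotation, and process-side resolution.

The downstream ROI logic needs the cell horizontal with the process pointing
right. The long axis is estimated by fitting a regression line to the
foreground pixels of the binary mask; the image is rotated by the line's
angle (bilinear interpolation, canvas enlarged to hold the content); and the
column profile of the rotated mask — per-column count of foreground pixels —
is used to decide whether the process (the smaller of the profile's two local
maxima) ended up left or right of the soma. If left, 180 degrees are added.

Angle convention: positive angles rotate the displayed image
counterclockwise (with the row axis pointing down, as images are drawn).
``rotate_frame(frame, fit_axis(mask))`` levels the cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import AxisUndefinedError, ProcessNotFoundError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Orientation:
    """Rotation to apply to every frame, plus whether a 180° flip was needed."""

    angle_deg: float  # in (-180, 180]
    flipped: bool

    def to_dict(self) -> dict:
        return asdict(self)


def normalize_angle(angle_deg: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (float(angle_deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


# ---------------------------------------------------------------------------
# rotation


def _rotation_geometry(shape: tuple[int, int], angle_deg: float):
    """Output shape, matrix and offset for a content-preserving rotation.

    A point ``p`` (relative to the input center, display coordinates
    x=column, y=row-down) appears at ``p' = R p`` in the output, with
    ``R = [[cos, sin], [-sin, cos]]`` — visual counterclockwise rotation.
    Returns the output→input mapping used by ``ndimage.affine_transform``.
    """
    n_rows, n_cols = shape
    rad = math.radians(angle_deg)
    c, s = math.cos(rad), math.sin(rad)
    out_rows = int(math.ceil(abs(n_cols * s) + abs(n_rows * c) - 1e-9))
    out_cols = int(math.ceil(abs(n_cols * c) + abs(n_rows * s) - 1e-9))
    # output -> input in (row, col) ordering
    matrix = np.array([[c, s], [-s, c]], dtype=np.float64)
    in_center = np.array([(n_rows - 1) / 2.0, (n_cols - 1) / 2.0])
    out_center = np.array([(out_rows - 1) / 2.0, (out_cols - 1) / 2.0])
    offset = in_center - matrix @ out_center
    return (out_rows, out_cols), matrix, offset


def rotate_frame(frame: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image center with bilinear interpolation.

    The output canvas is enlarged to contain the rotated content; pixels with
    no source support are 0. An angle of 0 is the bit-exact identity.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if angle_deg == 0.0:
        return frame.copy()
    out_shape, matrix, offset = _rotation_geometry(frame.shape, angle_deg)
    return ndimage.affine_transform(
        frame,
        matrix,
        offset=offset,
        output_shape=out_shape,
        order=1,
        mode="grid-constant",
        cval=0.0,
        prefilter=False,
    )


def rotate_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a binary mask, re-binarizing interpolated values at 0.5."""
    return (rotate_frame(np.asarray(mask, dtype=np.float64), angle_deg) >= 0.5).astype(
        np.uint8
    )


def inverse_map_points(
    points_rc: np.ndarray, original_shape: tuple[int, int], angle_deg: float
) -> np.ndarray:
    """Map (row, col) points from rotated-canvas coordinates back to the
    original frame's coordinates (the output→input map of the rotation)."""
    out_shape, matrix, offset = _rotation_geometry(original_shape, angle_deg)
    pts = np.atleast_2d(np.asarray(points_rc, dtype=np.float64))
    return pts @ matrix.T + offset


# ---------------------------------------------------------------------------
# axis estimation


def _ols_angle(mask: np.ndarray) -> float:
    rows, cols = np.nonzero(mask)
    if rows.size < 2 or np.unique(cols).size < 2:
        raise AxisUndefinedError("axis undefined; tilt the preparation")
    slope = np.polyfit(cols.astype(np.float64), rows.astype(np.float64), 1)[0]
    return math.degrees(math.atan(slope))


def fit_axis(
    mask: np.ndarray,
    refine: bool = True,
    tol_deg: float = 0.25,
    max_iter: int = 10,
) -> float:
    """Angle of the cell's long axis from a regression-line fit.

    Ordinary least squares of foreground row coordinates on column
    coordinates gives ``atan(slope)``. Because the cell has nonzero width, a
    single fit underestimates steep angles (regression dilution), so by
    default the fit is iterated: rotate the mask by the accumulated angle,
    re-fit the residual slope, and repeat until the residual is below
    ``tol_deg`` (at most ``max_iter`` passes). The result is the angle by
    which the image must be rotated to level the line.

    A near-vertical cell yields a near-zero slope (columns carry almost no
    information about rows), so the returned angle is ~0 and the process/soma
    separation downstream fails — the documented failure mode for vertically
    oriented cells. A strictly single-column foreground raises
    :class:`AxisUndefinedError`.
    """
    mask = np.asarray(mask)
    angle = _ols_angle(mask)
    if not refine:
        return angle
    for _ in range(max_iter - 1):
        residual = _ols_angle(rotate_mask(mask, angle))
        angle += residual
        if abs(residual) < tol_deg:
            break
    return angle


# ---------------------------------------------------------------------------
# column profile and process side


def column_profile(mask: np.ndarray) -> np.ndarray:
    """Per-column count of foreground pixels (length = number of columns)."""
    return np.asarray(mask, dtype=np.int64).sum(axis=0)


def find_local_maxima(
    profile: np.ndarray,
    min_separation: int = 10,
    smoothing_window: int = 5,
    min_prominence: float | None = None,
) -> list[tuple[int, float]]:
    """At most the two tallest local maxima of the smoothed column profile.

    The profile is smoothed with a centered moving average (window
    ``smoothing_window``; zero-padded at the edges, which also damps spurious
    border peaks), local maxima are located (plateaus count once, at their
    middle sample), peaks of negligible prominence — residual noise ripple on
    the wide soma hump — are discarded (default cutoff: 5% of the smoothed
    maximum, at least 1 count), and the survivors are thinned greedily by
    height so the kept peaks are at least ``min_separation`` columns apart.
    Returns ``[(column, smoothed_height), ...]`` sorted by column; empty for
    monotone profiles.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.size < 3:
        raise ValueError("profile must have at least 3 columns")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        smoothed = np.convolve(profile, kernel, mode="same")
    else:
        smoothed = profile
    if min_prominence is None:
        min_prominence = max(1.0, 0.05 * float(smoothed.max()))
    peaks, _ = signal.find_peaks(smoothed, prominence=min_prominence)
    order = sorted(peaks, key=lambda i: (-smoothed[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(i)
        if len(kept) == 2:
            break
    kept.sort()
    return [(int(i), float(smoothed[i])) for i in kept]


def resolve_orientation(
    mask: np.ndarray,
    base_angle_deg: float,
    min_separation: int = 10,
    smoothing_window: int = 5,
) -> Orientation:
    """Ensure the process points right; add 180° to the rotation if not.

    After rotating the mask by ``base_angle_deg``, the column profile must
    show two local maxima: the taller is the soma, the smaller the process.
    If the smaller maximum lies left of the taller, the cell is flipped by
    adding 180° to the saved angle. The final angle is saved once and applied
    directly to every subsequent frame.
    """
    rotated = rotate_mask(mask, base_angle_deg)
    profile = column_profile(rotated)
    maxima = find_local_maxima(
        profile, min_separation=min_separation, smoothing_window=smoothing_window
    )
    if len(maxima) < 2:
        raise ProcessNotFoundError(
            "process not distinguishable; retry after cleaning or tilt"
        )
    (col_a, h_a), (col_b, h_b) = maxima
    smaller_col = col_a if h_a < h_b else col_b
    larger_col = col_b if h_a < h_b else col_a
    if smaller_col < larger_col:
        return Orientation(
            angle_deg=normalize_angle(base_angle_deg + 180.0), flipped=True
        )
    return Orientation(angle_deg=normalize_angle(base_angle_deg), flipped=False)
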