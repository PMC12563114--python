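"""First-frame segmentation: histogram, elbow threshold, binarization, pruning.

The cell is separated from the background with a scale-free recipe: build the
intensity histogram of the nonzero pixels, take its mode as the background
level, hand the curve strictly right of the mode to the kneedle elbow finder,
and threshold at the elbow. Stray suprathreshold noise is then eroded with a
Game-of-Life style rule: a foreground pixel survives only if at least three
of its eight neighbors are foreground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError, EmptyImageError, EmptyMaskError

logger = logging.getLogger(__name__)


@dataclass
class Histogram:
    """Intensity histogram over the nonzero pixels of a frame.

    Pixels with intensity exactly 0 are cropped regions kept for storage
    efficiency, not data, and are excluded before binning.
    """

    bin_centers: np.ndarray  # strictly increasing
    counts: np.ndarray  # non-negative integers, same length


@dataclass(frozen=True)
class ElbowPoint:
    x: float
    y: float


def intensity_histogram(frame: np.ndarray, n_bins: int | None = None) -> Histogram:
    """Histogram the nonzero pixel intensities of ``frame``.

    With ``n_bins=None`` the binning is chosen by dtype: integer images get
    one bin per integer level in ``[1, max]`` (empty levels included, so the
    x-spacing handed to kneedle stays uniform); float images get 256
    equal-width bins over ``(0, max]``. An explicit ``n_bins`` forces that
    many equal-width bins over ``(0, max]``.
    """
    frame = np.asarray(frame)
    values = frame[frame > 0]
    if values.size == 0:
        raise EmptyImageError("empty image after zero exclusion")
    integral = np.issubdtype(frame.dtype, np.integer)
    if n_bins is None and integral:
        vmax = int(values.max())
        counts = np.bincount(values.astype(np.int64).ravel(), minlength=vmax + 1)[1:]
        centers = np.arange(1, vmax + 1, dtype=np.float64)
        return Histogram(bin_centers=centers, counts=counts)
    if n_bins is None:
        n_bins = 256
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    vmax = float(values.max())
    edges = np.linspace(0.0, vmax, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(bin_centers=centers, counts=counts.astype(np.int64))


def find_mode(hist: Histogram) -> float:
    """Bin center with the maximal count; ties resolved toward low intensity.

    The mode of the nonzero-pixel histogram is taken as the background level
    (background dominates single-cell fields). Biasing ties low keeps more of
    the tail inside the kneedle window.
    """
    if len(hist.counts) == 0:
        raise EmptyImageError("empty histogram")
    return float(hist.bin_centers[int(np.argmax(hist.counts))])


def kneedle(xs: np.ndarray, ys: np.ndarray) -> ElbowPoint:
    """Elbow of a decreasing, convex-ish curve (Kneedle, raw difference form).

    Both axes are min-max normalized to [0, 1]; for a decreasing convex curve
    the difference ``d_i = (1 - y_i) - x_i`` peaks at the elbow, and the input
    point maximizing it (first index on ties) is returned. No sensitivity
    smoothing is applied: the right-of-mode histogram tail this operates on is
    decreasing and convex by construction, and curve-direction auto-detection
    is deliberately out of scope. Violations of the expected shape are logged,
    never fatal.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be 1-D arrays of equal length")
    if xs.size < 3:
        raise ValueError("kneedle needs at least 3 points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    rises = np.diff(ys)
    y_range = ys.max() - ys.min()
    if np.any(rises > 0.1 * max(y_range, 1e-12)):
        logger.warning("kneedle input is not monotonically decreasing")
    x_span = xs[-1] - xs[0]
    y_span = ys.max() - ys.min()
    x_norm = (xs - xs[0]) / x_span
    y_norm = np.zeros_like(ys) if y_span == 0 else (ys - ys.min()) / y_span
    diff = (1.0 - y_norm) - x_norm
    i = int(np.argmax(diff))
    return ElbowPoint(x=float(xs[i]), y=float(ys[i]))


def compute_threshold(
    frame: np.ndarray,
    n_bins: int | None = None,
) -> float:
    """Intensity threshold separating background from cell.

    The histogram strictly right of the mode (background peak) is passed to
    :func:`kneedle`; the elbow's x-coordinate is the threshold.
    """
    hist = intensity_histogram(frame, n_bins=n_bins)
    mode = find_mode(hist)
    right = hist.bin_centers > mode
    if int(right.sum()) < 3:
        raise DegenerateHistogramError(
            "degenerate histogram; supply threshold manually"
        )
    elbow = kneedle(hist.bin_centers[right], hist.counts[right])
    return elbow.x


def binarize(frame: np.ndarray, threshold: float) -> np.ndarray:
    """0/1 mask: 1 where intensity is strictly above the threshold.

    Equality maps to background (conservative reading of "above").
    """
    return (np.asarray(frame) > threshold).astype(np.uint8)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def prune_noise(mask: np.ndarray) -> np.ndarray:
    """One synchronous Game-of-Life-style survival pass.

    A foreground pixel stays foreground iff at least 3 of its 8 neighbors are
    foreground (edge pixels count only existing neighbors); background pixels
    never turn on. All decisions use the pre-pass mask.
    """
    mask = np.asarray(mask, dtype=np.uint8)
    neighbors = ndimage.convolve(mask, _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return ((mask == 1) & (neighbors >= 3)).astype(np.uint8)


class CleanResult(NamedTuple):
    mask: np.ndarray
    threshold: float
    removed_per_pass: list[int]


def clean(
    frame: np.ndarray,
    max_iterations: int = 2,
    interactive: bool = False,
    n_bins: int | None = None,
    manual_threshold: float | None = None,
    prompt: Callable[[str], str] | None = None,
    display: Callable[[np.ndarray], None] | None = None,
) -> CleanResult:
    """Threshold the frame and prune noise, returning the clean binary mask.

    Batch mode (default) runs exactly ``max_iterations`` pruning passes or
    stops early at a fixed point. In interactive mode the mask is shown after
    each pass via ``display`` and the user is asked (via ``prompt``, default
    ``input``) whether further adjustment is necessary, mirroring bench use
    where the analyst eyeballs the mask.
    """
    threshold = (
        float(manual_threshold)
        if manual_threshold is not None
        else compute_threshold(frame, n_bins=n_bins)
    )
    mask = binarize(frame, threshold)
    removed: list[int] = []
    if interactive:
        ask = prompt if prompt is not None else input
        show = display if display is not None else (lambda m: None)
        while True:
            show(mask)
            answer = ask("further adjustment necessary? [y/N] ").strip().lower()
            if not answer.startswith("y"):
                break
            new = prune_noise(mask)
            removed.append(int(mask.sum() - new.sum()))
            mask = new
    else:
        for _ in range(max_iterations):
            new = prune_noise(mask)
            n_removed = int(mask.sum() - new.sum())
            removed.append(n_removed)
            mask = new
            if n_removed == 0:
                break
    for i, n in enumerate(removed, start=1):
        logger.info("cleaning pass %d removed %d pixels", i, n)
    if mask.sum() == 0:
        raise EmptyMaskError("cleaning removed the entire cell")
    return CleanResult(mask=mask, threshold=threshold, removed_per_pass=removed)
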