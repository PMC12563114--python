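"""Parametric ground-truth movies of a single polarized cell.

The generator emulates the experimental regime the pipeline targets: one
fluorescently labeled cell per field — an elliptical soma with a single
thinner apical process at an arbitrary orientation — sitting on a dimmer
background, with additive Gaussian camera noise, optional compartment-
specific transients (linear rise, exponential decay) and optional step
translations of the whole preparation (perfusion drift). A short dim neck
separates process from soma, reproducing the intensity gap seen between the
compartments in real recordings; without it the column profile would fall
monotonically from the soma peak and the process would never form the second
local maximum the placement logic keys on.

The transient scales the fluorescence *above* background:
``I(t) = bg + (level - bg) * (1 + dFF(t))`` on compartment pixels, so the
programmed peak equals the background-corrected dF/F0 the analysis recovers.
Every movie is a pure function of its spec (seeded noise): same spec, same
bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tiffio import ImageStack


@dataclass(frozen=True)
class TransientSpec:
    """Compartment transient: peak dF/F0, onset frame, rise/decay (frames)."""

    peak_dff: float = 0.0
    onset_frame: int = 40
    rise_frames: int = 5
    decay_frames: float = 15.0

    def dff(self, n_frames: int) -> np.ndarray:
        t = np.arange(n_frames, dtype=np.float64)
        out = np.zeros(n_frames)
        if self.peak_dff == 0.0:
            return out
        t0, rise = self.onset_frame, max(self.rise_frames, 1)
        rising = (t >= t0) & (t < t0 + rise)
        out[rising] = (t[rising] - t0 + 1) / rise
        falling = t >= t0 + rise
        out[falling] = np.exp(-(t[falling] - t0 - rise + 1) / self.decay_frames)
        return self.peak_dff * out


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic recording; see module docstring."""

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] | None = None  # (row, col); default frame center
    soma_semi_axes: tuple[float, float] = (60.0, 24.0)  # (along axis, across) px
    process_length: float = 40.0
    process_width: float = 8.0
    neck_length: float = 4.0  # dim gap between soma pole and process
    theta_deg: float = 15.0  # axis angle; fit_axis recovers this
    chirality: str = "right"  # process side before any rotation
    background_level: float = 15.0
    soma_level: float = 80.0
    process_level: float = 70.0
    noise_sd: float = 3.0
    soma_transient: TransientSpec = TransientSpec(peak_dff=0.5)
    process_transient: TransientSpec = TransientSpec(peak_dff=0.8)
    drift: tuple[tuple[int, int, int], ...] = ()  # (frame, d_row, d_col) steps
    n_frames: int = 120
    frame_period_s: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        a, b = self.soma_semi_axes
        if not (a > b > 0):
            raise ValueError("soma semi-axes must satisfy a > b > 0")
        if not (self.process_width < 2 * b):
            raise ValueError("process width must be below the soma minor axis")
        if not (self.process_level > self.background_level >= 0):
            raise ValueError("process level must exceed the background")
        if not (self.soma_level > self.background_level):
            raise ValueError("soma level must exceed the background")
        if self.chirality not in ("right", "left"):
            raise ValueError("chirality must be 'right' or 'left'")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        # the cell (plus accumulated drift) must stay inside the frame
        half_len = a + self.neck_length + self.process_length
        half_wid = max(b, self.process_width / 2)
        radius = math.hypot(half_len, half_wid)
        cr, cc = self.cell_center()
        for dr, dc in [(0, 0), *self.cumulative_drift()]:
            if not (
                0 <= cr + dr - radius
                and cr + dr + radius < self.shape[0]
                and 0 <= cc + dc - radius
                and cc + dc + radius < self.shape[1]
            ):
                raise ValueError("cell exits the frame under the drift schedule")

    def cell_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def cumulative_drift(self) -> list[tuple[float, float]]:
        """Cumulative (d_row, d_col) at each scheduled step, in frame order."""
        out, dr, dc = [], 0.0, 0.0
        for _, step_r, step_c in sorted(self.drift):
            dr += step_r
            dc += step_c
            out.append((dr, dc))
        return out

    def offset_at(self, frame_idx: int) -> tuple[float, float]:
        dr, dc = 0.0, 0.0
        for f, step_r, step_c in sorted(self.drift):
            if frame_idx >= f:
                dr += step_r
                dc += step_c
        return dr, dc


@dataclass
class GroundTruth:
    """Per-frame truth record accompanying a rendered movie."""

    spec: SynthSpec
    soma_mask: np.ndarray  # un-drifted masks, frame shape
    process_mask: np.ndarray
    soma_dff: np.ndarray  # per-frame programmed dF/F0
    process_dff: np.ndarray
    soma_mean: np.ndarray  # noise-free mean intensity on the compartment
    process_mean: np.ndarray
    times_s: np.ndarray

    def mask_at(self, compartment: str, frame_idx: int) -> np.ndarray:
        """Compartment mask shifted by the drift in effect at ``frame_idx``."""
        base = self.soma_mask if compartment == "soma" else self.process_mask
        dr, dc = self.spec.offset_at(frame_idx)
        out = np.zeros_like(base)
        rows, cols = np.nonzero(base)
        rows = rows + int(round(dr))
        cols = cols + int(round(dc))
        keep = (rows >= 0) & (rows < base.shape[0]) & (cols >= 0) & (cols < base.shape[1])
        out[rows[keep], cols[keep]] = 1
        return out

    def to_dict(self) -> dict:
        return {
            "theta_deg": self.spec.theta_deg,
            "chirality": self.spec.chirality,
            "drift": [list(d) for d in self.spec.drift],
            "times_s": self.times_s.tolist(),
            "soma_dff": self.soma_dff.tolist(),
            "process_dff": self.process_dff.tolist(),
            "soma_mean": self.soma_mean.tolist(),
            "process_mean": self.process_mean.tolist(),
        }


def _compartment_masks(
    spec: SynthSpec, offset: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize soma and process masks at the given drift offset.

    Pixels are tested in the cell's axis frame: ``u`` along the axis (unit
    vector (cos θ, sin θ) in (col, row-down) coordinates), ``v`` across.
    """
    n_rows, n_cols = spec.shape
    cr, cc = spec.cell_center()
    cr, cc = cr + offset[0], cc + offset[1]
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rad = math.radians(spec.theta_deg)
    cos_t, sin_t = math.cos(rad), math.sin(rad)
    u = (cols - cc) * cos_t + (rows - cr) * sin_t
    v = -(cols - cc) * sin_t + (rows - cr) * cos_t
    if spec.chirality == "left":
        u = -u
    a, b = spec.soma_semi_axes
    soma = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    u0 = a + spec.neck_length
    process = (
        (u >= u0)
        & (u <= u0 + spec.process_length)
        & (np.abs(v) <= spec.process_width / 2.0)
    )
    process &= ~soma
    return soma.astype(np.uint8), process.astype(np.uint8)


def render_movie(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Render the movie and its ground truth. Deterministic in ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    soma_dff = spec.soma_transient.dff(spec.n_frames)
    process_dff = spec.process_transient.dff(spec.n_frames)
    bg = spec.background_level
    soma_mean = bg + (spec.soma_level - bg) * (1.0 + soma_dff)
    process_mean = bg + (spec.process_level - bg) * (1.0 + process_dff)
    frames = np.empty((spec.n_frames, *spec.shape), dtype=np.float64)
    masks_cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}
    for t in range(spec.n_frames):
        offset = spec.offset_at(t)
        if offset not in masks_cache:
            masks_cache[offset] = _compartment_masks(spec, offset)
        soma, process = masks_cache[offset]
        frame = np.full(spec.shape, bg, dtype=np.float64)
        frame[soma == 1] = soma_mean[t]
        frame[process == 1] = process_mean[t]
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, size=spec.shape)
        frames[t] = np.clip(frame, 0.0, None)
    times = np.arange(spec.n_frames, dtype=np.float64) * spec.frame_period_s
    soma0, process0 = _compartment_masks(spec, (0.0, 0.0))
    truth = GroundTruth(
        spec=spec,
        soma_mask=soma0,
        process_mask=process0,
        soma_dff=soma_dff,
        process_dff=process_dff,
        soma_mean=soma_mean,
        process_mean=process_mean,
        times_s=times,
    )
    return ImageStack(frames=frames, times_s=times), truth


# ---------------------------------------------------------------------------
# presets


def default_deiters_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Deiters'-cell-like default: wide elongated soma, one thin apical process.

    256x256 frame; soma semi-axes 60x24 px; process 40x8 px; background 15,
    soma 80, process 70 intensity units; noise SD 3; 120 frames at 1 s with a
    transient starting at frame 40 (process peak dF/F0 0.8, soma 0.5).
    """
    return replace(SynthSpec(seed=seed), **overrides)


def cone_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Photoreceptor-like variant: long, wide outer segment, small soma.

    The different process/soma ratio means fewer process-sized ROIs fit on
    the soma than for the Deiters default.
    """
    base = SynthSpec(
        soma_semi_axes=(32.0, 26.0),
        process_length=60.0,
        process_width=24.0,
        seed=seed,
    )
    return replace(base, **overrides)


def two_gaussian_image(
    shape: tuple[int, int] = (128, 128),
    cell_fraction: float = 0.05,
    background: tuple[float, float] = (20.0, 2.0),
    cell: tuple[float, float] = (80.0, 5.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat two-population image: background Gaussian plus a central disk of
    cell-intensity pixels covering ``cell_fraction`` of the area. Returns the
    image and the true cell mask — a minimal fixture for threshold tests."""
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    image = rng.normal(background[0], background[1], size=shape)
    radius = math.sqrt(cell_fraction * n_rows * n_cols / math.pi)
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    mask = ((rows - (n_rows - 1) / 2) ** 2 + (cols - (n_cols - 1) / 2) ** 2) <= radius**2
    image[mask] = rng.normal(cell[0], cell[1], size=int(mask.sum()))
    return np.clip(image, 0.0, None), mask.astype(np.uint8)
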