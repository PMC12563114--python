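# Methods

This note documents the models and numerical choices behind `polaroi`: what
each stage assumes, which knobs matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Problem setting

One fluorescently labeled polarized cell — an elongated soma with a single
thinner apical process — recorded as a multipage grayscale TIFF, one page per
time point. The goal is a set of equally sized rectangular ROIs covering the
process tip and the soma, per-frame mean-intensity traces for each, and
robustness against translation of the preparation during the recording.
Multi-cell fields, richly arborized cells (astrocyte-like), and curved
(U-shaped) somas are out of scope by design.

## Segmentation

**Histogram.** Pixels with intensity exactly 0 are treated as cropped
padding, not data, and excluded. Integer images get one bin per integer level
in `[1, max]` (empty levels kept, so the elbow finder sees a uniform x-grid);
float images get 256 equal-width bins over `(0, max]`. The bin rule is an
engineering choice — the procedure is scale-free, so only the relative shape
of the curve matters.

**Mode = background.** In a single-cell field the background dominates, so
the histogram's maximal bin is taken as the background level. Ties break
toward the lower intensity, which keeps more of the tail inside the elbow
window.

**Elbow threshold.** The curve strictly right of the mode is, by
construction, decreasing and convex apart from the small cell lobe, so the
kneedle recipe is applied in its raw form: min–max normalize both axes and
return the input point maximizing `d_i = (1 − y_i) − x_i` (first index on
ties). No sensitivity smoothing and no curve-direction auto-detection — the
orientation is fixed by construction. Non-monotone inputs are logged, never
fatal. On a perfectly straight line `d ≡ 0` and the first point is returned
(documented degenerate behavior). Equality with the threshold maps to
background: "above" is read strictly.

**Pruning.** A foreground pixel survives a pass iff at least 3 of its 8
neighbors are foreground; background never turns on; updates are synchronous
(all decisions read the pre-pass mask). The 8-neighborhood and synchronous
update follow the Game-of-Life analogy; 4-connectivity and sequential updates
were the alternatives, but the 8-connected synchronous rule is the one the
analogy actually names. Pruning is monotone (never adds pixels), so iterating
reaches a fixed point in at most `n_pixels` passes. Batch runs default to 2
passes (or earlier convergence); interactive mode re-prompts after each pass,
mirroring bench use.

## Orientation

**Axis fit.** Ordinary least squares of foreground row coordinates on column
coordinates; the axis angle is `atan(slope)`. A single fit is biased toward
zero at steep angles because the cell has nonzero width (classic regression
dilution: `slope ≈ (1 − σ_v²/σ_u²)·tanθ` for axis/width spreads `σ_u, σ_v`);
for the default geometry the bias reaches ~6° at θ = 60°. `fit_axis`
therefore iterates: rotate the mask by the accumulated angle, re-fit the
residual slope, accumulate; the residual shrinks geometrically (ratio
`σ_v²/σ_u²`), so 2–4 passes reach the 0.25° stopping tolerance (10-pass cap).
The primitive remains a plain regression line, and the vertical-cell failure
mode survives: at 90° the columns carry no information about the rows, the
slope is ~0, no rotation happens, and the profile shows a single maximum —
the pipeline then refuses with "process not distinguishable", exactly the
behavior a vertically oriented cell should produce. A strictly single-column
mask raises earlier ("axis undefined").

**Rotation.** Implemented directly as an affine resampling (bilinear,
`scipy.ndimage.affine_transform`, `grid-constant` boundary) with an
explicitly controlled forward map `p' = R·p`, `R = [[cosθ, sinθ],
[−sinθ, cosθ]]` in display coordinates — positive = counterclockwise on
screen. Controlling the transform (rather than delegating to a convenience
wrapper) is what makes two things cheap and exact: the output canvas is
enlarged to hold all content, and ROI rectangles can be inverse-mapped onto
the original frame for overlays with the same matrix. Angle 0 is a bit-exact
identity; a full turn returns the input to ~1e-15. Rotated *masks* are
re-binarized at 0.5, since interpolation produces fractional values.

**Process side.** The column profile of the rotated mask is smoothed with a
5-column moving average (zero-padded edges, which also damps border peaks);
local maxima are detected with plateau handling (a flat top counts once, at
its middle sample); peaks with prominence below max(1 count, 5% of the
profile maximum) are discarded — residual noise ripple on the wide soma hump
would otherwise outrank the genuinely small process hump; survivors are
thinned to the two tallest at least 10 columns apart. If the smaller maximum
(process) sits left of the larger (soma), 180° is added to the saved angle.
The smoothing window, prominence cutoff and separation are engineering
defaults; the profile-maxima step itself has no canonical parameterization.

## ROI placement

The boundary between the compartments is the argmin of the raw profile
strictly between the two maxima (leftmost on ties — keeping more soma for
tiling); when there is no dip at all, the midpoint between the maxima is used
and logged as low-confidence. The process ROI is the exact bounding box of
foreground within the process columns — the simplest shape that covers most
of the process extent — and its (height, width) becomes the template for
everything else. Soma rectangles are placed right-to-left from the apical
foreground column, stepping by the template width, each centered vertically
on the midline row (per-column mean foreground row, rounded half-up) at its
center column; tiling stops at the basal end or the frame border, so the
count is `floor(soma extent / template width)`. The background ROI is the
template-sized window with zero foreground maximizing Chebyshev distance
from the foreground bounding box, searched exhaustively with integral-image
window sums and restricted to pixels with full support in the original frame
(the rotated canvas has empty corners that must not masquerade as
background). Forcing the background ROI to the template size keeps the
motion check's positional pixel pairing well defined.

## Motion detection and relocation

Measurement happens in rotated coordinates: each incoming frame is rotated
by the saved angle, so the saved rectangles apply directly. On every 5th
frame (configurable) the pixels of each cell ROI are paired positionally
with the background ROI's pixels and the pooled differences go into one
two-sided Wilcoxon signed-rank test — one decision per checked frame
(per-ROI p-values are logged for diagnostics). Zero differences are dropped;
n ≤ 25 uses the exact null distribution, larger n the normal approximation
with continuity correction. **Drift is declared when `p ≥ α`**: while the
cell sits under its ROIs the cell-vs-background difference is overwhelmingly
significant, and only when the ROIs have come to sample background does
significance vanish. This deliberately inverts the usual testing idiom;
smaller α therefore means *less* eager relocation. Relocation re-runs the
full first-frame chain on the current frame with the template (height,
width) forced from the previous layout — size and shape never change. If
re-segmentation fails mid-run, the stale layout is kept, the frame flagged,
and the run continues: partial data beats aborting a long recording. Pure
translation is the only drift model; rotation drift is out of scope.

Consequences worth knowing: a drift *along* the cell's axis that leaves most
ROIs on the cell will (correctly) not trip the pooled test — the signal is
still there; the check fires when the ROIs genuinely lose the cell, e.g.
perpendicular drift exceeding the cell's half-width. Under no drift and a
bright cell, the spurious-relocation probability is ≪ α because p ≈ 0 at
every check.

## Trace statistics

Background correction is a per-frame pointwise subtraction of the background
ROI trace, applied regardless of relocation flags. `dF/F₀ = (F_t − F₀)/F₀`
with `F₀` the mean over the baseline window (default: the first 10% of
frames when no stimulus timing is supplied; stimulus timing is experimental
metadata the tool cannot infer). The amplitude is the raw maximum of the
normalized trace — no implicit smoothing; an optional moving-average
pre-smoother (off by default) exists for noisy data. The width is the time
between the half-maximum crossings on the rising and falling phases, each
linearly interpolated between the bracketing samples — nearest-sample widths
are visibly biased at ~1 Hz sampling. Non-uniform time axes are supported.
A trace that never falls back below half-max after its peak gets a missing
width and a valid amplitude.

## Synthetic recordings

The generator emulates: an elliptical soma (semi-axes 60 × 24 px by
default), a rectangular process (40 × 8 px) at the apical pole, any axis
angle and chirality, intensity levels background 15 / soma 80 / process 70
(arbitrary units), additive Gaussian noise (SD 3, i.e. compartment SNR ≳ 18
per pixel), compartment-specific transients (linear rise over 5 frames, then
exponential decay with a 15-frame constant; default peaks 0.8 process / 0.5
soma, onset frame 40), integer step translations of the whole cell, and
120 frames at 1 s. A 4 px dim neck separates process from soma, standing in
for the intensity gap seen between compartments in real recordings; without
it the column profile decreases monotonically from the soma peak and no
second maximum exists for any detector to find. Transients scale the
fluorescence *above* background — `I = bg + (level − bg)(1 + dF/F₀(t))` — so
the programmed peak equals the background-corrected dF/F₀ the analysis
recovers; this also makes the recovered dF/F₀ insensitive to edge pixels
that interpolation mixes with background. The movie is a pure function of
its spec (seeded generator): same spec, same bits.

Not emulated: optical PSF blur, photobleaching, Poisson shot noise,
perfusion-correlated intensity fluctuations, neighboring stained structures,
and sub-pixel or rotational drift. Passing tests therefore demonstrate the
*algorithmic* contracts — thresholding, orientation, tiling, trigger logic,
trace math — not robustness to every optical artifact of a real microscope;
the known real-world failure modes (vertical cells, dye-flooded backgrounds,
multi-cell fields) are documented and, where reproducible, asserted as
failures, not patched over.

## Problem sizes and defaults

Test and acceptance runs use the generator's default conditions: 256 × 256
frames, 120-frame movies (40 frames for the drift experiment on a 200 × 200
thin-cell variant, where a 15 px perpendicular step at frame 20 exceeds the
cell's half-width), 50-seed threshold sweeps, a 26-case orientation sweep
(θ ∈ {−60°, …, 60°} × both chiralities), and 500–1000-check Monte-Carlo
estimates of the false-relocation rate. The interpolation loss at ROI edges
makes a rotated-frame ROI mean undershoot the true compartment level by a
few percent; comparisons against ground-truth *levels* allow for this, while
dF/F₀-based quantities are immune (the mixing factor cancels in the ratio).

## Known limitations

- Exactly one process: the profile logic assumes two maxima, no more.
- Near-vertical cells are rejected rather than guessed at; tilt the
  preparation or pass `manual_angle_deg`.
- The CSV keeps one soma-ROI column set; if a mid-run relocation changes the
  soma count, columns are padded with NaN for the epochs that lack them (the
  forced template makes count changes rare).
- The motion check detects loss of signal, not sub-pixel registration; small
  drifts that keep the cell inside its ROIs are deliberately ignored.
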