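# Methods notes

This note records the modelling assumptions, the defaults and why they
were chosen, the design decisions taken where the design was genuinely
open, and what the synthetic-data tests do and do not establish.

## Retinal input

The model is gaze-contingent: every 5 ms eye-position sample produces
a new retinal frame, even when the display frame is unchanged, because
eye movements move the image across the model retina. The frame is
shifted so the pixel under gaze sits at the centre of a square field
simulating 100°×100° of the (otherwise dark) viewing environment;
everything beyond the display is exactly black. Shifting is done at
integer working-resolution pixels, which preserves translation
covariance exactly and avoids resampling blur; the screen frame itself
is brought to the working resolution by repeated 3-tap binomial
decimation ([1,2,1]/4 per axis, then 2× subsampling) plus a bilinear
residual.

Working resolution defaults to 4 px/deg (a 400×400 field). This keeps
the smallest centre Gaussian (σ_c ≈ 0.13° for the foveal detectors)
at ≈0.5 px — marginal but acceptable for the foveal units, which play
no role in the eccentric receptive-field analyses — while keeping a
frame through the full 60-map bank affordable. The resolution is a
config field; all geometric measurements reported by the test-suite
sweeps are stable from 2 to 4 px/deg.

Colour conversion uses a generic sRGB → XYZ → LMS
(Hunt–Pointer–Estevez) chain with display gamma 2.2 and opponent axes
defined against the display white point, so achromatic input maps to
exactly (rg, by) = (0, 0). The true conversion is display-dependent;
the matrix is an argument so a monitor calibration can replace it.

## Space-variant grid

The collicular mapping is log-polar: with z = R·e^{iΦ} (hemifield-
local), u = B_u ln(|z+A|/A), v = B_v arg(z+A), A = 3°, B_u = 1.4 mm,
B_v = 1.8 mm. The analytic inverse is exact, so forward/inverse
round-trips hold to machine precision; the two hemifield sheets are
treated independently and points on the vertical meridian are assigned
to the right sheet.

Standard image processing needs a square, shift-invariant surface, so
the model grid is not the conformal sheet itself but a separable
log-polar resampling: along one hemifield's columns (fraction
s ∈ [0,1]) R = a(e^{c_u s} − 1), along rows Φ = c_v(s_row − ½). The
three scale constants are fitted by least squares — Nelder–Mead with
seeded random restarts, initial points log-uniform within a factor of
10 of the analytic guess (a = A, c_u = 4.5/B_u, c_v = 3.5/B_v) — so
that the grid's visual-space image matches the exact inverse image of
a 4.5 mm × 3.5 mm sheet grid. The fit is smooth and low-dimensional;
restarts are a formality and the default 200 used by the acceptance
script recovers the same optimum as 1000. The two hemifields split at
the centre column, mirrored, so the foveal representations abut.

Consequences worth knowing: the modelled sheet covers hemifield-local
polar angles only up to ≈ ±60° at high eccentricity (the 3.5 mm
medial–lateral extent does not reach the vertical meridian's image),
and the grid is anisotropic in the periphery (≈1.4°/px radially vs
≈0.4°/px tangentially at 40°). Both are properties of the mapping
constants, not bugs; analyses place receptive fields on or near the
horizontal meridian.

## Receptive fields and the feature bank

A DoG detector preferring disk size S with surround/centre ratio K
uses σ_c = (S/2)·√((1−K⁻²)/(4 ln K)), σ_s = K σ_c — the unique sizes
for which a centred disk of diameter S maximizes the response of
unit-mass Gaussians. S grows linearly from 0.75° at the fovea to 5°
at 40°. Detectors are realized as differences of two samples of a
lazily-computed Gaussian scale space (half-octave levels, linear
interpolation between bracketing levels, bilinear in space); the
numerical disk-diameter sweep recovers S within ~4%, the residual
coming from level quantization and the 1-px soft disk edge.

The spatio-temporal channels use a separable 3-D G2/H2 steerable
quadrature pair over a 9-frame luminance buffer. G2 is steered over
the six degree-2 monomial basis filters (plus a DC term computed from
the discrete kernel moments so a uniform input gives exactly zero);
H2 is the classic cubic-times-Gaussian least-squares fit to the exact
Hilbert transform (obtained from the Dawson function), steered over
the degree-1 and degree-3 monomials. Output is aligned to the buffer
centre, i.e. the temporal filtering is symmetric with a 4-frame
(20 ms) latency. Tuning directions: static edges at 4 orientations,
flicker along the pure-time axis, and motion at 3 speeds × 4
orientations with both temporal-slope signs giving the two opposed
directions of each pair. Default speeds 1, 4, 16 px/frame at the
working rate span slow-to-fast natural motion and are config-exposed.
Two spatial scales come from running the same bank at the working and
binomially-halved resolution.

Order of operations per low-level map: feature image in retinal space
→ per-unit space-variant DoG (K = 6.7 with |·| for luminance/colour;
K = 3.2 with half-wave rectification for the others) → opponent
subtraction for motion (both rectified signed differences per opposed
pair: 24 raw direction maps → 48) → salience competition → pooling.

The competition operator follows the four quoted steps: filter with a
large DoG (3° excitatory, 9° inhibitory Gaussian σ at the nominal
2 px/deg grid scale), add back, subtract a global-inhibition constant,
rectify. The constant is not published; the default is 2% of the
post-addback maximum (config-exposed) — small enough to preserve
isolated peaks, large enough that many equal peaks suppress each
other. Pooling replaces each grid value by the sum over a radius-3
circular neighbourhood.

### Measured receptive-field geometry

The probe-sweep measurements (also recomputed by
`scripts/acceptance.py`) give preferred disk sizes of 0.78° (fovea)
and 5.0° (40°), and activation-field half-max spans of 2.30° at 10°
and 7.41° at 40° eccentricity. The 40° span is dominated by the
pooling disc seen through the ≈1.37°/px peripheral magnification: the
half-max width of a radius-3 disc's chord profile is 5.2 px ≈ 7.1°,
with the DoG and competition skirts adding ~0.3°. The *full* response
footprint at 40° is ≈9.7°, i.e. the field is "approximately 10°"
across in the loose sense, but its half-max span is about a quarter
narrower; sensitivity checks over working resolution (2–4 px/deg),
probe diameter (0.5–2°) and sweep step leave the half-max value in
7.2–7.5°. This is reported as measured rather than adjusted.

## Saliency response and neuron fitting

High-level maps are equal-weight means within type; the saliency map
is their equal-weight mean. Per neuron, feature series collected at
the RF-centre unit are normalized leave-one-out (each test clip by the
per-feature training maximum; values above 1 are retained for
correlation analyses and only clipped when rendering maps), aligned by
maximizing mutual information over 0–150 ms delays in 5 ms steps, then
square-rooted and combined. The MI estimator uses a 16×16
equal-occupancy joint histogram; its bias is irrelevant because only
the argmax over delays is consumed, and ties break toward the smaller
delay. RF saliency is the mean over grid units inside the point-image
boundary (a 1.5 mm circle on the sheet mapped back to visual space);
"normalized sum" is read as the unit-count mean, which is equivalent
up to scale for all rank-based and tertile analyses.

## Neural analyses

Spike densities use a causal EPSP-like kernel (5 ms rise, 20 ms decay,
unit mass) for event-aligned analyses and 5 ms bins with a 50 ms
Gaussian for the fitting path. Neuron classification tests visual
(40–120 ms post-stimulus vs −80–0 ms) and motor (±25 ms vs −150 to
−50 ms) window rates with one-sided paired t-tests at α = 0.05;
visual-only → SCs, visual+motor → SCi, not visual → excluded.

Condition curves are 0–1 rescaled per neuron *jointly across that
neuron's conditions* (min/max within the 0–500 ms post-fixation
window). The per-condition alternative is available
(`norm_mode="per"`), but the joint default preserves the
between-condition amplitude differences the condition plots rely on.
Tertiles are per-neuron rank thirds with stable tie order (sizes
differ by ≤1). Epochs: 0–200 ms after fixation onset
(fixation-aligned) and −150 to −50 ms before saccade onset
(saccade-aligned, with fixations shorter than 150 ms dropped so the
window is saccade-free). Divergence marks use per-5-ms-bin paired
Wilcoxon tests with Bonferroni–Holm correction; the goal-split
high-vs-low tests are one-tailed paired t-tests Bonferroni-corrected
over the two goal conditions. Omnibus repeated-measures tests are
intentionally delegated: the pipeline's contract is the exported
per-neuron condition table, which standard routines consume.

## Synthetic data: what it emulates, and what it does not

Scripted scenes place events of every feature class (luminance and
colour disks, gratings, flicker patches, moving dots) on a grey or
textured background. Gaze alternates lognormal-duration fixations
(median 227.5 ms, log-σ 0.4457, calibrated so the central 95% of
durations spans ≈95–545 ms) with 20–40 ms raised-cosine saccades; with
probability p the next target is the strongest live event, and
event-directed fixations are shortened by 5% (the reaction-time
advantage of salient targets). Spiking is inhomogeneous Poisson:
rate = baseline + gain × saliency(t − latency), with the gain gated by
the goal-in indicator for SCi-like neurons. Defaults — baseline
10 spk/s, gain 30 spk/s, latency 50 ms, 300 analysable fixations per
neuron, goal probabilities ¼/¼/½ for in/opposite/other — are fixed
study conditions chosen to sit in the physiological range of
collicular free-viewing responses; they are not tuned per run.
Renewal-process irregularity, rate adaptation and history effects are
deliberately absent: the analyses operate on windowed means, which are
insensitive to spike-train fine structure at these counts.

Passing the recovery tests therefore shows that the *pipeline*
(segmentation, windowing, normalization, tertiles, goal splits, MI
alignment, statistics) faithfully recovers a known generative
structure of exactly the hypothesized form. It does not validate the
saliency model against real neurons, and the lightweight session
generator bypasses the video pathway entirely (the video pathway is
exercised separately by the rendered-scene tests at reduced
resolution: 1 px/deg retina, 64×64 grid, ~30 output frames — sizes
chosen so the full 60-map bank runs in seconds).

## Numerical/degenerate-input conventions

Constant series in the MI estimator return delay 0 with a degenerate
flag; zero training maxima drop that feature for that fold (logged);
flat densities normalize to zeros with a flag; mean-shift mode finding
escalates bandwidth 0.5° → 0.75° in 0.05° steps and returns a
rejection (not an exception) on a persistent tie; saccade detection
measures amplitude between velocity-threshold crossings, so slow
movement tails are excluded and a 10° step is recovered as ≈9.3°;
negative instantaneous rates are clamped at zero and counted.

## Known limitations

* The variable-resolution transform's published functional form was
  unavailable; the separable log-polar form above is this package's
  own reconstruction (constants refitted, not copied).
* No conformal mapping onto a curved SC surface; no photodiode frame
  timing; no affine/thin-plate-spline calibration (inputs are assumed
  pre-calibrated; only the mean-shift drift-correction mode finder is
  provided).
* The quadrature pair is the standard cubic polynomial approximation
  to the true Hilbert transform, leaving a few-percent phase ripple in
  the energies.
* Activation-field half-max spans in the far periphery run ≈25% below
  the design's nominal diameter (see above).
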