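# Methods

`mbkit` quantifies the structure and contractile function of micron-scale
two-dimensional cardiac muscle bundles (2DMBs): rectangular, 7:1
aspect-ratio multicellular strips of purified hPSC-derived cardiomyocytes
(nominally 308 × 45 µm) grown on micropatterned soft PDMS, contracting
uniaxially against the compliant substrate (auxotonic loading).  This
note records the models, estimators, defaults and their rationale, what
the synthetic-data generators do and do not emulate, and the numerical
choices a maintainer would want to know.

Conventions: 0-based pixel indices, `(x, y) = (column, row)`, origin at
the top-left pixel centre; micrometres, seconds and kilopascals
throughout; orientation angles are axial data on `(-90°, 90°]`.

## Displacement tracking

A template is cropped from a reference frame around each region of
interest (ROI) and matched against every frame by zero-normalized
cross-correlation (ZNCC; mean-subtracted and variance-normalized, robust
to the slow illumination drift typical of brightfield time series),
restricted to a `±search_radius` window (default 15 px).  The integer
peak is refined by a separable three-point quadratic fit, clamped to
±0.5 px.  Scores (peak ZNCC per frame) and border flags (peak pinned to
the search-window edge, indicating an undersized radius) travel with the
trace.  On band-limited texture the refinement recovers imposed subpixel
shifts to ≲0.03 px at a signal-to-noise ratio of 10, comfortably inside
the 0.1 px requirement for resolving 1% shortening at 0.5 µm/px.

The default reference is the first frame; `quiescent_auto` instead picks
the centre of the rolling window (default 25 frames) with least
frame-to-frame motion, for movies that begin mid-beat.  No drift
correction is applied by default; detrending is deliberately opt-in.

ROI pairs are auto-placed on the long axis at ±length/4 from the tissue
centre, so their separation spans the inner 50% of the bundle length —
the placement least sensitive to end effects (see the mechanics section).
The ROI is square, 10 px half-size by default; the source algorithm's ROI
dimensions are not published, so this is exposed as a parameter.

Quality control rejects a trace pair when any frame correlates below
`min_correlation` (default 0.5), when the median symmetrical-motion index
over moving frames exceeds 0.5, or when peak transverse displacement
exceeds half the peak axial displacement.  The symmetrical-motion index
is defined here as `|a_p + a_d| / (|a_p| + |a_d|)` on the long-axis
displacement components (0 = perfectly opposing contraction, 1 =
common-mode translation), evaluated only where the denominator exceeds a
0.05 µm noise floor; the original tool exports such an index without
printing its formula, so this definition is a documented surrogate.

## Shortening waveform and kinetics

The inter-ROI axial length is `L(t) = L_c + a_d(t) − a_p(t)`; the resting
length `L0` is the 90th percentile of `L(t)` (the bundle is longest at
rest, and a percentile is robust when no fully quiescent frame exists);
fractional shortening is `fs = (L0 − L)/L0`.

Beats are fs peaks with prominence ≥ 50% of the global maximum and ≥
0.3 s spacing, windowed between flanking minima, aligned on the
interpolated upstroke half-maximum crossing (more stable for
contraction-limb averaging than peak alignment), resampled onto a common
grid and merged as pointwise mean with a 95% band (±1.96 SEM).
Frequency is `(n − 1) / (span of peak times)`.

Derivatives are Savitzky–Golay (window 5 samples, order 3, at 50 fps).
A wider 7-sample window biases the second derivative by ~6% at the
quiescent-to-contraction corner of a raised-cosine beat, where the true
acceleration peak lives; window 5 keeps that bias at ~2.5% while leaving
the velocity estimates unchanged to 0.2%.  Both window and order are
arguments and are recorded in exported tables.

Extracted per merged beat (and per beat, for SDs): maximal fractional
shortening; normalized contraction/relaxation velocities (units 1/s,
geometry-independent; multiply by `L0` for µm/s) interpolated where fs
first (contraction) or last (relaxation) crosses 20/50/80% of the peak;
peak contraction acceleration; deceleration time, operationalized as the
time from contraction velocity dropping below 90% of its plateau (mean of
samples ≥ 95% of peak velocity — the "linear contractile slope") to the
fs peak; relaxation time to 90% recovery toward baseline.  The 90%
thresholds are configurable; the source publication states neither.

On the closed-form raised-cosine beat `fs = FS(1 − cos(πt/T_c))/2`
(FS = 0.05, T_c = 0.5 s, 50 fps) the pipeline reproduces
`v_20 = v_80 = 0.8·FS·π/(2T_c) = 0.1257 s⁻¹`,
`v_50 = FS·π/(2T_c) = 0.1571 s⁻¹` within 2% and the peak acceleration
`FS·π²/(2T_c²) = 0.987 s⁻²` within 5%.

Drug responses are per-tissue paired fold changes (after/before) per
parameter, with zero or undefined baselines flagged rather than dropped,
and batch summaries as mean ± SD of folds.

## Sarcomere structure

Striation-marker images (MyBP-C, α-actinin) are bandpass filtered by a
difference of Gaussians tuned to sarcomere periods (1.2–3.5 µm),
thresholded at 30% of the 99th percentile of the filtered amplitude, and
the resulting striation bands labelled as connected components with
intensity-weighted centroids.  Band fragments shorter than half the
median band extent are dropped (their centroids are displaced by the
clipping that created them).

Bands are paired into sarcomere units by nearest-neighbour search:
a valid pair is 1.2–3.5 µm apart, mutually parallel and perpendicular to
its displacement vector within 35°, and overlapping transversally by at
least 30% of the shorter band (the two z-lines of one sarcomere flank the
same myofibril; bands of neighbouring myofibrils do not overlap along the
band direction).  The angular gate is deliberately wide — the elongation
direction of a single ~1.4 µm band carries ~8–10° of estimation noise,
and a tight gate silently truncates the tails of disordered orientation
distributions, biasing σ low; cross-myofibril pairing is instead rejected
by the geometric overlap test.  Unit length is the centroid distance
(the weighted centroids of successive bands lie on the myofibril axis),
and unit orientation is the direction of the displacement vector.

Orientation statistics treat angles as axial data: deviations are
unwrapped around the circular mean of the doubled angles, so
distributions straddling ±90° are handled correctly.  The per-image
alignment metric σ is the width of a Gaussian fitted by least squares to
2°-binned counts — using the bin-integrated Gaussian (stable when σ is
comparable to the bin width) plus a flat floor term that absorbs the
sparse far-field counts from occasional mispairings.  A direct
(sample-SD) estimator is also provided; it is unbiased on clean angle
lists but outlier-sensitive on segmented images.  Fits require ≥ 30
units.  Single-image σ estimates carry 5–15% spread (unit yield varies
across the image), so σ comparisons should pool several images, as the
original study did when compiling hundreds of angle measurements per
condition.

## Myofibril density

F-actin images are resampled onto a tissue-aligned (axial × transverse)
grid, averaged axially within 10 µm windows, and background-subtracted
with a rolling minimum (12 µm span, lightly smoothed) — making the
measurement invariant to DC offsets and global intensity scaling.
Bundles are profile peaks with prominence ≥ 20% of the window's profile
range.  Each peak's width is measured at half its height above the local
background — identical to the full width at half prominence for isolated
bundles, but clipped at inter-peak minima so crowded bundles tile the
profile instead of being measured high on their shoulders (which would
systematically undercount dense tissue).  The per-window area fraction is
the summed width over the tissue width; the tissue value is the mean
over windows and the heterogeneity is their coefficient of variation.
Coverage fractions of 0.2–0.8 are recovered within 0.05 absolute on
generated layouts; the residual bias at 0.8 comes from sub-resolution
gaps whose bundles merge.  The original MyoQuant peak criteria are not
published; these defaults are declared surrogates.

## Substrate mechanics

A quasi-static linear model of the bundle–substrate system.  The tissue
is a thin membrane of axial stiffness `k_m = E_tissue · t_tissue`
(defaults 10 kPa × 8 µm) carrying an imposed contractile eigenstrain
ε₀ ∈ [0, 0.2]; the substrate is an elastomer layer of thickness `h`
(default 70 µm, E = 8 kPa, ν = 0.49) bonded to rigid glass.  The surface
responds through the scalar spectral kernel

    G(k) = 2 (1 − ν²) tanh(k h) / (E k),

which reproduces the Boussinesq half-space form `u = P(1 − ν²)/(πEr)` as
`h → ∞` (verified against the closed form to < 5%, comparing displacement
differences to a distant reference point, since the absolute 2D
point-load field has no finite DC level) and stiffens to the
layer-shear response `G → 2(1 − ν²)h/E` as `kh → 0`.  Only the axial
displacement is carried — transverse motion of a uniaxial contraction is
second order.  Membrane equilibrium `τ = ∂x[χ k_m (∂x u + ε₀)]` and the
substrate response `u = G ∗ τ` are closed into one linear system solved
matrix-free (LGMRES with FFT-applied kernel, zero-padded to suppress
periodic images; footprint indicator χ smoothed by 4 µm; relative
residual ≤ 1e−9 enforced).  Grid default 4 µm spacing with 280/120 µm
margins; halving the spacing moves the peak displacement by ~1%.

Scope and honesty: the source publication's supplemental model is not
public, and this formulation is a documented surrogate.  With the
published passive moduli (E_tissue 8–12 kPa) the load-transfer length
`E/(2(1 − ν²)k_m)⁻¹ ≈ 15 µm` is far below the bundle length, so only
~1% of the imposed eigenstrain appears as realized shortening — the
observed 5–11% shortening against the same substrate implies an active
axial stiffness well above the passive range, and the printed traction
(≈120 µN/mm) is correspondingly not reproduced here.  All conclusions
drawn from this module are therefore qualitative, and they all hold in
the model: surface displacement one buffer-gap away from the bundle edge
is < 10% of the peak under-tissue displacement at the 240 µm (long-axis)
and 80 µm (short-axis) layout gaps, and decays monotonically with gap;
the deviation of the surface field from the half-space solution falls
monotonically with layer thickness (the full curve is exposed — no
single published threshold criterion exists to reproduce); force at
fixed realized shortening varies sub-proportionally across
E_tissue ∈ [8, 12] kPa; and fs estimated from ROI pairs spanning the
inner 50% of the length is an order of magnitude less sensitive to
placement offsets than end-to-end placement.  Modulus sensitivity is by
default evaluated at the midpoint of the realized-shortening range every
modulus can reach.

## Synthetic data

The contraction generator renders band-limited Gaussian texture
(correlation length 2 µm, contrast 30 on background 100) confined to the
bundle footprint and warps it every frame with the uniform-axial-strain
map `x ← x_c + (x − x_c)/(1 − ε(t))` (the exact inverse warp) using
cubic-spline resampling, so the imposed ε(t) is analytically exact and
serves as the reference standard for tracking accuracy.  Waveform
families: raised cosine (default; 0.5 s contraction, 0.5 s relaxation at
0.4 Hz, peak FS 5% — the platform's observed scale) and a two-sigmoid
alternative.  Optional additive noise (default SD 2% of contrast),
linear drift and beat-synchronous common-mode translation.  Not
emulated: optics (PSF, shot noise), bleaching, out-of-plane motion.

The monolayer surrogate tiles the field of view with independently
beating rectangular domains (random axis, amplitude jitter CV 0.4,
random phase), each sized to fit its tile — a fixture for the
organized-vs-disorganized heterogeneity contrast, not a biophysical
monolayer model.

Structure images: striations are rendered as randomly placed ~7-sarcomere
myofibril chains (width 1.4 µm), each an independently rotated rectangle
carrying an exact cosine grating (period = sarcomere spacing) whose ends
fall on grating troughs (every rendered band is complete).  One angle is
drawn per chain from N(µ, σ); because all chains are statistically
identical apart from the angle, occlusion where chains overlap (resolved
as a maximum-intensity projection, with per-chain brightness jitter) is
independent of the drawn angle and the stored draws are an unbiased
ground-truth sample.  Areal chain density 0.55.  F-actin bundle images
are smooth-edged axial stripes (0.5 µm edge, standing in for optical
blur) with widths/gaps either given or drawn to a target coverage.

Movies in the test and acceptance suites use 0.5 µm/px over the full
330 × 100 µm field at 50 fps (structure images 0.2 µm/px) — a 3×
coarser sensor than the 40×/0.1625 µm-px acquisition, chosen so many
full-length movies fit in one session; the subpixel tracking margin at
this scale is validated explicitly.  Passing these tests demonstrates
correct recovery of known kinematics and geometry; it does not exercise
optical artifacts, focus drift, or biological waveform variability.

## What the tests do and do not show

Recovery tests compare against *realized* generator draws (the angles,
layouts and strain waveforms actually rendered), not merely requested
population parameters.  Closed-form checks (kinetics, Boussinesq) and
the exhaustive spatial-domain ZNCC oracle are independent of the code
paths they validate.  The printed reproducibility statistics (87%/73%
variability reductions, 110× yield, CV 0.13, n = 23 per group) are exact
arithmetic on published summary numbers.  Experimental means that
required living tissue (5.0% vs 0.9% shortening) are represented only by
the qualitative organized-vs-monolayer variability contrast.  The
published power figure of 205 for nonpatterned monolayers does not
follow from the CV-based formula with the printed CV of 1.58 (which
yields ≈1312); the inputs behind it are unknown, so it is not
reproduced.
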