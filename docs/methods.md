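# Methods

This note records the models, conventions, and design choices behind
`chromatrace`, in the order data flows through the package.

## Color model

All conversions assume sRGB primaries, D65 white, 2° observer — the
dominant convention for consumer cameras; no camera metadata we could rely
on states otherwise. Channel values are 8-bit-scaled reals in [0, 255];
arithmetic is floating point throughout and values are rounded only for
display. The sRGB→XYZ step uses the IEC 61966-2-1 piecewise inverse
companding and the canonical 7-decimal matrix; the Lab reference white is
taken as the image of RGB (255,255,255) under that matrix, so white maps to
L\*=100, a\*=b\*=0 exactly rather than to within matrix-rounding error.
HSV uses the standard hexcone formulas with saturation and value scaled to
[0, 255] and hue in degrees [0, 360); achromatic pixels take hue 0 by
convention, and on max-channel ties the red sector wins, then green.

ΔE is the CIE 1976 Euclidean distance in L\*a\*b\*. The more elaborate
ΔE94/ΔE2000 variants are deliberately out of scope: for *differences over
time of the same scene* the 1976 form is monotone enough, and it keeps the
metric a true metric (the property tests rely on the triangle inequality).
As a rough reading guide: ΔE < 1 is imperceptible and below the
instrumental noise floor, ~2–10 an early-stage shift, above ~50 a complete
colorimetric transformation.

`rgb_sum_response` = 765 − (R+G+B) is kept as a secondary scalar for
fade-to-colorless chemistry where brightness loss, not hue, carries the
signal.

## Regions of interest

Raster conventions: 0-based indices, row-major, origin top-left, half-open
rectangles. Grid partitions assign remainder rows/columns to the last
cells — the simplest deterministic rule; cell masks are disjoint and their
union is exactly the parent, which the tests verify through the
mass-balance identity Σ(cell mean × cell count) = parent mean × count.
Well membership uses pixel-center Euclidean distance ≤ radius; overlapping
wells warn rather than fail because tightly pitched plates are legitimate.
Non-rectangular hand-drawn ROIs and automatic well detection are
non-goals.

## Trace analysis

The ΔE reference frame defaults to the first sample but is a parameter:
the trace is known to be sensitive to this choice, and re-referencing is
sometimes the right call (e.g. after an induction period). Resampling a
trace keeps every k-th sample; if thinning drops the reference frame, ΔE
is recomputed against the nearest retained sample — a ΔE series is a set
of distances, not coordinates, so it cannot be re-anchored by subtraction.

Rate of change is estimated by centered finite differences on a
boxcar-smoothed series. Even smoothing windows are rounded up to the next
odd length so the kernel stays centered; an even kernel would bias every
detected time by half a sample spacing. The plateau detector reports the
earliest time the rate stays below ε for `min_run` consecutive windows
*and* the accumulated ΔE has reached `min_excursion` (default 3 ΔE units,
just above the ~2-unit noise floor) — without the guard, the unreacted
start of every trace would qualify. No universal ε is claimed; end-point
wall-times depend on it and it is an explicit parameter.

Rate fits use `scipy.optimize.curve_fit` with a deterministic initializer
(A₀ = max ΔE, k₀ from the time to half-max), bounds k > 0, A ≥ 0. The
second-order form A·kt/(1+kt) fixes the initial concentration scale c₀ to
1 because only the product k·c₀ is identifiable from a unitless color
trace; the reported k must be read in those units. Non-convergence is
returned as a flagged summary, never an exception, so plate screens don't
abort on one dead well.

Mutual information uses the equal-width histogram plug-in estimator (in
nats) — simple, deterministic, and adequate at the n ≳ 10³ sample sizes of
a video trace; its positive bias is about (bins−1)²/2n nats, which the
independence test accounts for. k-NN estimators (Kraskov-style) are a
known better-converging alternative and a natural extension. Offline
measurements are paired to the nearest-in-time sample (ties to the
earlier), with out-of-span points dropped with a warning rather than
extrapolated.

## Spatial mixing metrics

Binarization is an inclusive per-channel RGB band test. *Contact* counts
4-adjacent differing pairs, each edge once, borders contributing nothing —
the standard pixel-edge perimeter estimator (marching-squares contour
length is a documented non-choice). It is invariant under mask complement
and reported both raw and normalized by the total adjacent-pair count so
ROIs of different sizes can be compared.

GLCM: gray levels come from the Rec. 601 luma (0.299R + 0.587G + 0.114B)
binned into G equal-width levels over [0, 255] (255 in the top level).
Defaults G = 16, offset (1, 1) (one row down, one column right), symmetric
accumulation, single offset — angular averaging over multiple offsets is
out of scope. Entropy is reported in bits. Homogeneity uses the
inverse-difference weight 1/(1+|i−j|); the inverse-difference-moment
weight 1/(1+(i−j)²) is available as an option. ASM ∈ (0,1], entropy ≤
log₂G², and all three features are invariant to gray-level reversal —
texture characterizes spatial structure, not absolute gray level, which is
why uniform white and uniform black score identically.

## Synthetic data

The generators define the conditions the tests and the acceptance script
run under; they are fixtures with physics, not dials.

**Reaction** (`gen_reaction`): a uniform vessel whose color interpolates
*linearly in L\*a\*b\** between the start and end colors, following
first-order 1−e^(−kt) or second-order kt/(1+kt) progress. Lab-linear
interpolation makes the noiseless ΔE trace exactly the endpoint color
difference times the progress curve, so round-trip rate recovery is exact
by construction — the deliberate design for a kinetic ground-truth
fixture (an RGB-linear blend bends the Lab path and distorts the apparent
order). Camera noise is i.i.d. Gaussian per channel per pixel, clipped to
[0, 255] — the simplest sensor stand-in; no vignetting, rolling shutter,
or codec artifacts are modelled, so passing tests say nothing about those
effects on real footage.

**Mixing** (`gen_mixing`): a scalar concentration field on a 64×64 lattice
(default), evolved by operator splitting: semi-Lagrangian rotation about
the grid center with angular displacement `swirl`·exp(−(r/r₀)²) per step
(a differential vortex — fast core, still walls — which shears the blob
into a spiral filament, the mechanism that makes Contact rise before it
decays), then one explicit 5-point diffusion step (stability bound
D ≤ 0.25; reflecting boundaries make the diffusion step exactly
mass-conserving and variance-contracting, which is what the conservation
test checks — bilinear advection resampling is not exactly conservative
and is excluded from that check by setting swirl to 0). The initial blob
is Gaussian-edged (σ = radius/2): injected dye is never a perfectly sharp
disc, and a sharp disc's instantly diffusing halo would put the maximum
rate of mean-color change at t = 0 instead of mid-mixing. Rendering blends
solvent toward dye color by 1−e^(−α·c) (Beer–Lambert-style saturation,
α = 4): with a linear blend and conserved mass the spatial mean color
would be constant in time and "time of maximum ΔE rate" undefined.
Defaults (D = 0.05, swirl = 0.6 rad/step, 300 steps at 5 fps) run the
clip through complete homogenization of the thresholded interface; weak
large-wavelength gradients decay on the much slower D·(π/L)² timescale
and may persist, which is why the homogenization test checks the
interface, not the raw variance. The entropy peak and the maximum-ΔE-rate
time are expected to be approximately, not exactly, coincident; the test
allows 20% of the clip duration.

**Plate** (`gen_plate`): circular wells on a regular lattice over a dark
background, each well running its own Lab-linear first-order program with
a per-well k (default log-spaced 0.01–0.1 s⁻¹ across the plate), plus the
matching ROISet. Shrinking the well radius reduces pixels per well and
hence signal-to-noise — the property test on radius monotonicity exists
because that trade-off is the practical limit of plate screening by
camera.

All generators are bit-reproducible from their spec; seeds are explicit
fields, never global state.

## Pipeline and I/O

Channel order is fixed to RGB at the ingestion boundary regardless of
decoder convention. Stills are written as PNG only — lossless, so
write/read round trips are pixel-identical and codec color shifts cannot
contaminate fixtures. Timestamps come from frame index / fps (container
frame rate for videos, configured fps for stills). CSV output uses 6
significant digits, and identical configs produce byte-identical CSVs;
every run writes a provenance log (config echo, version, frame count,
seed) sufficient to re-run it.

## Problem sizes

The test suite and acceptance script use desk-scale problems chosen to
exercise every code path with comfortable statistics: 600-sample kinetic
traces (50 noisy replicates), 10⁴-sample mutual-information calibrations,
a 64×64 × 301-frame mixing clip, and a 6-well plate — sizes at which the
statistical properties under test (median recovery error, estimator bias,
series shape) are already stable.

## Known limitations

ΔE collapses a 3-D color trajectory to a scalar and cannot distinguish a
direct chromatic shift from a multi-stage path that bends or reverses in
Lab space; it is also sensitive to the reference frame. Only first- and
second-order progress models are fitted — no model discovery. The mixing
simulation is a caricature of stirred-tank hydrodynamics (no turbulence
spectrum, no 3-D projection effects). Inter-device color correction,
perspective correction, and vessel tracking are out of scope, as are
camera-hardware effects beyond additive Gaussian noise.
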