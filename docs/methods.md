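# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `padkin`, in the order the analysis runs them.

## Channel hydrodynamics and force calibration

The axial velocity in a rectangular duct is the classical odd-harmonic
series; the pressure-flow relation carries the finite-width bracket
`1 − Σ 192h/(n⁵π⁵w)·tanh(nπw/2h)`.  Series are summed over odd *n* until a
term contributes less than 1e−12 of the running total, with a hard cap at
n = 9999.  Hyperbolic-function arguments above 700 switch to their
asymptotic limits (`tanh → 1`, `cosh(a)/cosh(b) → exp(a−b)`), so extreme
aspect ratios evaluate without overflow.  The cross-section integral of the
profile reproduces the imposed flow rate to better than 0.1% for
1 ≤ w/h ≤ 100 (validated against Gauss–Legendre quadrature).

Real chambers have a lid that sags ~10–20 µm toward the side walls,
modeled as `h(y) = h0 + αy + βy²`.  At a fixed flow rate this raises the
center velocity, hence the force, by `C1 = Δp_par(h_eff)/Δp(h0)`, with the
cubic-mean height `h_eff = ((1/w)∫h(y)³ dy)^{1/3}` evaluated in closed form
(checked against numerical quadrature at 1e−10 relative).  The default is
the wide-channel simplification `C1 = h0³/h_eff³`, which is what the
calibration workflow applies in practice; the exact pressure-ratio form is
available via `correction_c1(..., exact=True)` and agrees within 1% for
w/h0 > 20.  A typical chamber (h0 = 165 µm, h_eff ≈ 155 µm) gives C1 ≈ 1.2.

The drag on a wall-attached sphere is Stokes drag at the sphere-center
height of the wide-channel profile times C1 and the wall-correction
constant C2 = 1.618, adopted from a resolved-particle lattice-Boltzmann
study and treated as configuration (the flow solver is deliberately not
part of this package).  F(Q) is exactly linear, so the flow rate for a
target force is a closed-form inversion, not a root find.  All internals
are SI; the config layer converts from mm/µm/µL·s⁻¹ on load.

## Detection, localization, linking

Detection is normalized cross-correlation against a particle template
(synthetic Gaussian disk by default; an empirical reference image can be
supplied).  Correlation maxima above 0.5 of the frame maximum — and above
an absolute floor of 0.4, which keeps particle-free noise frames empty —
are refined by a 2D Gaussian least-squares fit in an 11×11 px window.
Fits that leave the window or collapse to an implausible width fall back
to the integer peak.  Duplicates within one template radius are merged.
Because normalized correlation is contrast-blind, smooth cell texture can
resemble the template; the fitted amplitude and peak sharpness are exposed
on every detection so downstream code can separate beads from texture.

Radial-symmetry localization (for the engulfment movies) solves the 2×2
least-squares problem for the point closest to all gradient lines.  Pixels
below the 90th percentile of squared gradient magnitude are dropped (flat
background carries no radial information), gradients are computed on a
σ = 1 px smoothed copy, and weights decay with distance to the
gradient-magnitude centroid.  The estimate is exact for symmetric
noise-free input; Monte-Carlo RMSE is ≈ 0.05 px at SNR 15.

Linking is greedy nearest-neighbor with a per-transition step limit
(default 3 µm/frame) and optional gap bridging — adequate because the beads
are slow (D ≈ 0.2 µm²/s at 1 Hz) and sparse.  No global assignment, motion
model, or drift correction is attempted.

## Two-state binding kinetics

Speeds are frame-to-frame displacement magnitudes, median-filtered over a
symmetric ±15 s window (31 frames at 1 Hz) with shrinking windows at the
ends.  Bound means filtered speed < 0.25 µm/s; that threshold sits in the
valley between the localization-noise mode of immobile particles
(~0.08 µm/s) and the diffusive mode (~0.8 µm/s), where the number of
state changes is minimal.  Four QC rules remove tracking artifacts: tracks
must start during sedimentation, be unbound at their first frame, persist
to within 5 s of the shear phase, and never spend > 30 s within 4.5 µm of
another particle.

Rates are occupancy ratios pooled per measurement: k_on = N_binding /
T_unbound and k_off = N_unbinding / T_bound, split by near-cell vs
near-coverslip context.  Bookkeeping conventions (chosen here; any
convention consistent with the definitions is defensible):

* each inter-frame interval contributes dt to the state and context of its
  leading frame; an event's context is that of the post-transition frame;
* irreversible bindings count toward N_binding and their bound time toward
  T_bound, but contribute no unbinding event;
* with this convention N/T estimates the per-frame transition hazard
  p/dt = (1 − e^{−k·dt})/dt *exactly*.  For frame-sampled data this is what
  any occupancy-ratio estimator converges to; `continuous_rate` inverts the
  transform (k = −ln(1 − k̂·dt)/dt) and is used whenever an estimate is
  compared against a continuous-time generator rate.  At the rates these
  assays produce (k·dt ≤ 0.025) the distinction is below ~1% and the raw
  ratio is reported.  A half-frame ("trapezoidal") occupancy convention was
  evaluated and rejected: at stationarity the transition in- and outflow
  half-frames cancel, so it does not reduce the sampling bias.

A binding is irreversible when it starts ≥ 200 s before the end of
sedimentation and no unbinding follows before that end.  The reported
fraction divides by all binding events (the assay's definition); a
`denominator="eligible"` variant divides only by bindings old enough to
qualify, which is the correct normalization when validating a configured
per-binding irreversibility probability.  The remaining fraction is the
ratio of bound-particle counts 30 s after force onset to counts at onset;
values slightly above 1 are legitimate counting fluctuations.  Replication
statistics (mean ± SEM) are always computed across measurements, never
across particles.

## Morphometrics

Segmentation: median filter (disk radius 3 px) → central-difference
gradient magnitude → binarize at a fraction of the maximum (default 0.33,
working range 0.30–0.35) → dilate (disk 5 px) → fill holes → erode →
remove border-touching components and components below a minimum
equivalent diameter (default 1 µm, converted through the pixel size).  The
smoothing plus dilation/erosion suppresses boundary detail below roughly
10 nm at SEM pixel sizes, which is intended: the roughness metric should
reflect µm-scale morphology, not pixel noise.

Descriptors: equivalent diameter from area; eccentricity as the
major/minor axis ratio of the moment-equivalent ellipse (1 = sphere);
roughness as perimeter over the equal-area circle's perimeter.  The
perimeter estimator is the 4-direction Crofton formula, chosen because it
is nearly unbiased on the smooth, round outlines this pipeline produces
(−0.5% on rasterized disks); it undershoots axis-aligned polygons by ~5%,
so a chain-length estimator is selectable where that bias matters.  The
choice is fixed per analysis because roughness inherits it directly.
Tests use a 20.8 nm/px grid — ten times the instrument's 2.08 nm/px — so a
3 µm particle spans ~150 px instead of ~1500; the pipeline is
scale-invariant apart from the pixel-size conversion.

## Internalization

The cell mask is the product of (a) a DIC local-contrast mask — intensity
range (max − min) within a radius-3 px circular window above a threshold
T_DIC — and (b) a thresholded maximum projection of the fluorescence
stack.  Both thresholds are required configuration (they were tuned by eye
in the assay this emulates); an Otsu suggestion is easy to add on top.
Post-processing fills holes ≤ 40 µm², smooths with a Gaussian (3 px) and
re-binarizes at 0.5, and drops objects < 80 µm².  The covered area may be
extrapolated from the imaged ROI to a configurable target area; the target
is configuration because the assay's nominal coverslip area is not
something this package should hard-code.

Interaction counts are standardized for coverslip-to-coverslip variation:
PCI_stand = PCI · (N_cells,std / (A_CS/A_singleCell)) · (N_particles,std /
N_particles,CS) — exactly linear in the raw count and inversely
proportional to the particle load.  Conditional internalization
probability = internalized / interactions; absolute = conditional ×
remaining fraction; the absolute probability's uncertainty combines the
two relative SEMs in quadrature.  Whether a particle is internalized
(fully surrounded by actin in the confocal stack) enters as a per-particle
boolean — automated 3D surround detection is out of scope.

Engulfment dynamics use ring ROIs around each tracked particle: the mean
intensity in [r−3, r+2] px divided by the mean in [r+9, r+12] px, per
frame and channel.  The ratio of a uniform frame is exactly 1 and global
multiplicative drift (photobleaching, lamp flicker) cancels.  When the
particle radius is not given it is chosen from [0.5, 1.5]× the nominal
radius to maximize (ring − reference)/reference-SD.  The LifeAct peak is
the trace maximum if it exceeds a threshold; the LysoTracker onset is the
first sustained crossing (≥ 5 frames) of an onset threshold.  Both
thresholds are configuration — the underlying signals have no canonical
absolute scale.  Particles with no detected onset are excluded from the
ordering fraction's denominator.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the estimators consume,
under the acquisition conditions of the assay: 1 Hz frames, a 600 s
sedimentation phase, a 30 s shear phase, ~3 µm beads, and ensembles of
~500 particles per measurement.  Defaults: D = 0.22 µm²/s (Stokes–Einstein
for a 1.5 µm-radius sphere in 37 °C water), 0.05 µm localization noise,
rates within the experimentally observed decades (k_on ~ 8×10⁻⁴–2.5×10⁻²
s⁻¹, k_off ~ 1.5×10⁻⁴–2.5×10⁻² s⁻¹).  Binding switches with per-frame
probabilities 1 − e^{−k·dt} (the exact discretization of the two-state
chain); a Bernoulli draw at each binding makes the bond permanent with
probability p_irreversible; the shear phase detaches each reversible bond
with probability p_detach while permanent bonds survive.  Context is
geometric: disk-shaped "cell" regions in the field.  Movies are Gaussian
PSFs over smooth textured blobs with Gaussian read noise; SEM images are
supersampled anti-aliased ellipses with low-order Fourier boundary
perturbations; engulfment events are ring brightenings (Gaussian-in-time
actin, sigmoidal acidification).

Deliberate simplifications: sedimentation appears only as staggered track
starts (no vertical dynamics); bound particles are perfectly immobile;
there is no hydrodynamic interaction between particles, no drift, no
photobleaching beyond what the ring normalization cancels, and cell
texture is statistically stationary rather than cell-shaped.  Passing
tests therefore demonstrate that the estimators recover known truth under
the assay's sampling conditions — not that detection or classification
would reach the same accuracy on real DIC movies, where texture, debris
and focus drift are harsher.

A six-type synthetic bead panel (`pipeline.default_panel`) spans the
measured ζ-potential range (−93 to −5 mV) with generator truths encoding
the observed monotone trend (more negative ζ → faster binding, slower
release, more irreversible bonds, better shear survival).  Per-binding
irreversibility probabilities were set so that the standing bound
population at shear start — which irreversible bonds dominate after 600 s
— spans remaining fractions from a few percent to ~100%, matching the
dynamic range the assay reports.  Conditional internalization truths are
deliberately uncorrelated with ζ, mirroring the empirical finding that
only the absolute probability tracks the ζ-potential.

## Problem sizes and determinism

Every stochastic step takes a seed or `numpy` Generator; a fixed seed
reproduces all outputs bit-for-bit.  Validation ensembles use 500
particles × 600 s per rate combination (the assay's own scale — ~550
particles per measurement), 100-event engulfment ensembles, and
60–100-draw localization Monte Carlos; these sizes keep the full test
suite under half a minute while leaving the statistical checks
well-powered (3-SE windows, binomial CIs).

## Known limitations

* C2 is a constant for one particle size and wall distance; no
  lubrication-theory dependence on gap or radius is modeled.
* The occupancy-ratio rates are biased for dwell times approaching the
  frame interval (see `continuous_rate`); dwell-time distribution fitting
  or survival analysis is explicitly out of scope.
* The baseline context classifier is a texture-energy heuristic intended
  for synthetic benchmarks and as an interface reference; real data would
  use the pluggable external-model hook.
* Group-difference testing (Kruskal–Wallis and post hocs) is delegated to
  standard statistical packages; only Pearson correlation and SEM
  aggregation are first-class here.
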