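# Methods

## Model

The walker is reduced to a single stance leg of length L (thigh l1 plus
shank-to-rocker segment l2, l1 + l2 = L) standing on a circular-arc foot
of radius r, with the centre of mass (COM) at the hip (the intersection
of the two model legs) and a massless swing leg.  Rolling the arc extends
the effective leg: the ratio of virtual to real leg is the roll factor,
ρ_G = 1/(1 − r/L) in the 1-DOF rocker model.  Adding a knee gives the
2-DOF form used throughout, in which ρ is identified from spatiotemporal
data alone, ρ = 1 + f/(Sl − f), with f the anatomical foot length and Sl
the step length.  The closed forms for step length, cadence, speed and
vertical COM excursion follow from the small-angle kinematics of this
model and are implemented literally (module `arcgait.model`):

* the cadence expression is dimensionally steps **per second**
  ((1 − 2ξ)√(2 − ρ)/T₀); since cadence is conventionally quoted per
  minute, the package computes in s⁻¹ and exposes both (`cadence_per_second`,
  `cadence` = ×60);
* the double-support factor (1 − 2ξ) multiplies the whole cadence and
  speed expressions (not the square-root argument) — only this grouping
  gives zero cadence when double support fills the cycle (ξ → 0.5) and
  ~100 steps/min at normal ρ;
* the inherent period is T₀ = √(L/g) with **no 2π factor**, and the swing
  period is T = 1/ω with ω = √((2 − ρ) g/L); both are this model's
  conventions and are kept as printed rather than "corrected" to the
  2π-harmonic form.

Domain policy: the pendular quantities raise `DomainError` outside
1 < ρ < 2 (ρ = 1 is admitted for ω and T, where the model degenerates to
the inherent pendulum) instead of returning NaN/complex.  Only the
recognition layer consumes out-of-band ρ values.  The map ρ(Sl) has a
pole at Sl = f; |Sl − f| < 1e-12 m raises `SingularStepError`, which the
step pipeline converts to a flagged record and the classifier maps to the
small-broken-step style (a vanishing step).

## Single-support dynamics

Linearizing the moment balance about the rocker's ground contact point
gives θ̈ = (g/L)(2 − ρ)θ.  For ρ < 2 the coefficient is **positive**: the
upright equilibrium is hyperbolic and the solutions are cosh/sinh, the
standard falling behaviour of an inverted pendulum through mid-stance.
The model nonetheless names ω = √((g/L)(2 − ρ)) a natural frequency and
builds the swing period from it; we implement the equation of motion
literally and document the tension rather than flipping the sign.  The
integrator is fixed-step RK4 (default dt = 1e-3 s) — the ODE is linear
and smooth, and the independent cosh/sinh closed form gives a crisp test
oracle (observed convergence order ≈ 4; the convergence study uses
dt ∈ {0.02, 0.01, 0.005} s, where the discretization error is far above
the ~1e-13 rad roundoff floor that the dt = 1e-3 run already reaches).

Geometry: COM height is the exact two-link expression
h = l1·cosθ + (l2 − r)·cos(θ − β) + r, evaluated as a droop
L − h = l1(1 − cosθ) + (l2 − r)(1 − cos(θ − β)) so the upright case is
exactly zero in floating point.  The hip-to-contact distance Liv is not
fixed by the model's published description; the default is Liv = L − r
(contact one rocker radius below the ankle-rocker centre line near
upright), overridable.  In the linearized contact relation we adopt the
grouping θr′ = (Lρ/Liv)θr + ((l2 − r)/Liv)βr.  The knee angle β is held
at a configurable constant (default 0) during single support, as the
model treats it as small there.  A moment-balance residual checker,
m(g + ÿ)(x − xa) − m·ẍ·(y − ya), is provided as a qualitative diagnostic:
the linearization drops O(θ) terms that do not cancel, so the residual is
*not* numerically zero; tests assert only its linear scaling with
amplitude.

Consistency of the two excursion formulas: the closed form
Δh = ρf²/(8L(ρ − 1)²) is the small-angle limit of the two-link droop when
(i) the half-step angle is taken in its small-angle form θ = Sl/(2L) and
(ii) the rocker radius is tied to ρ through the 1-DOF relation
r = L(1 − 1/ρ).  Under those conventions the two agree within 5% (worst
~3.1%) over ρ ∈ [1.4, 1.8] and f/L ∈ [0.2, 0.35]; with θ = arcsin(Sl/2L)
the agreement degrades to ~12% at the long-step corner, which is why the
small-angle convention is the package's definition of the half-step
angle.

## Measurement pipeline

Heel strike is operationalized as a local minimum of the vertical
heel-marker coordinate, gated by a minimum inter-event separation
(default 0.4 s) and prominence (default 3 mm) so noise wiggles and quiet
standing do not register; consecutive same-side strikes bound a gait
cycle, gated to a plausible duration of [0.4, 3.0] s.  The stride is the
forward heel displacement across a cycle (overground) or belt speed ×
cycle time (treadmill — forward displacement is degenerate there), the
step length is stride/2, the step duration cycle/2, and ρ follows from
Eq. ρ = 1 + f/(Sl − f) per step.  Cadence by counting divides the number
of steps in a window by the window length (one detected single-side cycle
= two steps).

Smoothing: the named quintic-spline filter of gait practice is not
re-implemented bit-exactly (its parameters are not published for this
protocol); the default smoother is a zero-phase 4th-order Butterworth
low-pass at 6 Hz — the customary kinematic cutoff at gait frequencies —
with a GCV smoothing-spline alternative.  Both preserve constants and
introduce no phase lag (asserted by tests).

Joint-angle landmarks: cycles are resampled to a fixed 101-point 0–100%
grid and divided into the seven classical phases (defaults LR 0–10,
MSt 10–30, TSt 30–50, PSw 50–60, ISw 60–73, MSw 73–87, TSw 87–100%,
configurable).  Hip extremes are global; the stance knee peak Kmax1 is
the largest *interior* local maximum before pre-swing (a plain windowed
maximum would grab the flexion ramp rising toward the swing peak at the
window's edge), and Kmax2 is the global knee maximum.  The two knee-peak
names are assigned stance-first by package convention, since published
descriptions of the pair are not fully consistent.  The four ankle
landmarks are windowed extrema: Amax1 in a small initial-contact window
(0–3%), Amin1 over LR+MSt, Amax2 over TSt, Amin2 over PSw+ISw — the
heel-, ankle-, forefoot- and toe-rocker events.  Ties break to the
earliest % cycle; flat curves flag the cycle degenerate, and degenerate
cycles are dropped from landmark-vs-ρ tables.

## Synthetic data

The generator emulates the validation protocols (100 steps per walking
pattern, 100 Hz capture) with full ground truth, and its defaults are the
study conditions:

* style-conditional draws: normal walking ρ ~ U(1.4, 1.8) (the observed
  normal range), inefficient ρ ~ U(2.1, 3.5), small broken steps
  Sl ~ U(0.3f, 0.9f);
* step duration = 1/NC(ρ) in the pendular band; outside it a slow-cadence
  draw U(0.9, 1.4) s per step, chosen so two-step cycle durations stay
  inside the detector's plausibility gate;
* heel trajectories: consecutive steps are paired into left-foot cycles
  (an odd trailing step is dropped and recorded in the manifest); the
  vertical coordinate is a raised-cosine arc whose minimum falls exactly
  on each strike, and the forward coordinate follows a cycloid-like
  profile with zero velocity at the strikes — as at real heel contact —
  which makes stride estimates first-order insensitive to strike-timing
  jitter.  Cycle durations are snapped to whole samples so planted events
  lie exactly on the grid.  Treadmill mode subtracts the per-cycle belt
  displacement, bounding the marker by stride/(2π);
* joint angles: each landmark value is linear in the cycle's ρ
  (configurable slope/intercept maps; defaults follow the qualitative
  trends of normal walking) plus optional Gaussian noise, threaded by a
  shape-preserving monotone cubic through the canonical phase locations,
  so windowed extraction recovers planted values exactly at zero noise.
  The maps describe the normal band; for out-of-band styles the curves
  are generated at ρ clamped to [1.1, 1.9] (stored alongside the true ρ
  in the manifest).  The hip flexion peak is planted at 88% (terminal
  swing) — physiological, and necessary because a landmark planted
  exactly on the cycle boundary would be overwritten by the neighbouring
  cycle's sample;
* determinism: all draws flow through `numpy.random.default_rng` seeded
  from the spec; identical spec + seed give identical bundles.

What the generator does **not** emulate: soft-tissue artefact and marker
occlusion, left/right asymmetry, stride-to-stride correlation (draws are
i.i.d.), double-support kinematics, and full-body marker sets.  Passing
closure tests therefore demonstrate the pipeline's correctness under the
model's own assumptions, not robustness to every artefact of real motion
capture.

## Recognition and statistics

Classification is the threshold rule on per-step ρ: ρ ≤ 1 small broken
step, 1 < ρ < 2 inverted-pendulum (normal), ρ ≥ 2 inefficient — band
edges closed on the abnormal side ("between 1 and 2" read as open).
Accuracy per style is the share of that style's steps recognized as it.
The error-rate denominator is ambiguous in the published description;
the default is steps of *other* true styles (a false-positive rate), with
a false-discovery-proportion option (`error_rate_denominator="predicted"`).
Per-subject accuracies are summarized as arithmetic means to two
decimals.

Line fits are ordinary least squares with intercept, R² = 1 − RSS/TSS
(so R² equals the squared Pearson correlation of the data with the fitted
values; a constant response reports R² = 0 with a warning rather than
NaN; a constant predictor is a degenerate design and raises).  A
case-resampling percentile bootstrap provides slope CIs.  Model-vs-
measurement comparison pairs each in-band step's model predictions
(Sl, NC, V, Δh at the step's ρ) with the measured values and reports
Pearson r per parameter, excluding out-of-band records with a count.
Curve comparisons use the closed forms with the profile fixed; no free
parameters are fitted unless explicitly requested.

## Problem sizes and tolerances

Default test and acceptance runs use 100 steps per condition (the
protocol's per-pattern count), 10 000 random tuples for the algebraic
identity (tolerance 1e-10 relative), 1e-6 rad for the dynamics oracle at
dt = 1e-3 s, 5% for the excursion cross-check, 0.02 for the mean
absolute ρ-recovery error at 2 mm marker noise, 95% per-style accuracy at
1 cm step-length noise, and 1e-10/1e-12 for the regression identities.
The whole suite runs in a few seconds on one CPU.

## Known limitations

* The moment-balance residual is diagnostic only (see above); the package
  does not re-derive the linearized equation of motion from first
  principles.
* No toe-off detection from markers; phases are windowed by % cycle.
* No kinetics (torques, ground reaction forces, metabolic cost) and no
  double-support or step-to-step transition dynamics.
* The treadmill stride fallback requires a configured belt speed; it is
  not estimated from the data.
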