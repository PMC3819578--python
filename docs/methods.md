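# Methods

## Models

### Tissue kinetics

All simulated tissue curves follow a one-tissue compartment model with a
vascular contribution. The total measured signal is

    M(t) = K Int[0,t] ca + (K1 - K) Int[0,t] ca(s) e^(-k2 (t-s)) ds + Vo ca(t)

with K1 the unidirectional clearance (mL g^-1 min^-1), k2 the efflux rate of
the exchangeable pool (min^-1), Vo the vascular dynamic volume (mL/cm^3), and
K an optional net irreversible (trapping) clearance, zero by default. With
K = 0 this is the standard reversible one-tissue model; the precursor-pool
dynamic volume is Vg = (K1 - K)/k2. The convolution is evaluated exactly for
a piecewise-linear input (per-interval analytic integration with expm1-stable
algebra), so constant-input closed forms are reproduced to machine precision.
Frame values are exact time-averages of M over each frame; optional noise is
zero-mean Gaussian per frame with SD = noise_scale * sqrt(M / frame
duration), mimicking count statistics. All randomness flows through
`numpy.random.default_rng` seeds and is bit-reproducible.

### Graphical (Patlak) analysis

The measured pair (m(T), ca(t)) is transformed into V(T) = m(T)/ca(T) and
Theta(T) = Int[0,T] ca / ca(T). The plasma integral is trapezoidal on the
plasma sampling grid; ca and its running integral are linearly interpolated
to frame mid-times (the within-frame convention for frame-averaged data at
this temporal resolution). Three nested regressions are provided: the full
four-parameter transfer model, its K = 0 (reversible) reduction, and the
early-time line. Nonlinear fits are bounded below at zero, start from a
linear fit over the earliest minute of the window (Vg starts at twice the
observed maximum of V), and restart from three jittered initial values on
non-convergence; standard errors come from the Jacobian at the solution. The
full model is internally parameterized as (K, K1 - K, Vg, Vo) so the
constraint K <= K1 is structural. The model-order decision fixes K at zero
when |K| < 2 SE(K) — a two-sigma operationalization of "not significantly
different from zero".

The fitting window is an interval of *real circulation time* (default 0-4
min, closed, applied to frame mid-times), not of normalized time; with the
default input function 4 min of circulation corresponds to Theta ~ 10 min.
The window exists because circulating metabolites that do not enter brain
depress V(T) at later times; within the window the default analysis uses
total plasma activity (a parent-fraction correction is available by flag,
see below).

### Cerebral blood flow

For the freely diffusible water tracer the one-tissue model integrates to an
exact linear relation M(T) = (K1 + k2 V0) Int ca - k2 Int M + V0 ca(T), so
the three coefficients are estimable per region by Lawson-Hanson non-negative
least squares (scipy's active-set implementation) and F = K1 = p1 - p2 p3.
Because the observed response is a frame average, all design columns are
likewise frame-averaged (blood terms by trapezoid on the refined blood grid;
the tissue integral from the frame averages themselves). Water is treated as
fully extracted (F identified with the water clearance); the V0 column can
be dropped by flag. Nonnegativity of every returned parameter is a hard
constraint of the solver.

### Transfer metrics

extraction_fraction, ps_product and clearance_from_ps implement the
Crone-Renkin relations as exact algebraic inverses (log1p/expm1 forms;
round-trip identity holds to 1e-12 relative). K1 = F (extraction exactly 1)
is a domain error rather than PS = infinity: finite-precision safety, and
measured data never reach it. Inputs must share units; nothing is rescaled
implicitly. Corollary used in the interpretation of results: if PS <= F then
E <= 1 - 1/e ~ 0.63.

## Synthetic study design

The generator emulates a two-tracer, two-group design: a 3-min water session
(21 equal frames) and a 90-min PiB session (30 graded frames: 6x10 s,
6x20 s, 6x60 s, 3x2 min, 3x5 min, 6x10 min — only the totals are fixed by
the design; the grading is a standard convention). The arterial input is a
gamma-variate bolus A (t/tp)^a e^(a(1-t/tp)) plus a saturating plateau
P (1 - e^(-t/tau)) with P = 0.10 A, reproducing the triphasic PiB plasma
course: peak within the first minute, decline to a plateau at ~10% of peak
by 4 min. Defaults: tp = 0.45 min, A = 40 kBq/mL, a = 3, tau = 1.5 min. The
parent (unmetabolized) fraction follows the Hill form
f(t) = 1/(1 + (t/7.2)^3.8), calibrated so metabolite-corrected plasma
activity is below 3% of the plasma peak at 10 min and ~1% at 15 min. The
water input is a sharper bolus with a recirculation plateau and no
metabolite phase.

Tissue uptake of PiB is driven by the *parent-corrected* plasma curve (only
intact tracer crosses the barrier); water uptake by whole-blood activity.
Per-subject regional truths are drawn from group means and between-subject
SDs truncated at zero. The default groups are six healthy controls and five
patients with regional flow means of 54/52/54 vs 43/40/47 and clearance
means of 28/24/27 vs 25/22/26 mL hg^-1 min^-1 (frontal lobe / cortex /
cerebellum), SDs derived from the corresponding SEMs. Parameters without a
stated value, chosen once on realism grounds: PiB precursor volume
Vg = 2.0 mL/cm^3 (so k2 = K1/Vg ~ 0.12-0.14 min^-1, within the published
range of early PiB one-tissue fits), water partition volume 0.83 mL/cm^3
(k2 = F/0.83, i.e. 0.65 min^-1 at F = 0.54), vascular volume 0.05 +/- 0.01
mL/cm^3, noise_scale 0.05 (single-digit-percent noise on early frames).

What the generator does *not* emulate: amyloid binding (no k3 component by
default, so late-time group contrasts reflect only delivery), partial-volume
and reconstruction effects, input-curve delay/dispersion, radioactive decay
(curves are decay-corrected by assumption), and subject-level input-function
variability. Passing tests therefore validate the estimation chain under the
stated kinetic model, not robustness to those real-data effects.

## Estimator properties and numerical choices

- The CBF estimator is essentially unbiased on noiseless data (< 0.2% at the
  default frame schedule) and its median error at fixture noise is ~2% over
  200 replicates.
- The graphical K1 estimator carries a *known upward bias under bolus
  inputs*: once plasma activity collapses from peak to plateau (~10x within
  ~1.5 min), the tissue still holds the bolus load, so V(Theta) rises above
  the reversible model's asymptote Vg + Vo inside the fitting window, and
  the regression compensates by raising K1. On noiseless synthetic data the
  bias is +2% at k2 = 0.05, +4% at k2 = 0.08, +8% at the default k2 = 0.14,
  +11% at k2 = 0.20. Alternatives were evaluated and found worse: frame-
  duration weighting (+15% at default k2), frame-averaged ca in the Patlak
  transform (+10%), parent-corrected input within the window (+12%). Uniform
  weights, mid-time evaluation, and total-plasma input are therefore the
  defaults; the bias propagates to E (~ +8%) and, amplified by a factor
  ~E/((1-E) ln(1/(1-E))) ~ 1.4 at E ~ 0.5, to PS (~ +11%). Group *flow*
  recovery is unaffected.
- With the default bolus input and the 0-4 min window, a small trapping
  component (K = 0.02 mL g^-1 min^-1) is statistically invisible: the full
  fit returns K at its zero bound with a large standard error, and the
  model-order decision selects the reversible model — consistent with the
  K ~ 0 finding the analysis is designed around. Under an informative
  (constant) input over 30 min the same decision detects K = 0.02 in
  essentially every low-noise replicate and keeps the reversible model for
  K = 0 data, confirming that the selection logic, not the estimator, is
  the limiting factor.
- Degenerate inputs: ca(T) = 0 at an evaluated frame raises a
  degenerate-input error naming the frame; windows with fewer frames than
  free parameters + 1 raise an insufficient-data error; per-region fit
  failures inside the cohort pipeline are logged as warnings and yield
  missing values rather than aborting the subject.
- Group summaries use Welch's unequal-variance t-test (two-sided); the
  extraction fraction is stored as a fraction and reported as a percentage;
  SEM = SD/sqrt(n) with ddof = 1. Regional-difference correlations with
  three regions are flagged as descriptive.
- The windowed uptake contrast uses frame-duration-weighted mean activity
  (not integrals), making it robust to unequal frame schedules.

## Problem sizes

Simulation studies in the test suite use 200 replicates for recovery medians,
100 replicates for model-selection rates, and 500 replicate cohorts (6 vs 5
subjects) for the group-difference power check; these sizes give Monte Carlo
SEs comfortably below the margins being asserted.
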