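# Methods

## The experiment being modelled

A plant acclimated in a growth chamber experiences a staircase of
rising vapour pressure deficit (VPD), produced by lowering relative
humidity at constant temperature (temperature changes would confound
the response through aquaporin conductance and xylem viscosity).  Two
measurement levels run in parallel: an infrared gas analyser logs leaf
gas exchange (stomatal conductance `gs`, transpiration `E`,
assimilation `A`) every 60 s against six leaf-to-air VPD levels, and a
0.01-g balance logs total pot mass every 10 s against five chamber VPD
levels.  The pot is covered, so mass loss is transpiration.

VPD is computed with the Tetens saturation-pressure formula
`es(T) = 0.6108 * exp(17.27 T / (T + 237.3))` kPa; Magnus- and
Buck-type fits agree to well under 1% over 0–60 °C, and the constants
are module-level so an alternative fit can be swapped in.  Design
(set-point) VPD and realized (measured-mean) VPD are distinct fields
throughout and are never asserted equal: realized chamber means differ
from set-point computations at the second decimal in practice.

## Steady-state extraction

Records are assigned to steps by elapsed time against the design
schedule, not by matching RH readings (RH overshoots during
transitions).  Steps own the half-open interval (start, end], so a
record logged exactly at a boundary counts as the last reading of the
ending step.  The steady-state value at a level is the mean over the
final `window_min` minutes (default 5) of the step; a window mean is
far less noise-sensitive than a single end-of-step snapshot, and with
60-min steps and ~10-min stomatal relaxation the residual transient in
the window is a fraction of a percent of the step change.  Levels with
no records in the window are flagged missing, never interpolated;
downstream statistics use available levels only, and the transpiration
reduction excludes (with a logged reason) any plant missing a baseline
level.

## Response statistics

* `phi_E = 1 - E_meas/E_pred`, with `E_pred` the two-point line
  through `E` at the two lowest levels, extrapolated to the target
  level's realized VPD.  A least-squares line through two points *is*
  that line, so the baseline is computed exactly; degenerate baselines
  (equal VPD) are rejected.  `phi_E` may legitimately be negative
  (super-linear response); targets with non-positive `E_pred` are
  flagged invalid.  Scale invariance (multiplying all `E` by c > 0
  leaves `phi_E` unchanged) is property-tested.
* Limitation of A uses each plant's own maximum `A` across levels and
  sums across the accession's plants at a fixed level:
  `sum(A_max - A_meas)/sum(A_meas)`.  The per-level (not cumulative)
  reading is used because results are reported level by level.
* `phi_stom` is the absolute OLS slope of `gs` on `ln(VPD_leaf)`,
  fitted per plant (≥ 3 levels required) and averaged to accession;
  `a` is the fitted `gs` at 1 kPa.
* Whole-plant `E_rate` differenced from 5-min window-mean masses at
  step start and end, over the time between window centres, divided by
  leaf area and converted by the molar mass of water
  (18.015 g mol⁻¹).  The start-minus-end orientation makes
  transpiration positive.  Mass *gains* beyond a small tolerance
  trigger a watering-event warning.

## Segmented regression

Model: `y = alpha_plant + b1*x + b2*(x - psi)_+` with fixed per-plant
dummy intercepts.  A random-intercept mixed model is the textbook
formulation, but with 3–8 plants per accession the variance component
is fragile to estimate and the estimands (psi, slopes) are identical
under the fixed-effect approximation, so the dummy coding is used.

Estimation is Muggeo-style iterative linearization: at the current
psi, regress on `U = (x - psi)_+` and `V = -1{x > psi}`; the V
coefficient gamma estimates `b2 * (psi_true - psi)`, so
`psi <- psi + gamma/b2`, iterated to |delta psi| < 1e-6 (50-iteration
cap).  Three robustness layers are added, because the raw update both
overshoots and can stall on a rising branch of the profile RSS (the
proposed direction need not be downhill at a kink where psi crosses a
data point):

1. each update is backtracked (step halving) until the profile RSS
   does not increase, making the iteration a descent;
2. starts at the median, both quartiles, and the minimiser of a
   25-point coarse profile scan are all run, best RSS kept;
3. a bounded scalar minimisation of the profile RSS in the winning
   coarse-grid neighbourhood polishes the estimate.

Tests verify agreement with an exhaustive 2000-candidate grid oracle
to within grid resolution on random instances.  The breakpoint is
constrained to the interior of the observed x range (margin of one
smallest x-gap per side; solutions pinned there are flagged
`boundary`).  With 5–6 discrete VPD levels the breakpoint can be only
interval-identified (flat profile RSS between two levels, e.g. when
the slope change vanishes); the bracketing-interval midpoint is then
reported with an `interval-identified` flag.  `SE(psi)` is the delta
method `SE(gamma)/|b2|`; slope SEs come from the final OLS covariance.

## Davies test

With psi unidentified under the null "no slope change", standard
likelihood asymptotics fail.  For K = 10 candidate breakpoints equally
spaced between the 2nd and (n−1)th ordered distinct x (K shrinks with
a warning when there are fewer distinct x), the absolute Wald t for b2
at fixed psi is computed; with M its maximum and V its total variation
along the grid, the p-value is the Davies upper bound doubled for the
two-sided alternative:

    p = min(1, 2 * [Phi(-M) + V * exp(-M^2/2) / sqrt(8*pi)])

A grid with zero statistic everywhere (exactly linear noiseless data)
returns p = 1.  Calibration: 500 linear-null simulations (n = 30,
sigma = 0.2) give an empirical rejection rate of 0.054 at alpha =
0.05 in the test suite — near-nominal and slightly conservative, as
expected of an upper bound.  The one-sided (undoubled) version is
anti-conservative (~0.12) and is not used.

## Trait matrix, clustering, ordination, testing

Sixteen accession-mean traits: limitation of A at the five upper leaf
levels; `phi_E` at the three highest leaf levels and the highest
whole-plant level; breakpoint, slope before and slope after at both
measurement levels; `phi_stom`.  Columns are z-scored (sample SD;
constant columns are an error).  k-means (Lloyd) runs from
`n_restarts` random centre sets (default 10,000) via scikit-learn,
best within-cluster SS kept, deterministic given the seed; k = 3 is a
configured input — a silhouette-vs-k diagnostic is written but never
auto-selects.  PCA is computed on the same scaled matrix by SVD;
loading signs are fixed by making each component's largest-magnitude
entry positive, and the loadings table is ordered by |PC1|.  Per-level
accession differences use a one-way ANOVA omnibus F plus pairwise
t-tests BH-adjusted within the level (matching per-level
significance-letter conventions); trait–trait association is squared
Pearson correlation with its two-sided t-test.

## Synthetic cohorts

Per plant: `gs(V) = a - phi_stom ln V` (floored at 0.01 mol m⁻² s⁻¹);
`E(V)` piecewise linear with the archetype's breakpoint and slopes
plus a Gaussian per-plant intercept offset (SD 0.3 mmol m⁻² s⁻¹,
clipped so steady E stays positive); `A = A_max gs/(gs + g50)` — a
rectangular hyperbola so the photosynthetic cost of closure follows
from one interpretable parameter (g50 = 0.08 mol m⁻² s⁻¹).  Within a
step every quantity relaxes exponentially (10-min time constant, so
end-of-step windows are effectively steady; fast ABA kinetics are
deliberately not modelled).  Observation noise is iid on the logged
records (defaults: gs 0.01, E 0.1 mmol, A 0.4; balance readings 0.01 g,
matching the balance's resolution).  The balance trace integrates
instantaneous whole-plant E times leaf area at interval midpoints, so
mass is conserved exactly before noise.  The default cohort is nine
accessions in archetype groups of 1/2/6 with five plants each —
archetype I: psi 1.75 kPa, slopes 1.2/0.25, low gs; II: psi 2.0,
slopes 3.0/−0.5 (net shutdown); III: psi 2.5, slopes 2.5/1.2.  One
master seed; per-plant streams derive from a CRC32 hash of
(accession, plant), so adding a plant never perturbs others and
regeneration is byte-identical.

What the generator does *not* emulate: E and gs are drawn from their
own response laws rather than coupled through the transport equation,
leaf temperature never deviates from the set-point, there are no
diurnal trends, drifts, or instrument dropouts, and noise is iid
Gaussian.  Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
pathology of real instrument data.

A known, deliberate bias: the gravimetric `E_rate` is a start/end
window step average (that is how the measurement is defined), which
smears the relaxation transient into the response; whole-plant slopes
are biased toward zero and breakpoints slightly upward relative to the
generative steady-state parameters.  The ground-truth checker's
default tolerances are therefore looser for the whole-plant level
(0.3 kPa / 0.5 slope units vs 0.15 / 0.25 at the leaf level).  With
noise off and the relaxation time constant set near zero, recovery is
exact at both levels (tested at 1e-6).

## Problem sizes and numerical choices

The test suite simulates cohorts of 3–9 accessions with 2–5 plants
(full time-series resolution), 200 single-archetype accessions for
recovery statistics, 500 null datasets for Davies calibration, and 50
random instances against a 2000-candidate grid oracle.  Convergence
tolerance on psi is 1e-6 kPa; profile-RSS flatness is declared below
1e-10 relative; `b2` below 1e-8 of the response slope scale is flagged
`no-slope-change` (psi SE undefined there).  k-means with 10,000
restarts on a 9 x 16 matrix is used where the mass-restart behaviour
itself is under test; elsewhere a few hundred restarts give the same
partition.
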