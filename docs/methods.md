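# Methods

## Model

Binding is treated as 1:1 Langmuir mass-action kinetics under
pseudo-first-order conditions: the analyte (e.g. mCherry) is in large
excess over the immobilized binder, so the association phase relaxes
exponentially with observed rate `k_obs = k_on·C + k_off` and the
dissociation phase decays at `k_off`. Each phase of each curve carries its
own amplitude and baseline; the three rates (k_on, k_off, k_leak) are
shared across the whole dilution series. The `exp(−k_leak·t)` factor
multiplies the entire signal and models slow loss of His-tagged binder
from the Ni-NTA sensor tip.

Two modelling conventions are fixed deliberately:

- **Phase-local time.** `t` restarts at 0 at the start of each phase, and
  the leak factor uses phase-local `t` in both phases — the leak decay
  does not carry over across the association→dissociation boundary. A
  global leak clock would be the physically continuous alternative; the
  per-phase amplitudes absorb the difference in practice, and the
  phase-local form is what is implemented throughout.
- **Zero-concentration controls** use the same equations (k_obs reduces
  to k_off); no special-casing.

Out of scope by design: heterogeneous-ligand / 2:1 / mass-transport-
limited binding models, and the loading/equilibration phases of the
four-phase BLI run (only association and dissociation enter the fit).

Units: concentration μM, time s, k_on μM⁻¹s⁻¹, k_off and k_leak s⁻¹,
K_D = k_off/k_on μM. Signal is an arbitrary linear scale (instrument nm
shift); all inferences are invariant to rescaling it (see σ-invariance
below).

## Global fit

All curves are fit simultaneously: 4n + 3 free parameters for n curves.
Residuals are ordered curve-by-curve, association before dissociation,
time-ascending, so the SSE is bit-reproducible. The optimizer is SciPy's
bounded trust-region-reflective least squares (`least_squares`,
`method="trf"`), which satisfies the contract the analysis needs: bounded,
derivative-based, monotone in the objective, deterministic for a given
(dataset, start, options).

- **Bounds:** rates in [0, 10³] in their natural units (positivity is
  physical); amplitudes in [0, 10·max|signal|]; baselines in
  ±10·max|signal|. The wide nuisance bounds avoid distorting profile CIs.
- **Parameter scale:** linear (no log transform); non-negativity is
  handled by the bounds. This keeps the exhaustive grid-search comparison
  used in testing straightforward.
- **Convergence:** relative SSE change below 1e-10 (also applied as the
  step tolerance), with a 5,000-evaluation budget; running out of budget
  returns `converged=False` rather than raising. Jacobian-based column
  scaling (`x_scale="jac"`) handles the rate/amplitude scale disparity.
- **Initialization:** per curve, a one-dimensional log-grid scan fits a
  single exponential to the association phase (amplitude and baseline are
  solved linearly at each candidate rate); regressing the provisional
  observed rates on concentration — weighted by association amplitude,
  since the control carries no rate information — gives the k_on (slope)
  and k_off (intercept) guesses, floored at 1e-6. k_leak starts from the
  log-linear terminal slope of the zero-concentration control when that
  trace is clearly positive and decaying, else 1e-4 s⁻¹. Baselines come
  from phase endpoints, amplitudes from phase spans, and the guess is
  clipped into the bounds.
- **Degenerate designs** (fewer than 2 curves, or no two distinct
  concentrations with one nonzero) are rejected up front.

The assumed measurement uncertainty σ_data enters only the *reported*
chi-squared (χ² = SSE/σ²); it cancels in the normalized chi-squared ratio
and therefore affects neither point estimates nor confidence intervals.
This cancellation is asserted numerically in the test suite.

## Confidence intervals

For each of k_on, k_off, K_D: fix the parameter on a 41-point log-spaced
grid over [best/4, best×4], refit everything else warm-started from the
global optimum (and from the neighbouring grid point's solution whenever
that start has lower SSE — a pure improvement), and record
χ²_N = SSE/SSE_opt. Values are accepted while χ²_N stays below

    1 + (n/DF) · F_α(n, DF),   α = 0.05,

with n the full fit's free-parameter count and DF the total data-point
count. Two conventions here follow the published procedure rather than
the textbook F-test: DF is the raw data count (not N − p), and the
threshold uses all n parameters (not 1 profiled df). At n = 35,
DF = 2800 the quantile is ≈ 1.43 and the threshold ≈ 1.018.

Endpoints are the outermost accepted values on each side, refined by
log-scale bisection between the last accepted and first rejected grid
points to 1e-3 relative precision; a side with no crossing inside the
4-fold range is flagged censored at the range edge. The reported
`best ± half-width` uses the maximum accepted deviation. Profiling K_D
reparameterizes to (k_on, K_D, k_leak) with k_off = k_on·K_D.

**Coverage is conservative by construction.** Because the threshold
inflates the single-parameter cutoff by the full parameter count, the
interval is an upper bound on the 95% CI: under matched-model simulation
the probability that χ²_N at the true value exceeds the threshold is
far below 0.05, and empirical coverage in this package's simulation
studies is ≈ 100%, not ≈ 95%. Users needing calibrated (rather than
conservative) intervals should be aware of this property of the
procedure.

**Noiseless data** drive SSE_opt to the round-off floor, where the χ²_N
ratio is dominated by optimizer termination noise. Fits with SSE below
1e-12 per point are treated as exact: the interval degenerates to the
best-fit value instead of profiling.

## Synthetic data generator

The simulator produces datasets with the statistical structure the
analysis assumes: a two-fold dilution series (default 8, 4, 2, 1, 0.5,
0.25, 0.125 μM plus a 0 μM control — eight curves), 300 s association and
dissociation phases on uniform 175-sample grids (2,800 points total),
association amplitudes following equilibrium saturation
`a_on = a_max·C/(C + K_D)` with a_max = 1 signal unit, dissociation
amplitudes continuing the noiseless association endpoint (optional flag;
the fit treats the phases' amplitudes as independent either way),
baselines at 0, a default probe leak of 5e-4 s⁻¹, and additive i.i.d.
Gaussian noise with σ defaulting to 0.5% of a_max. One integer seed
derives an independent substream per curve (keyed by curve index), so
changing the series length never reshuffles existing curves' noise.

Declared assumptions rather than measured facts: the saturation amplitude
model, the leak rate, and the noise magnitude are not reported for the
original instrument runs; equilibrium saturation and a small leak are the
physically standard choices. What the simulator deliberately omits —
baseline drift, spikes, correlated noise, mass-transport effects,
loading-phase artefacts, model misspecification generally — bounds what
passing tests show: parameter recovery and CI behaviour are demonstrated
under the model's own assumptions, not under real instrument pathology.

The scenario library carries the seven published best-fit rate pairs for
LaM8 and its GG15/AK74 LOV-insertion variants (pseudo-dark C450V,
pseudo-lit I532E/A536E, and illuminated states); each entry's k_off/k_on
reproduces its published K_D within the rounding of the published rates.

## Problem sizes used in the test suite

Unit and property tests run on a reduced design — 4 curves
(2, 1, 0.5, 0 μM), 40–60 samples per phase, σ = 1% amplitude — chosen so
the full suite exercises every code path at interactive speed; the
acceptance-level recovery checks use the full 8-curve, 2,800-point
design for all seven scenarios. The CI-coverage study uses 200
replicates of the reduced design, testing membership of the true k_on
via a single profiled refit at the true value, which is equivalent to
membership in the scan-based interval for any value inside the 4-fold
profiling range. The optimizer cross-check freezes nuisances at their
generating values on a tiny 2-curve dataset and compares the fitted
(k_on, k_off) against an exhaustive 200×200 grid-search argmin.

## Known limitations

- Strictly 1:1 kinetics; no avidity, rebinding, or surface heterogeneity.
- A single local fit from a data-driven start (no multi-start or
  Bayesian uncertainty); a grossly wrong start could in principle reach a
  different local optimum, though the initializer has recovered all
  tested scenarios.
- The CI procedure is conservative (see above) and its endpoints are
  bounded by the 4-fold profiling range; extremely flat likelihoods
  produce censored endpoints, not wider intervals.
- The leak factor is phase-local by convention; datasets whose leak
  visibly continues across the phase boundary will absorb the mismatch
  into the per-curve dissociation amplitude.
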