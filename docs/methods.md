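# Methods

## Model

The pipeline works with female-only, age-classified linear projection:
**n**ₜ₊₅ = **A n**ₜ on 18 five-year age bins (0–4, 5–9, …, 80–84, 85+).
**A** is a Leslie-type matrix with three structural parts and nothing else:

- progression survival on the subdiagonal, `s_i = 1 − 5·D_i/N_i` for bins
  0–4 … 80–84, where `D_i` and `N_i` are annual deaths and mid-period
  population of bin i (deaths are quintupled because the step is five
  years); negative values, which arise when quintupled deaths exceed the
  population, are clamped to zero;
- stasis of the open 85+ class in the bottom-right diagonal cell, same
  formula applied to the open class (no longevity-tail correction);
- fertility on the top row, `f_i = (5·B_i/N_i)·√s_i·√s(0–4)`, the
  birth-flow approximation: births occur continuously within the step, so
  the mother must survive on average half a step for late births to occur
  and the newborn half a step to be counted, giving the square-root
  discounts. `B_i` is female births to mothers in bin i, estimated from
  total births as `B / (1 + SRB)` with SRB the sex ratio at birth
  (constant, default 1.05 males per female).

First-bin survival splits infant from child mortality,
`s(0–4) = 0.2·s(0) + 0.8·s(1–4)`, because deaths under age 1 far exceed
those at ages 1–4; the weights are the one-year and four-year shares of the
bin. The maternal survival entering `f_i` is the bin's own progression
survival (stasis for the open class — immaterial in practice since
fertility at 85+ is zero, but fixed for definiteness).

Migration is absent from the model; it projects a closed female population.

## Cleaning rules

Country–years whose single-year death vector contains a run of **five or
more consecutive exact zeros** are excluded before matrix construction
(such runs indicate broken data collection or impractically small
populations). The run is evaluated over the full 86-cell vector including
the open class; no separate population-size floor is applied. Bins with
zero population raise a flagged degenerate-bin error and the country–year
is excluded and audited rather than yielding NaN rates. Every exclusion is
written to a CSV audit with the triggering rule, and rows in = rows
retained + rows excluded holds per run.

## Transient indices

With eigenvalues ordered by non-increasing magnitude (ties broken by
descending real, then imaginary part — the indices below are
tie-invariant):

- damping ratio λ₁/|λ₂| — the asymptotic *rate* of transient decay, not
  its amplitude; flagged infinite when λ₂ = 0;
- case-specific reactivity ‖Ân₀‖₁ with Â = A/λ₁ and n₀ the observed
  structure normalised to unit sum — relative population size after one
  step with growth factored out; values below 1 are first-step attenuation
  and are reported as-is;
- inertia ‖Â^h n₀‖₁ at horizon h = 100 steps (500 years; configurable) —
  the lasting multiplicative offset caused by the unstable initial
  structure, computed by iterated matrix–vector products rather than an
  explicit matrix power.

λ₁ must be real up to 1e-9 (the imaginary part is then discarded);
otherwise the matrix is flagged as non-Perron and rejected. Non-finite
index values are flagged in the output record, and flagged rows are
excluded listwise (and counted) from correlations and PCA.

## Non-normality metrics

All three use the Frobenius norm only; the spectral-norm variants would
complicate the Henrici metric's interpretation without changing the
comparative picture.

| metric | formula | zero iff normal |
|---|---|---|
| Frobenius | √‖AᵀA − AAᵀ‖_F | commutator vanishes |
| Henrici | √(‖A‖_F² − Σₖ\|λₖ\|²) | Schur's inequality is tight |
| Ruhe | maxₖ \|σₖ − \|λₖ\|\| | SVD = eigendecomposition |

Ruhe pairing: singular values and eigenvalue magnitudes are each sorted in
descending order and paired by rank — the only self-consistent reading of
"ordered correspondingly", since SVD routines return σ descending.

All three are positively homogeneous of degree 1, so the value on
Â = A/λ₁ is exactly the raw value divided by λ₁; standardising therefore
*raises* non-normality precisely for declining populations (λ₁ < 1).

Numerical handling: the Henrici argument ‖A‖_F² − Σ|λ|² is analytically
nonnegative but computed eigenvalues carry backward error of order
n·eps·‖A‖, leaving rounding residue of order n²·eps·‖A‖_F² on normal
matrices; the outer square root would inflate that to ~1e-7. Arguments
within the deadband n²·eps·‖A‖_F² are snapped to zero; a negative argument
beyond 1e-12 is logged before flooring. The Frobenius and Ruhe metrics get
no deadband: on symmetric and diagonal input their cancellations are exact
in floating point, while on non-symmetric normal matrices (e.g.
circulants) they can legitimately return ~1e-7 of amplified rounding —
documented rather than masked.

## Pseudospectra

Convention: the ε-pseudospectrum is {z : σ_min(zI − A) ≤ ε}, equivalently
the eigenvalues of all perturbations with ‖E‖ ≤ ε. The grid stores
σ_min(zI − A) on an evenly spaced raster; the displayed "height" 1/σ_min
for perspective plots is derived, not stored. Defaults: the bounding box
covers the spectrum expanded by 20% of the larger spectral extent,
symmetric about the real axis; 201×201 points; contour levels are powers
of ten from 1e-8 to 1. All are configurable — no canonical choice exists
for these display parameters, so they are fixed here and echoed in run
metadata. Because the matrices are real, σ_min is conjugate-symmetric and
only the upper half-plane is computed, then mirrored (rows are mirrored
only when an exactly matching negative coordinate exists in the grid, so
asymmetric user boxes remain correct).

The encapsulation summary rasterises each ε-sublevel set, labels its
connected components (4-connectivity) and reports, per eigenvalue and
level, whether the component containing the eigenvalue's nearest grid cell
also contains another eigenvalue, plus the component's cell count. Levels
below the grid minimum have empty sublevel sets and are skipped with a
warning. This is a coarse, grid-resolution-limited diagnostic by design;
curve-traced contours are out of scope.

## Comparison layer

Spearman correlations use mid-ranks for ties with the large-sample t
approximation for two-sided p-values; coefficients are conventionally
reported to 2 decimal places. Constant columns make the coefficient
undefined: the scalar routine raises, and the correlation-matrix writer
records NaN for that pair.

PCA is an eigendecomposition of the correlation matrix of the
scaled-and-centred variables (year, λ₁, damping ratio, reactivity,
inertia, and either the raw or the scaled non-normality triple). Loadings
are orthonormal eigenvectors, sign-fixed so each component's
largest-magnitude loading is positive; the loading report lists variables
whose |loading| exceeds 10% of the component's largest, in decreasing
order.

Component retention uses Horn's parallel analysis: 1000 iterations
(configurable; the iteration count is not canonical) of standard-normal
data of matched shape, correlation-matrix eigenvalues per iteration, bias
at rank k = (95th percentile of simulated k-th eigenvalues) − 1, and
retention of the leading components whose debiased eigenvalue exceeds 1.
The simulation seed is mandatory and derived from the run seed, making
retention deterministic.

Trend curves are deliberately plain: per-calendar-year mean, median and
central 95% interval per metric, plus the first year the annual mean λ₁
drops below 1. No smoother is fitted.

## Synthetic data

The generator emulates the *shape* of a European demographic extraction:
single-year female population, deaths and total births by maternal age,
ages 0–84 plus "85+", one row per country/year/age, CSV.

- Mortality: Makeham–Gompertz `a + b·e^{c·age}` per 5-year step
  (defaults a = 1e-3, b = 2e-5, c = 0.1), times an infant excess
  (default 8) at age 0, clamped to [0, 1]. This gives ≈0.8% infant and
  ≈6% per-step mortality at 80, a low-mortality regime.
- Fertility: Gaussian hump centred at 28 with SD 6 years, zero outside
  ages 12–55, normalised so per-step daughter rates over all single-year
  ages sum to `tfr_scale` (default 4.25). A cohort spends one-fifth of a
  step at each single-year age, so lifetime daughters ≈ tfr_scale/5 = 0.85
  (TFR ≈ 1.74) — slightly below replacement, λ₁ just under 1, as in
  late-20th-century Europe.
- Per country–year, both schedules are multiplied by independent
  log-uniform factors with half-width 0.10 (drawn from a per-country-year
  seeded stream), emulating cross-country and temporal rate variation;
  `schedule_for` reproduces any country–year's realised schedule without
  re-simulating, which is what the exact rate-recovery tests compare
  against.
- The age pyramid is the stationary structure under the realised
  mortality (the open class holds inflow divided by its per-year death
  rate), perturbed multiplicatively on ages 18–37 by a boom/bust factor
  drawn uniformly within ±15%. The magnitude is a free choice — the data
  the pipeline targets do not document their deviation from stability —
  picked to produce reactivity and inertia visibly different from 1
  without leaving the plausible λ₁ band.
- Deaths are `population × rate/5` per year (the rate is per 5-year
  step), so the downstream estimator `1 − 5·deaths/population` recovers
  the realised rate *exactly* when noise is off; this makes parameter
  recovery an exact test rather than a statistical one. Counts are
  real-valued by default; Poisson sampling is opt-in, separating estimator
  correctness from sampling noise.
- Anomaly injection writes runs of exactly-zero deaths (or population
  floors) into chosen country–years to exercise the exclusion filter.

What the generator does **not** emulate: migration, male dynamics, war- or
policy-driven shocks, age-heaping and other reporting artefacts, serial
correlation of rates within a country over time (factors are drawn
independently per country–year), or any real country's levels. Passing
tests therefore demonstrate the correctness of the estimators, indices and
bookkeeping under known rates — not that any substantive demographic
finding generalises to real extractions.

## Problem sizes and numerical choices

Default test and demo panels use 3 countries × 10 years (30 matrices);
matrix ensembles for property checks use 100 synthetic matrices; Poisson
recovery uses ~1e5 persons per bin, where 3 standard errors of the crude
rates are a fraction of the rates themselves. Pseudospectra default to
201×201 but tests use 21–81 point rasters, which already resolve the
properties being checked (distance map, Lipschitz bound, nesting,
symmetry). Parallel-analysis checks use n = 500 rows, p = 9 columns, 1000
iterations.

Tie-breaks and degenerate inputs: eigenvalue sorting is by (|λ|, Re λ,
Im λ) descending; a zero subdominant eigenvalue yields a flagged infinite
damping ratio; zero population vectors and zero-variance PCA columns raise
named validation errors; matrices violating the Leslie sparsity pattern
(anything nonzero off the top row, subdiagonal and stasis corner) are
rejected at construction.

## Known limitations

- The 85+ stasis inherits all open-class heterogeneity; no abridged
  life-table correction is applied beyond the printed formulas.
- Reactivity/inertia are case-specific (tied to the observed n₀);
  transient bounds, Kreiss constants and sensitivity analyses are out of
  scope.
- The encapsulation summary depends on grid resolution near eigenvalue
  clusters; treat component merges at fine ε with caution.
- Only the standardised (Â) transient indices are computed;
  unstandardised reactivity is intentionally not implemented.
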