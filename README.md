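# transientpop

Transient dynamics and non-normality of age-structured human population
projection matrices.

## The problem

Population projections usually lean on asymptotic quantities: the dominant
eigenvalue λ₁ of a population projection matrix (PPM) gives the long-run
growth rate, and the damping ratio λ₁/|λ₂| the rate at which deviations
from the stable age structure decay. Real populations, however, are never
at their stable structure — baby booms, wars and demographic transitions
leave cohort bulges that amplify or attenuate population size for decades
before asymptotics take over. Whether a life cycle is *prone* to such
transient amplification is a property of the matrix itself, captured by its
**non-normality**: a matrix that commutes with its transpose (A\*A = AA\*)
is fully described by its eigendata and cannot amplify transients that
eigenvalues miss; the further a PPM is from normal, the larger the
amplification its structure can support.

`transientpop` is a pipeline for demographers and population ecologists who
want to quantify this on Eurostat-shaped data: single-year counts of female
population, deaths and births by maternal age, per country and year.

## What it computes

For each country–year the pipeline builds an 18×18 Leslie-type matrix on
5-year age bins (0–4 … 80–84, 85+) with a 5-year timestep,
**n**ₜ₊₅ = **A n**ₜ, from the standard approximations

- survival (subdiagonal, and 85+ stasis in the corner):
  s = 1 − 5·deaths/population, clamped below at 0,
- first-bin survival: s(0–4) = 0.2·s(0) + 0.8·s(1–4), splitting infant
  from child mortality,
- fertility (top row, birth-flow approximation):
  f = (5·births/population)·√s(maternal)·√s(0–4),

with female births estimated from total births via a constant sex ratio at
birth (default 1.05 males per female), and country–years containing five or
more consecutive zero deaths across single-year classes excluded as
implausible.

From each matrix it derives:

- **λ₁** and the **damping ratio** λ₁/|λ₂|;
- **case-specific reactivity** ‖Ân₀‖₁ and **inertia** ‖Â¹⁰⁰n₀‖₁, the
  relative population size one step and 100 steps (500 years) after
  starting from the observed structure n₀ (scaled to sum to 1), with growth
  factored out through the standardised matrix Â = A/λ₁;
- three **non-normality metrics**, on both A and Â:
  Frobenius √‖A\*A − AA\*‖_F, Henrici √(‖A‖_F² − Σ|λ|²), and Ruhe
  maxₖ|σₖ − |λₖ|| (singular values vs eigenvalue magnitudes, rank-paired);
- **pseudospectra**: σ_min(zI − A) over a complex-plane grid — the ε-level
  sets are the eigenvalues of all perturbations of size ≤ ε;
- a comparison layer: Spearman correlations, PCA on the scaled-and-centred
  metrics with Horn's parallel analysis (95th-percentile conservative
  correction) for component retention, and per-year trend summaries.

A synthetic-data module generates Eurostat-shaped panels from known
Makeham–Gompertz mortality and Gaussian fertility schedules, so every stage
is testable — including exact recovery of the configured rates — without
downloading anything. User-supplied tables in the same CSV shape are
accepted throughout.

## Worked example

```python
import transientpop as tp

cfg = tp.SyntheticConfig(n_countries=1, years=(2005, 2005), seed=11)
series = tp.simulate_country_series(cfg)[0]
binned = tp.bin_to_five_year(series)          # 18 five-year bins
ppm = tp.build_ppm(binned)                    # 18x18 projection matrix

record = tp.transient_record(ppm, binned.population)
from transientpop.nonnormality import fill_record
fill_record(record, ppm)
print(record.lambda1, record.damping_ratio, record.reactivity, record.inertia)
```

prints

```
0.9598788209182634 1.0660631731104673 1.0345909301509928 1.8295944345307196
```

λ₁ ≈ 0.96: the population declines ~4% per 5-year step asymptotically.
The damping ratio 1.07 is close to 1, so transients decay slowly. The
observed structure (which carries a cohort boom) makes the population 3.5%
larger than the asymptotic trajectory after one step (reactivity 1.03) and
leaves it 83% larger for good (inertia 1.83). The same record carries the
six non-normality values (e.g. scaled Henrici ≈ 3.73).

The full pipeline runs from the shell:

```sh
transientpop run-all --seed 11 --output out/
# retained 30 of 30 country-years; outputs in out
```

producing `metrics.csv` (one row per country–year), the exclusion audit,
the matrix bundle, Spearman/PCA outputs and trend summaries. On this
synthetic panel the transient indices correlate strongly
(ρ(reactivity, inertia) = 0.98 in `spearman_scaled.csv`) and the three
scaled non-normality metrics co-move (pairwise ρ ≥ 0.95) — short-term and
lasting amplification are two faces of the same matrix property.
`transientpop pseudospectra --matrix <file>` exports a σ_min grid for any
single matrix.

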