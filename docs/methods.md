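# Methods

## Trial model and ANOVA

Every trait is modelled as

    y_ijk = μ + a_i + r_j(i) + g_k + (ag)_ik + e_ijk

with year, replication-within-year, genotype, genotype×year and residual
terms. All effects are treated as random draws from zero-mean normals for
simulation and heritability interpretation; the ANOVA itself is an
ordinary least-squares decomposition and makes no distributional
assumption beyond additivity.

`fit_anova` computes **sequential (Type I) sums of squares** in the fixed
order year → rep(year) → genotype → genotype×year, by differencing
residual sums of squares of nested design matrices (ranks from the same
least-squares factorisations give the dfs, so rank-deficient and
unbalanced layouts are handled without special cases). For the balanced,
complete layouts this pipeline targets, Type I equals Type III, so the
choice is inconsequential there; it matters only for unbalanced evaluator
panels, where the least-squares decomposition is still well defined. A
`require_balanced` flag refuses unbalanced cells outright for users who
want the textbook decomposition guarantee.

When a trait has no within-year replication (one observation per
genotype-year: loaf measurements, dough extensibility, protein traits),
the model reduces to year + genotype and the interaction is confounded
with error; the fitted table flags this (`reduced=True`) and downstream
code switches estimators accordingly. Genotypes observed in a single year
are excluded with a warning, since their interaction effect is not
estimable. F statistics for every term are formed against the error mean
square; no interaction-as-denominator testing is attempted.

Rep-within-year is kept as its own line and never pooled into error by
default; both mean squares are emitted so either error definition can be
used.

## Heritability estimators

**Mean-square ratio** (replicated traits): `h² = 1 − MS_G×Y/MS_G`.
Negative estimates are reported raw (with a clamp option) because their
confidence intervals legitimately cross zero. The 90% limits are the
Knapp–Stroup–Ross construction

    UL = 1 − [(MS_G/MS_G×Y) · F_{1−α/2; df1, df2}]⁻¹
    LL = 1 − [(MS_G/MS_G×Y) · F_{α/2;   df1, df2}]⁻¹

with df1 = g−1, df2 = (g−1)(y−1) and α = 0.10 by default. Because
F_{α/2} < 1 < F_{1−α/2} at matching dfs, the interval always brackets the
point estimate; with g = 76, y = 2 the two dfs are equal (75, 75) and the
interval has exactly nominal coverage under the balanced normal model —
the test suite verifies 0.90 ± 0.04 empirically over 1000 simulated
trials.

**Variance components with year as replicate** (unreplicated traits):
method-of-moments extraction `σ̂g² = (MS_G − MS_e)/r`, `σ̂e² = MS_e`,
truncated at zero with a flag, then `h² = σ̂g²/(σ̂g² + σ̂e²/r)`. The
method-of-moments choice is validated by exact reproduction of the
reference trial's reported values (0.68 loaf volume, 0.35 extensibility,
0.90 gliadin:glutenin, 0.85 total HMW-GS) from its printed mean squares.

BLUPs shrink entry means toward the grand mean by
`k = σ̂g²/(σ̂g² + σ̂e²/r)`, clamped to [0, 1]; they are used as the fourth
GWAS environment, not as a mixed-model fit.

## Synthetic trial generator

`simulate_phenotypes` draws each effect once per index combination
(years, evaluators nested in years, genotypes, genotype-year cells,
residuals per observation). Genotype effects are drawn **jointly across
traits** from a multivariate normal with the target genetic correlation
matrix; year, interaction and residual effects are independent across
traits, because entry-mean correlations at the simulated variance ratios
are dominated by the genetic component. Sensory scales are emulated by
clipping the latent sum to the scale bounds and rounding to the nearest
unit — applied after effect summation, which slightly attenuates realised
variances relative to the configured components (the recorded truth
refers to the latent scale). Evaluator counts may differ by year (the
drivers use 4 and 6) with a balanced default for exact-ANOVA testing.

The default study conditions mirror the reference trial: 76 genotypes,
2 years, variance components derived from the published mean-squares
table by the same method of moments the estimators use. The SNP panel is
simulated at reduced scale — 2,000 markers in the drivers, 500–1,000 in
the simulation-heavy tests, versus ~12,800 in a real genotyping-by-
sequencing panel — with per-marker allele frequency uniform on the MAF
range, exact expected missingness and heterozygosity rates, and **no
linkage disequilibrium**: markers are independent. Consequences: (i)
QTL detection power per marker is realistic but there are no proxy hits
adjacent to a planted QTL, so "number of hits" is not comparable to an
LD-structured panel; (ii) population-structure PCs capture nothing real
(there is no structure), so their inclusion in the scan only costs dfs.
Passing tests therefore demonstrate the statistical machinery is
calibrated, not that real panels behave this way.

`inject_qtl` adds `(dose − mean dose) × additive effect` to every
observation of the trait, with missing calls contributing the mean dose
(zero increment); effect sizes can be given as trait units per allele
copy or as the two-homozygote difference in percent of the trait mean
(`effect_pct = 100·|2a|/mean`).

## Protein fractions

Ratios (Gli:Glu = F3/(F1+F2), HMW:LMW = F1/F2, UPP:TPP =
U(F1+F2)/[E(F1+F2)+U(F1+F2)]) are computed from raw absorbance areas;
A% percentages (per fraction over the set total) are what enters trait
tables, since they express composition independent of total protein. F4
(albumins/globulins) takes part in no ratio. Gli:Glu uses total (E+U)
areas by default with an extractable-only option, since either reading is
defensible. The bundled fraction-area generator is synthetic plumbing —
lognormal totals with Dirichlet shares — and is not fit to any
instrument.

## Multivariate analysis

Correlations are pairwise-complete Pearson with t-distribution p-values
and no multiplicity correction (matching trial-report convention; stars
at 0.1/0.05/0.001). PCA runs on centered, optionally unit-scaled columns
via SVD; sporadic missing cells are mean-imputed by default (or rows
dropped), and signs are fixed by making each loading column's
largest-magnitude entry positive. PCR is OLS of the response on the first
k scores; k defaults to 6 in the drivers, with
`n_components_for(model, cumvar)` available to pick k by cumulative
variance instead. Entry-mean tables may use genotype rows or
genotype-year rows; both layouts are supported.

## GWAS

Only the fixed-effect GLM scan is implemented; multi-locus methods
(BLINK, FarmCPU) are out of scope, but their result tables can be
imported into `consensus_hits` on equal terms, since the consensus rule
is model-agnostic. Structure covariates are the leading PCs of the
mean-imputed filtered dose matrix (default 3). Missing doses are dropped
pairwise per marker; a marker needs n_pcs + 3 complete lines or it is
skipped with a NaN row. Both significance gates (raw p ≤ 1/n and
BH-adjusted p < 0.1) apply conjunctively by default, with single-gate
options, because the conjunctive reading is the stricter and safer one.
The two-homozygote comparison uses Welch's t-test with heterozygotes
excluded and refuses classes with fewer than 2 lines.

Dose coding counts the major allele at read time for HapMap/VCF input
(recorded per marker so effect signs are reproducible); numeric CSV input
is taken as coded. Recoding an allele flips dose d → 2−d and flips only
the effect sign.

## Selection overlap

Top-k sets are tie-inclusive over distinct values: every genotype tying
or beating the k-th ranked distinct value is kept (the only reading under
which a "top-10" set can contain 21 lines). Overlap percentages use the
selecting (first) set as denominator with half-up integer rounding,
matching the reference arithmetic 14/34 → 41% and 6/12 → 50%; the report
labels the denominator explicitly because the measure is asymmetric.

## Numerical choices and problem sizes

* Least-squares fits use `numpy.linalg.lstsq` (SVD-based, rcond=None);
  tiny negative sequential SS from floating-point cancellation are
  clipped at zero, and the decomposition is checked against the corrected
  total SS at 1e-9 relative.
* BH adjustment delegates to statsmodels (`fdr_bh`); the step-up
  definition is kept as an independent oracle in the tests.
* F quantiles come from `scipy.stats.f`; the test oracle inverts the
  regularised incomplete beta function independently.
* Simulation-heavy checks use 1000 trials (interval coverage), 200 trials
  per heritability level (recovery), 1000 markers (null calibration) and
  100 seeds × 500 markers (power) — sizes chosen to keep Monte-Carlo
  error well inside the tolerances being asserted.

## Limitations

* No REML/mixed-model machinery: heritability is moment-based, BLUPs are
  simple shrinkage, and the GWAS has no kinship correction.
* The generator produces no LD, no population structure, no
  genotype-environment covariates and no agronomic covariates.
* The unreplicated-trait estimator treats year as the only replicate, so
  its σ̂e² absorbs genotype-year interaction; this is the correct analogue
  of the replicated design but means h² estimates from the two paths are
  not directly comparable for the same trait.
* Dataset-dependent quantities of the reference trial (its correlation
  table, PCA percentages, PCR R², specific SNP catalogue) depend on
  unpublished raw data and are covered by property-based checks on
  simulated trials instead of exact reproduction.
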