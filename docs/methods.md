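# Methods

## Design and data model

The package models a single-stage cluster sample: `a` primary sampling
units (hospitals/centers), every eligible subject within a selected unit
enrolled, no stratification and no weighting. The reference design is the
Brazilian 27-center severe-maternal-morbidity surveillance network, whose
per-center subject counts are shipped as `STUDY_CLUSTER_SIZES` (27
clusters, 9,555 subjects, mean cluster size 353.9; cluster sizes range
from 48 to 1,086).

Analyses are per dichotomized variable. A `VariableSpec` carries a
declarative success rule (category equality, set membership, or a numeric
threshold such as "< 30 years") and an optional subpopulation rule
restricting the denominator (e.g. "among abortion cases"). Missing values
are handled listwise **per variable**: a missing cell removes the record
from that variable's denominator only, which is why each variable has its
own valid `n` and mean cluster size `n_a`. Clusters with zero valid
records for a variable are dropped for that variable, and the effective
cluster count `a_eff` replaces `a` in every downstream formula. This
choice matters for sub-denominator variables (denominators as small as 8
or 9 subjects) for which not all centers contribute; one-way ANOVA needs
at least one observation per group, so contributing clusters are the only
coherent group set.

## Estimators

**Prevalence.** The ratio estimator `r = Σy_α / Σx_α` pools counts over
clusters and equals the overall valid-sample proportion. Clustering
affects its variance, not its value.

**ICC.** One-way ANOVA on the 0/1 subject values gives MSB (between
clusters, `a−1` df) and MSW (within, `n−a` df), `F = MSB/MSW`, and

    ρ̂ = [(F−1)·a/n] / [1 + (F−1)·a/n].

With the mean cluster size `k = n/a`, this is algebraically identical to
the variance-components form `(MSB − MSW)/(MSB + (k−1)·MSW)` for every
cluster-size pattern, so both published computing formulas agree to
machine precision (a tested invariant). Raw estimates may be negative
(sample between-cluster variance below its expectation under
independence); the raw value is kept internally, clamped to `[0, 1]` for
reporting, and printed as `<0.001` below the three-decimal floor, matching
the reporting convention of the reference tables.

**ICC standard error and CI.** The asymptotic variance is Smith's
large-sample formula for the ANOVA estimator with unequal group sizes,
evaluated at `k0 = (n − Σn_i²/n)/(a−1)`:

    var(ρ̂) = 2(1−ρ)²/k0² · [ (1+(k0−1)ρ)²/(n−a)
              + { (a−1)(1−ρ)(1+(2k0−1)ρ) + ρ²(Σn_i² − 2Σn_i³/n + (Σn_i²/n)²) } / (a−1)² ]

with a normal-approximation 95% CI clamped to `[0, 1]`. For equal sizes
this reduces to the classical equal-group variance. Validation: under
Gaussian one-way data on the 27-cluster design the formula matches the
Monte-Carlo sampling sd of ρ̂ (0.026 vs 0.025), and at ρ = 0.077 it yields
se = 0.0273 — reproducing the CI widths printed in the reference tables.

**Design effect.** `DEFF = var_actual / var_SRS` with

    var_actual = Σ_α (r_α − r)² / [a(a−1)],   var_SRS = r(1−r)/(n−1).

Cluster proportions `r_α` enter unweighted — fidelity to the published
estimator over statistical optimality; size-weighting would shrink the
influence of small centers but would no longer reproduce the reference
values. `n` is the variable's valid denominator, not the full cohort. At
boundary prevalence (`r` = 0 or 1) the SRS variance vanishes and the
ratio is reported as NaN with a flag rather than raised, since a pipeline
over ~150 variables must survive degenerate columns.

**Sample size.** `n* = ⌈(a/ICC)·(DEFF − 1 + ICC)⌉`, undefined for
non-positive ICC. Rounding is upward (sample sizes are conservative
integers); 1e-9 is subtracted before the ceiling so that values that are
integers up to float noise (e.g. DEFF = 1 giving exactly `a`) are not
inflated by one subject.

## Degenerate cases

- MSW = 0 with MSB > 0 (perfect within-cluster homogeneity): F treated as
  +∞, ρ̂ = 1, flagged `degenerate_msw_zero`.
- All subject values identical: ICC carries no information; reported 0
  with flag `constant` and NaN se/CI.
- MSB = 0: raw ρ̂ is negative (e.g. −1 for two identical half-and-half
  clusters); reported 0 via clamping.
- Pipeline-level: per-variable failures (no valid observations, a single
  contributing cluster) become flagged rows in the output, never silent
  drops; configuration errors (a rule naming an absent column) abort.

## Synthetic cohorts

`SimulationScenario` draws, for each cluster, `p_α ~ Beta(μ(1−ρ)/ρ,
(1−μ)(1−ρ)/ρ)` (all clusters share `p = μ` when ρ = 0), then i.i.d.
Bernoulli(`p_α`) subject values, then masks cells missing completely at
random at `missing_rate`. Under this beta-binomial model the marginal
prevalence is exactly μ and the population ICC of the generated 0/1
values is exactly ρ — no latent-scale conversion, which is why it is the
validation surface: parameter recovery of the estimators is a direct
check. Cluster sizes are fixed, never resampled, mirroring the
census-within-cluster design. Defaults: the study's 27-cluster size
vector; seed 20120921; every stochastic routine takes an explicit seed and
the same seed yields byte-identical output files.

What the generator does **not** emulate: informative or
variable-specific missingness (real chart abstraction loses data
non-randomly), correlation between variables (each is drawn
independently on the shared cluster frame), region-level structure, and
any clinical case-definition logic. Passing recovery tests therefore
demonstrate the estimators' correctness under the stated sampling model,
not robustness to those real-data features.

## Reference tables and summaries

The packaged TSV transcribes the study's published per-variable estimates:
154 rows (process 37, outcome 69 — including indented sub-items and the
two summary outcome rows — personal/obstetric 40, structure 8) with the
printed strings preserved. `<0.001` entries are valued at 0.0005 for
ordering and medians — below the printable floor, preserving rank without
inventing precision; the affected entries sit far from every reported
median. Two pairs of duplicate row labels within the outcome block were
disambiguated with parenthetical suffixes so name-keyed comparisons are
well-defined; values are unchanged. Block summaries use the midpoint
median for even counts. The regression checker compares tables cell by
cell at half a unit in the last printed digit per column and reports
mismatches rather than raising.

Recomputed from this fixture (and asserted in the test suite): process
ICC median 0.09 / DEFF median 20.52; outcome 0.021 / 6.24; overall ICC
median 0.0345 (prints as 0.035); 75% of ICCs below 0.1;
process-to-outcome mean-ICC ratio 2.60; n* = 7,072 = 74% of the 9,555
enrolled, from the main outcome's ICC 0.077 and DEFF 21.09 with a = 27.

## Numerical and testing choices

- The ANOVA is computed from per-cluster sums (binary data admit exact
  sufficient statistics); independent plain-loop oracles and
  `scipy.stats.f_oneway` cross-check it in the tests on 1,000+ random
  small instances at 1e-12.
- Monte-Carlo suite sizes: 200 replicates for estimator-mean recovery,
  500 for CI coverage, on the full 27×9,555 design — chosen to keep
  Monte-Carlo error well below the asserted tolerances while the whole
  suite stays fast.
- The per-cell comparison tolerances of the regression checker are half a
  printed unit; they are about transcription fidelity, not statistical
  agreement.

## Known limitations

- The asymptotic normal CI for the ICC undercovers in small-`a`, skewed
  settings: at the study conditions (27 clusters, μ = 0.095, ρ = 0.077)
  empirical coverage over beta-binomial replicates is ≈ 0.83 against the
  nominal 0.95, because the right-skewed cluster-probability distribution
  inflates the true sampling variance of ρ̂ (sd ≈ 0.035) beyond the
  normal-theory asymptotic value (≈ 0.026); even under Gaussian
  components coverage at 27 clusters is ≈ 0.89. The corresponding
  calibration test documents this gap. Users needing calibrated intervals
  at few clusters should bootstrap over clusters; that is out of scope
  here because the interval definition follows the reference methodology.
- The linear ANOVA ICC on 0/1 data is the estimator of record here; no
  random-intercept logistic or latent-threshold ICC is provided, and no
  finite-population correction or weighting is applied.
- Per-variable published ICC/CI/DEFF values cannot be recomputed from raw
  data (the underlying charts were never released); they are covered by
  the transcription fixture and its regression harness instead.
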