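# Methods

`slopeflow` implements the statistical machinery of a population-genomic
study of gene flow among grasshopper populations along a steep elevational
gradient (five sites, 1,577–3,515 m a.s.l., ~35 km apart): SNP
diversity/differentiation statistics, competing spatial gene-flow models
compared by approximate Bayesian computation (ABC), an independent
composite-likelihood estimate from the site-frequency spectrum, Mantel tests
of trait–predictor association, and phenological-overlap metrics from weekly
adult surveys. Everything runs on synthetic data the package generates
itself; no sequencing data are required.

## Genotype substrate and filters

Genotypes are biallelic SNP dosages (0/1/2 copies of the alternate allele)
for diploid samples grouped into populations ordered by elevation. Two
post-calling filters mirror a GBS pipeline's final steps:

- **Hardy–Weinberg imputation** (`impute_missing`): each missing call is
  replaced by the genotype with maximal Hardy–Weinberg probability under its
  population's allele frequency at that locus, if that probability reaches
  the confidence cut-off (default 0.70); loci still incomplete afterwards are
  dropped, so downstream modules always see a complete matrix. This is a
  deliberate simplification of haplotype-model imputation: the downstream
  statistics need only a complete matrix, not phase-aware calls.
- **MAF filter** (`filter_maf`): loci with pooled minor-allele frequency
  strictly below 2% are removed (missing calls excluded from denominators).

## Diversity and differentiation

Per locus, with `r` populations, per-population alternate-allele frequencies
`p_k`, observed heterozygosities `h_k`, and harmonic-mean diploid sample
size `ñ`, the Nei–Chesser unbiased estimators are

    H_O = mean_k h_k
    H_S = ñ/(ñ−1) · [1 − mean_k(p_k² + q_k²) − H_O/(2ñ)]
    H_T = 1 − (p̄² + q̄²) + H_S/(rñ) − H_O/(2rñ),   p̄ = mean_k p_k .

Multi-locus indices follow the ratio-of-averages convention (components
averaged across loci first): `F_IS = 1 − H_O/H_S`, `F_ST = (H_T − H_S)/H_T`,
Jost's `D_est = (r/(r−1))(H_T − H_S)/(1 − H_S)`. Pairwise F_ST recomputes
the components on each two-population restriction; Latter's linearization
`F_ST/(1 − F_ST)` provides the genetic-distance matrix for Mantel tests.
Plain per-population expected heterozygosity `2 p_k q_k` is reported
separately from the bias-corrected `H_S`.

Note that the finite-sample corrections make these estimators slightly
negative (O(1/n)) when two samples are literal copies of each other; the
tests assert that bound rather than exact zero.

## Spatial gene-flow models and the simulator

Five migration topologies over demes ordered low → high elevation: `dn`
(unidirectional downslope, adjacent demes), `up` (unidirectional upslope),
`ss` (bidirectional stepping stone), `am` (island model, all pairs equal),
and `sk` (island model plus an extra unidirectional rate from every deme
into the top deme — a summit "sink" maintained by lowland sources, used for
the one species that straggles above its main range). The scalar rate `m`
is a per donor→recipient edge proportion of individuals per generation;
forward topologies become backward lineage-movement rates by edge reversal.
Priors: `m ~ U(0.001, 0.05)`; per-deme `N_e` i.i.d. log-uniform(200, 10,000)
(per-deme draws, since the study reports per-population estimates).

The simulator is a structured coalescent: within deme `i` lineages coalesce
at pairwise rate `1/(2 N_e[i])` per generation; migration follows the
backward matrix. SNPs are generated as a constant-intensity Poisson process
on total branch length streamed across independent genealogies until the
requested SNP count is reached. This reproduces the sampling distribution
of SNPs ascertained from simulated sequences — class probabilities
proportional to expected subtending branch length, e.g. the single-deme
folded spectrum ∝ 1/i + 1/(2n−i) — including mild linkage between SNPs that
share a genealogy, as SNPs on one short simulated sequence would. The
intensity is calibrated per dataset from four unmarked pilot genealogies
(target ≈ 1 SNP per genealogy); it only trades genealogy count against
linkage and does not affect the ensemble SNP distribution. Placing a single
conditioned SNP uniformly on each realized tree was considered and rejected:
it draws classes with probability E[ℓ_i/L] rather than E[ℓ_i]/E[L], which
deviates measurably (tens of standard errors at 10⁵ loci) from the neutral
spectrum. Haplotypes are paired at random within demes per site.

For the d-island coalescent with per-edge backward rate `m`, the expected
pairwise (two-deme Nei) F_ST is `1/(1 + 8 N d m)` — derived from expected
coalescence times (within 2Nd, between 2Nd + (d−1)/(2 m_tot)) and verified
against msprime; the familiar `1/(1 + 4 N m_tot (d/(d−1))²)` form is the
global d-deme F_ST, not the pairwise one, and the two differ by a factor
2(d−1)/d in the denominator coefficient. Tests use the pairwise form.

The summary-statistic vector per dataset (fixed ordering): mean total gene
diversity `H_T`; segregating-site counts overall and per deme; mean pairwise
sequence differences between each deme pair; pairwise Nei F_ST per deme
pair. Statistics with zero MAD over a reference table (e.g. the overall
segregating-site count, constant under SNP-count conditioning) are excluded
from ABC distances with a warning.

## ABC engine

The reference table holds one row per simulation (model label, parameter
draw, summary statistics); distances are Euclidean on median/MAD-standardized
statistics, and a query accepts the nearest `⌈tol · rows⌉` rows (boundary
ties broken by table order after a seeded shuffle).

- **Model choice** (`ABCModelChoice`): `rejection` posterior = share of each
  model among accepted rows; `mnlogistic` fits an Epanechnikov
  distance-weighted multinomial logistic (soft-max) classifier on the
  accepted rows, centred at the observation — the deterministic special case
  of the neural-network family of regression corrections. Models absent from
  the accepted set are reported with probability 0 and flagged untestable.
- **Cross-validation** (`cross_validate`): leave-one-out over `n_cv`
  pseudo-observations per model, classified against the table minus
  themselves; returns the confusion matrix and mean correct-assignment rate.
- **Goodness of fit** (`goodness_of_fit`): observed statistic = median
  standardized distance to the accepted set (tol 0.01); null from
  pseudo-observed table rows; `p = (1 + #{null ≥ obs})/(n_rep + 1)`.
- **Parameter estimation** (`estimate_parameters`, tol 0.05): rejection
  acceptance, then weighted local-linear regression adjustment of each
  parameter toward the observed statistics (log scale for `N_e`), clamped to
  the prior support; point estimates and intervals are weighted quantiles
  (2.5/50/97.5%). A rank-deficient design falls back to the unadjusted
  sample with a warning.

## AFS composite likelihood

Per population the folded spectrum counts loci by minor-allele copy number
(classes 0…n_k, class 0 = monomorphic within the population); optionally the
2-D joint folded grid is kept per population pair. The expected spectrum
under a model is Monte-Carlo estimated from the simulator with add-one
smoothing; the composite log-likelihood sums
`obs_count · log(expected proportion)` over classes, treating loci and
spectra as independent. The pairwise joint grids (`joint=True`) retain the
between-population allele-frequency covariance that the marginals integrate
out, and are markedly more informative about migration-scaled population
size at weak differentiation. Maximization is cyclic
coordinate search on (log m, log N_e) — seven-point line searches with a
halving bracket, stopping at 0.001 relative parameter change — with common
random numbers (one simulation seed per restart) so the optimizer sees a
deterministic surface; best of `restarts` seeded starts. Parametric
bootstrap refits datasets simulated at the point estimates and reports
percentile intervals.

**Identifiability caveat.** The conditioned-SNP spectrum is exactly
invariant under `(N_e, m) → (c N_e, m/c)` (only the time unit changes), so
the composite likelihood has a ridge along `N_e · m = const`: absolute
`N_e` is identified only jointly with `m`, or conditionally on a known `m`
(freeze a coordinate by passing equal bounds). Sequence-based AFS tools
anchor absolute `N_e` via the mutation rate and monomorphic sites; this
module's ascertained-SNP likelihood deliberately has no mutation-rate
parameter. The recovery tests therefore check `N_e` with `m` fixed at its
known value, using the pairwise joint spectra.

## Distances and Mantel tests

Predictors: geographic distance (equirectangular local projection, km; any
affine-close convention gives identical Mantel r), elevational distance
(|Δ elevation| m), environmental distance (Euclidean on z-scored mean annual
temperature and growing-season length from the five-site table), genetic
distance (linearized pairwise F_ST). Trait-category distances are Euclidean
on z-scored population means (growth: body mass, femur length;
reproductive: clutch size, ovariole number, egg mass, clutch weight;
physiological: preferred body temperature, CT_min, CT_max); z-scoring
prevents unit-dominated distances. Categories with complete data for fewer
than three populations are emitted as N/A. The Mantel test correlates
lower-triangle vectors (Pearson), permutes rows+columns of the second matrix
jointly (999 by default), and reports the one-sided upper p with the +1
correction (p is never 0, and matches the convention under which a strongly
negative r yields a large p).

## Phenology

Pianka's symmetric overlap `O = Σ p_j p_k / √(Σ p_j² Σ p_k²)` is computed on
weekly adult-count proportions aligned on the union of surveyed weeks (zeros
where one site recorded no adults; unsurveyed weeks are absent, not
zero-filled). Percentile phenology is the day of year on which the
cumulative adult proportion first reaches 15% / 85% (first-crossing, no
interpolation — the day the percentile adult was actually surveyed). Sites
with zero seasonal totals are skipped with a warning; adults only.

## Synthetic data

`species_config` returns the four study-shaped sampling layouts (3–5 demes,
8–23 diploids per deme, 4,087–9,454 SNPs) and their candidate model sets
(`sk` only for the five-deme widespread species); `site_table` the five-site
environment table. `gen_survey_data` draws weekly Poisson counts around a
Gaussian season whose peak shifts later with elevation (defaults: ~3 d /
100 m delay, 3-week spread, peak ~60 adults — a realistic montane mid-summer
season); `gen_trait_clines` draws population trait means linear in elevation
plus Gaussian noise, with defaults emulating the study's direction of clines.
The generators emulate seasonal timing shifts and linear clines only — not
observation gaps, multi-species surveys' shared weather shocks, GBS
missingness or linkage structure — so passing tests demonstrate correctness
of the estimators under the stated models, not robustness to those
real-data artifacts.

## Problem sizes used in the test and calibration runs

The study-scale analyses are scaled down to desk scale as the package's
standard test configuration: reference tables of 5,000 simulations per model
(the study used 2,000,000) with 200 SNPs per dataset (the study matched each
species' 4,087–9,454 SNPs); leave-one-out cross-validation with 100
pseudo-observations per model at acceptance fractions 0.001 and 0.005;
parameter-recovery tables of 3,000 rows; goodness-of-fit calibration on an
800-row single-model table with 99-replicate nulls over 500 runs; AFS fits
with 1,500 Monte-Carlo loci, 3 restarts and 5 cycles. At 200 SNPs the
summary statistics carry substantially more sampling noise than at the
study's SNP counts, which lowers attainable model-discrimination rates
(see README's reproduction section); all other calibration properties
(interval coverage, null rejection rates, closed-form agreement) are
scale-robust.

## Numerical choices

- Event-driven kernel in numba with an inline xoshiro256** generator;
  per-dataset seeds are drawn from the user's `numpy.random.Generator`, so
  every public entry point is reproducible from one seed.
- MAD-standardization drops zero-MAD statistics rather than dividing by 0.
- Acceptance-boundary distance ties are broken by table order after a seeded
  shuffle; `⌈tol·rows⌉` rows are always accepted.
- Weighted quantiles interpolate the cumulative weight at midpoints.
- Degenerate inputs fail loudly: non-biallelic VCF records, samples missing
  from the population map, populations with no data at a locus, constant
  distance matrices, all-zero survey seasons, non-communicating migration
  structures (detected by reachability and by an event-count guard).

## Known limitations

- No recombination within genealogies, no selection, no population-size
  change through time; `m` is constant and shared across edges.
- The HW-imputation stand-in ignores linkage information a haplotype model
  would use, so it drops more loci than the study's pipeline would.
- Regression model probabilities from tiny accepted sets (tol 0.001 of a
  small table) are high-variance; the rejection method is the stabler
  reference at desk scale.
- The Monte-Carlo expected AFS makes `fit_afs` accuracy depend on
  `n_sim_loci`; the common-random-numbers surface is deterministic but still
  one realization.
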