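# slopeflow

Demographic inference and phenotype association for populations arrayed
along an elevational gradient. The package grew out of a study system of
four grasshopper species sampled at three to five sites spanning ~2,000 m of
elevation over ~35 km in the Colorado Front Range, where the central
questions are: how much gene flow connects populations along the slope, in
which direction does it move, and do genetic, geographic or environmental
distances predict the phenotypic clines observed in growth, reproductive and
physiological traits?

It is aimed at population geneticists and evolutionary ecologists who want a
self-contained, testable implementation of that analysis chain — from a
filtered SNP matrix to model-based gene-flow inference — that can be
exercised end-to-end on synthetic data with known truth.

## What it computes

- **Diversity and differentiation** (`slopeflow.popgen_stats`): per-SNP and
  multilocus Nei–Chesser estimators — H_O, unbiased within-population gene
  diversity H_S, total gene diversity H_T — and the derived indices
  F_IS = 1 − H_O/H_S, F_ST = (H_T − H_S)/H_T (ratio-of-averages across
  loci), Jost's D_est, pairwise F_ST matrices and Latter's linearization
  F_ST/(1 − F_ST).
- **Spatial gene-flow models** (`slopeflow.demography`): a structured
  coalescent simulator over five migration topologies — downslope (`dn`),
  upslope (`up`), stepping stone (`ss`), island (`am`) and source–sink
  (`sk`, an island plus extra unidirectional flow into the summit deme) —
  producing SNP datasets whose sites follow the neutral ascertained-SNP
  frequency spectrum.
- **ABC model choice and estimation** (`slopeflow.abc`): rejection and
  distance-weighted multinomial-logistic posterior model probabilities over
  a simulated reference table, leave-one-out cross-validation, a
  median-distance goodness-of-fit test, and regression-adjusted parameter
  posteriors for the migration rate m and deme sizes N_e — exposed as
  scikit-learn-style estimators (`ABCModelChoice`, `ABCParameterEstimator`).
- **AFS composite likelihood** (`slopeflow.afs`): folded minor-allele
  spectra per population and a Monte-Carlo composite-likelihood fit with
  parametric bootstrap.
- **Trait–predictor association** (`slopeflow.distances`): geographic,
  elevational, environmental, genetic and trait-category distance matrices
  and Mantel permutation tests.
- **Phenological overlap** (`slopeflow.phenology`): Pianka's index on weekly
  adult-count proportions and 15th/85th-percentile phenology dates — an
  ecological ceiling on between-site mating opportunity.
- **Synthetic data** (`slopeflow.synthetic`): the four study-shaped species
  layouts, the five-site environment table, and survey/trait generators with
  controllable phenological delay and cline slopes.

## Worked example

Simulate a three-deme stepping-stone dataset shaped like the study's
three-site species (23/21/21 diploids), write it as VCF + population map,
then run the statistics and the phenology pipeline:

```sh
$ slopeflow synth --species "C. pellucida" --model ss --m 0.01 --ne 1000 \
      --n-snps 300 --seed 7
wrote synthetic.vcf / .popmap.tsv / .survey.csv / .traits.csv

$ slopeflow stats synthetic.vcf synthetic.popmap.tsv
213 loci retained; F_ST=0.0111 D_est=0.0057 (tables at stats.*.csv)

$ slopeflow overlap synthetic.survey.csv
3 site-pair records, 3 percentile rows written to phenology.*.csv
```

`stats` applied the 2% pooled-MAF filter (300 → 213 loci: conditioned SNPs
are frequently rare in a sample of 65 diploids) and reports multilocus
F_ST ≈ 0.011 — low differentiation, as expected for adjacent demes of 1,000
diploids exchanging 1% of individuals per generation. The pairwise matrix
(`stats.pairwise_fst.csv`) shows the stepping-stone footprint: adjacent
pairs ≈ 0.005, the two-step pair ≈ 0.014:

```
,pop1,pop2,pop3
pop1,0.0,0.00498,0.01448
pop2,0.00498,0.0,0.00542
pop3,0.01448,0.00542,0.0
```

The survey table was generated with the default ~3 d/100 m phenological
delay, so Pianka overlap is lowest for the most separated pair
(`phenology.overlap.csv`: 0.875 and 0.913 for the adjacent pairs, 0.668 for
the 853 m extreme pair; adjacent-pair ordering fluctuates with Poisson
sampling noise at this delay).

Model selection against a simulated reference table works the same way from
the shell (`slopeflow abc-build`, `abc-select`, `abc-cv`, `abc-gof`,
`abc-estimate`) or from Python:

```python
import numpy as np
from slopeflow.abc import ABCModelChoice, build_reference_table
from slopeflow.demography import PriorSpec

table = build_reference_table(
    ["dn", "up", "ss", "am"], n_per_model=2000, prior=PriorSpec(),
    samples=np.array([23, 21, 21]), n_snps=200,
    rng=np.random.default_rng(1),
)
clf = ABCModelChoice(tol=0.005, method="mnlogistic").fit_table(table)
posterior = clf.posterior(observed_stats)   # -> per-model probabilities
```

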