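# clonarch

Clonal-architecture analytics for bulk-sequenced AML cohorts.

In acute myeloid leukemia, the *presence* of a driver mutation is only part of
the story: its clonal abundance (variant allele frequency, VAF), the order in
which drivers were acquired, and the topology of the clone tree (linear chain
vs branched subclones) all carry prognostic and pharmacological information
that binary mutation calls miss.  `clonarch` implements that analysis layer
for tabular cohort data — a patient table with overall survival, a somatic
variant table with raw VAFs and copy number, optionally a PyClone-style
mutation-cluster table and an ex vivo drug-response (AUC) matrix — and ships a
seeded synthetic-cohort generator with full ground truth so every stage can be
validated by parameter recovery.

It is written for computational hematology / cancer-genomics groups analyzing
aggregated bulk-sequencing cohorts.

## The statistics at the core

* **VAF correction.** Raw VAFs are put on a common clonal scale:
  `CCF = min(1, VAF · CN / m)` and corrected VAF `= CCF/2` (m = mutation
  multiplicity, default 1; hemizygous male-X sites use CN = 1).
* **High/low VAF thresholds** per gene: median split, a fixed `>30%` rule, and
  maximally selected rank statistics — the cutpoint μ maximizing the
  standardized two-sample log-rank statistic over admissible splits, with a
  permutation p-value that accounts for the selection.
* **Co-occurrence / epistasis.** Two-sided Fisher exact tests with
  Haldane–Anscombe-corrected odds ratios; Cohen's *d* for clinical features;
  triple-vs-double genotype hazard ratios; plain Bonferroni correction per
  scan family.
* **Acquisition order.** Within a patient, gene *a* precedes gene *b* when its
  corrected VAF is at least 5 percentage points higher (ties within 5 points
  are ambiguous).  Pooled pairwise wins feed a Bradley–Terry model,
  P(a before b) = p_a/(p_a+p_b), fit by minorization–maximization with Wald
  CIs on the log-ability scale.
* **Clone trees.** Clusters attach in descending CCF under two constraints:
  strict nesting (child below parent by ≥ z pooled SEs) and an
  uncertainty-aware pigeonhole rule (children's CCFs cannot exceed the
  parent's by more than ε plus z pooled SEs).  A cluster that can nest nowhere
  becomes a sibling — statistically indistinguishable CCFs are what force a
  *branched* call.  Heterogeneity: Shannon diversity over clone-exclusive
  fractions (nats), MATH score `100 · 1.4826 · MAD(VAF)/median(VAF)`, and
  mutation/clonal burden.
* **Survival.** Univariate Cox partial likelihood (Breslow ties, Efron
  optional) by Newton iteration, two-sided log-rank tests, Kaplan–Meier
  summaries (via lifelines).
* **Drug screen.** Per drug–gene pair with ≥ 5 mutated samples, VAF range
  ≥ 0.25 and AUC range ≥ 75: ordinary least squares of AUC on corrected VAF.
  Negative slope = VAF-dependent *sensitivity*, positive = *resistance*
  (p < 0.05, Bonferroni q < 0.1 flagged); plus binary mutant-vs-WT rank-sum
  scans and co-mutation-background screens.

## Worked example

```python
import numpy as np
from clonarch.simulate import SimConfig, simulate
from clonarch.ordering import pairwise_dominance, bt_rank

cfg = SimConfig(n_patients=500, seed=7, subset_probs={"de_novo": 1.0})
cohort, truth = simulate(cfg)
fit = bt_rank(pairwise_dominance(cohort, margin=0.05), min_patients=2)
print(fit.to_frame().head(3)[["unit", "ability", "rank"]])
```

prints

```
     unit   ability  rank
0    TET2  1.947301     1
1  DNMT3A  1.341552     2
2   U2AF1  0.962259     3
```

i.e. DNA-methylation and splicing drivers are ranked earliest-acquired —
the fitted log-abilities (sum-to-zero scale; higher = earlier) recover the
generative ordering with Spearman correlation 0.87 against the true ability
scores on this cohort.

The full analysis, as a sequence of narrative scripts writing tables under
`results/`:

```bash
python analysis/01_simulate_cohorts.py      # three study cohorts + ground truth
python analysis/02_cooccurrence_survival.py
python analysis/03_vaf_thresholds_survival.py
python analysis/04_mutation_order.py
python analysis/05_clonal_architecture.py
python analysis/06_drug_screen.py
python analysis/07_recovery_report.py       # recovery vs planted ground truth
```

The same stages are available from the shell over user-supplied tables via
the `clonarch` CLI (`clonarch simulate|cooccur|vaf-survival|ordering|
clonality|drugscreen|all`); each run writes a manifest (seed, input
checksums, row counts, warnings) sufficient to reproduce it.

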