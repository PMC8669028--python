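# Methods

This note documents the statistical models behind `clonarch`, the choices
made where the methodology was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter when reproducing results.

## VAF correction

Bulk sequencing reports the variant allele frequency (VAF): the fraction of
reads carrying the mutant allele.  To compare mutations across copy-number
states and sexes we convert to the cancer cell fraction

    CCF = min(1, VAF · CN / m),       corrected VAF = CCF / 2,

where CN is the total local copy number and m the mutation multiplicity.
Multiplicity defaults to 1 — a conservative, documented knob, since amplified
mutant alleles cannot be resolved from single-sample bulk data.  Missing CN
defaults to 2 on autosomes and to 1 on the non-pseudoautosomal X in males
(hemizygous).  CCFs above 1 are capped and flagged rather than rejected:
binomial read noise routinely pushes VAFs past their theoretical maximum.
The corrected VAF lives on the familiar heterozygous-diploid scale, so a
fully clonal het mutation sits at 0.5.

## High/low VAF thresholds

Three binning rules, per gene:

* **median** — high iff strictly above the per-gene median of corrected
  VAFs; exact-median values bin low.  Genes with one carrier are skipped.
* **fixed** — high iff strictly above a cutpoint (default 0.30 on the raw
  scale), the heuristic threshold in common clinical use.
* **maxstat** — maximally selected rank statistics.  We compute log-rank
  (Savage) scores `a_i = δ_i − Λ̂(t_i)` from the Nelson–Aalen cumulative
  hazard, then for each candidate cutpoint μ (midpoints between adjacent
  distinct VAFs, restricted to the 10th–90th VAF percentiles with each arm
  holding ≥ `min_prop` = 10% of patients) the standardized linear rank
  statistic of the low arm.  This equals the two-sample log-rank statistic
  with permutation-variance standardization and makes the scan O(n) per
  dataset.  The returned cutpoint maximizes |T|; its p-value permutes VAFs
  against survival and repeats the whole scan (default 10,000 draws,
  seeded), giving exact finite-sample control of the selection multiplicity.
  An asymptotic approximation is deliberately not the reference: the
  permutation version is seedable and exact at desk scale.

## Association statistics

Pairwise co-occurrence uses the two-sided Fisher exact test; the
odds-ratio point estimate applies the Haldane–Anscombe +0.5 correction when
any cell is zero (flagged).  Clinical effect sizes are Cohen's *d* with
pooled SD and a normal-approximation 95% CI.  Triple-genotype scans compare
carriers of all three mutations against carriers of exactly two (Cox PH).
Multiple testing uses plain Bonferroni, one scan table per family — chosen
deliberately over FDR-style procedures because it is the named method in
this analysis tradition; q = min(1, p · family size).

## Survival engine

Univariate Cox proportional hazards on a binary indicator is fit by Newton
iteration on the partial likelihood with Breslow tie handling (Efron
switchable).  Covariates are fixed effects; no frailty model is provided.
Wald 95% CIs come from the observed information; p-values from the
two-sided log-rank test (lifelines).  Zero events in one arm make the
partial likelihood monotone: the fit is flagged, β is capped at ±20, and
the CI bound on the event-free side is reported as 0 or ∞.  Kaplan–Meier
estimates (Greenwood variance, median survival) also come from lifelines;
on tie-free data the in-package Breslow fit and lifelines' Efron fit agree
to ≤ 1e-4, which the test suite uses as an independent cross-check.

## Mutation acquisition order

Within one patient, unit *a* (gene or functional category; the largest
corrected VAF per unit represents it) is called earlier than *b* when
`VAF_a − VAF_b ≥ margin`, boundary inclusive, with margin 0.05 by default
(configurable 0.01–0.10); differences inside the margin are ambiguous.
The boundary comparison carries a 1e-12 tolerance so IEEE-754
representation cannot flip a call at exactly 5 points.

Nonambiguous calls pool into a win matrix (one win per patient per ordered
pair) for a Bradley–Terry model, fit by the classical MM iteration to
tolerance 1e-8 (≤ 10,000 iterations; the log-likelihood is monotone across
iterations and asserted so).  Identifiability is fixed by a sum-to-zero
constraint on log-abilities — equivalent up to shift to a reference-unit
constraint and symmetric in the units.  Standard errors come from the
pseudo-inverse of the observed information (singular by construction along
the shift direction).  Complete separation (a unit that wins or loses every
comparison) adds 0.5 pseudo-observations to both directions of every
compared pair, flagged.  A disconnected comparison graph restricts the fit
to the largest connected component and reports the excluded units.

Ordering-based survival compares a-first vs b-first patients (ambiguous
excluded) with at least 5 patients per direction.  Power is intrinsically
limited: at realistic co-mutation frequencies even a 2,000-patient cohort
yields tens of orderable patients per pair, and VAF-inferred ordering
misclassification attenuates hazard ratios toward 1.  The analysis scripts
report this honestly rather than inflating planted effects.

## Clone trees and architecture

Input clusters come either from a PyClone-style loci table (mutation →
cluster, cellular prevalence; cluster SE from the provided std dev, or the
binomial fallback `sqrt(ccf(1−ccf)/depth)` flagged when absent) or from a
deterministic 1-D Gaussian-kernel mode clustering of per-variant CCFs
(bandwidth 0.04, modes merged below 0.10).  The stand-in clustering is a
simple, fully documented device — it does not attempt Dirichlet-process
inference, and because it sees only CCF values it cannot separate sibling
clones at indistinguishable prevalences (see limitations).

Trees are built greedily and deterministically: clusters sorted by
descending CCF (cluster-id tie-break), founder = maximum.  Each cluster
attaches to the deepest node satisfying

1. strict nesting: `CCF_parent − CCF_child ≥ z·sqrt(se_p² + se_c²)`
   (z = 1.96), and
2. the pigeonhole sum rule with the same statistical slack:
   `Σ children + candidate ≤ parent + ε + z·sqrt(se_p² + se_c²)` (ε = 0.05).

If no node passes both, the cluster becomes a sibling at the shallowest
node whose sum rule tolerates it; if none, the architecture is
*unresolved*.  Branched = any node with ≥ 2 children.  Giving the sum rule
the same uncertainty slack as the nesting rule is a deliberate design
choice: with ε alone, two statistically equal clusters (e.g. 0.5/0.5 under
a 0.9 founder) would be unplaceable even though the sibling topology is the
only biologically coherent reading.  This rule is a deterministic stand-in
for consensus-tree enumeration: patients for which both a chain and a
branch are consistent are resolved in favor of the deepest admissible
nesting, and may legitimately disagree with tools that enumerate all
models.

Heterogeneity metrics: mutation burden (variant count), clonal burden
(clusters with ≥ 1 member and CCF > 0.01 — a noise floor), median
mutations per clone, Shannon diversity in natural log over clone-exclusive
fractions (node CCF minus children's sum, clamped at 0, normalized; raw
CCF weights with a method flag when the tree is unresolved), and the MATH
score `100 · 1.4826 · MAD / median` over corrected VAFs (the
consistency-scaled MAD of the original MATH definition).

## Drug screen

Lower AUC = greater ex vivo sensitivity.  The binary scan compares mutant
vs wild-type AUC per drug–gene pair (two-sided Wilcoxon rank-sum, exact
null distribution at combined n ≤ 30; direction from the median
difference; Bonferroni q < 0.1).  The VAF screen regresses AUC on
corrected VAF across mutant samples only (wild-type samples carry no VAF),
restricted to pairs with n ≥ 5, ΔVAF ≥ 0.25 and ΔAUC ≥ 75 — heuristics
that require both a dynamic range of clonal abundance and of drug
response.  Two-sided slope p-values; sensitive/resistant calls at p < 0.05
with a Bonferroni q < 0.1 flag; both thresholds configurable.  The
context screen applies identical logic inside a co-mutation background
(samples mutated in both genes), labelled `background:target`.

## Synthetic cohort generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions the analyses assume.

Per patient: drivers are independent Bernoulli draws from panel
prevalences (patients with zero drivers redraw one gene, counted);
acquisition order is Plackett–Luce over per-gene ability scores, so the
downstream Bradley–Terry fit is correctly specified and recovery failures
indicate implementation bugs rather than model misspecification.  Clone
count is truncated Poisson (mean 3, max 5, capped by the mutation count);
the tree is a nested chain (each child 50–72% of its parent's CCF) or, with
probability 1 − `p_linear`, branched: the founder splits into two sibling
subclones taking *equal* shares of 75–92% of its CCF, extra clones chaining
below one sibling.  Equal sibling prevalences are deliberate: from a single
bulk sample, well-separated fractions always admit a nested chain, so the
only branched configuration identifiable at all is competing subclones at
statistically indistinguishable prevalences.  The generator therefore
represents the identifiable subset of branched biology, and architecture-
recovery results quantify performance on exactly that subset — not on
branched tumors whose topology single-sample bulk data cannot reveal.
Optional passenger variants (Poisson mean per patient, default 0; the WES
subcohort uses 8) populate clones the way whole-exome data would.

Mutations map to clones in acquisition order along the tree's topological
order, so the founder always carries the first-acquired driver.  Observed
VAFs are binomial read counts at Poisson depth (floor 30) after CN events
(rate 5%: CN 1/3/4) and male-X hemizygosity.  Survival is exponential with
log-hazard linear in configured binary features (mutation status, true
high-VAF, architecture, pairwise order, triple genotype) — proportional
hazards holds exactly, so Cox recovery is unbiased by construction —
with an independent exponential censoring clock calibrated to the target
censoring fraction.  Drug AUCs are `intercept + slope · observed VAF +
noise` for planted drug–gene pairs and baseline Gaussian noise otherwise,
on a 0–300-type scale.

What the generator does **not** emulate: relapse/longitudinal sampling,
mutational signatures, epistatic prevalence structure (genes are sampled
independently, so co-occurrence scans are null by construction), subclonal
copy-number architecture, and inter-study batch heterogeneity.  Passing
recovery tests therefore demonstrate correctness of the estimators under
their assumed models, not robustness to violations real aggregated cohorts
contain.

## Problem sizes and numerical conventions

Recovery analyses run at desk scale, chosen as the smallest sizes at which
the estimators are comfortably in their asymptotic regime: Bradley–Terry
recovery on 10 genes × 500 patients at depth 500; maxstat on n = 400 with
10,000 permutations and 200 null replicates of n = 60 with 400
permutations for the type-I error; Cox recovery at n = 1,000;
architecture recovery on 300 WES-style patients at depth 1,000; drug-screen
power/size over 200 replicates of n = 10.  Fisher p-values are checked
against a hypergeometric tail-sum enumeration over canonical orbit
representatives (row/column swap and transpose symmetries) of every 2×2
table with total n ≤ 60.

Conventions: Breslow ties by default; dominance boundary inclusive with a
1e-12 float tolerance; exact-median bins low and the 30% rule is a strict
inequality; BT MM tolerance 1e-8; tree building is invariant to input row
order; all random draws flow from explicit seeds (per-stage streams keyed
by stage name, so adding a stage never perturbs another's randomness).

## Known limitations

* VAF-inferred ordering and clonality assume a single dominant sampling of
  the tumor; spatially or temporally separated subclones can violate it.
* CCF-only clustering merges equal-prevalence siblings; branched calls
  need mutation-level cluster memberships from an upstream tool.
* The clone-tree rule resolves chain/branch ambiguity deterministically and
  may disagree with consensus-enumeration tools on ambiguous patients.
* Ordering-based survival is weakly powered at realistic co-mutation
  frequencies; hazard ratios are attenuated by call misclassification.
* The Wilcoxon exact method switches to the asymptotic approximation above
  combined n = 30; with heavy ties the exact method is unavailable.
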