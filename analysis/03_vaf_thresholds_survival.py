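"""VAF binning, clinical effect sizes and survival by VAF threshold.

Per gene: median split of corrected VAFs; Cohen's d of clinical features
between high- and low-VAF carriers; a maximally selected rank-statistic
cutpoint against overall survival with a permutation p-value; and the Cox
hazard ratio of high vs low VAF at that cutpoint.
Writes results/vaf_effects.tsv and results/vaf_survival.tsv.
"""

import dataclasses
import warnings

import pandas as pd

from common import RESULTS, stage_seed

from clonarch.assoc import clinical_effects, effects_to_frame
from clonarch.cohort import filter_subset, max_vaf_per_gene, read_cohort
from clonarch.errors import ClonarchError
from clonarch.survival import cox_univariate
from clonarch.vaf import bin_by_median, maxstat_cutpoint

MIN_MUTATED = 30   # genes with fewer mutated patients are too sparse to bin

if __name__ == "__main__":
    cohort = filter_subset(
        read_cohort(RESULTS / "cohort_main" / "patients.tsv",
                    RESULTS / "cohort_main" / "variants.tsv"),
        "de_novo")
    vafs = max_vaf_per_gene(cohort, scale="corrected")
    counts = vafs.groupby("gene").size()
    genes = sorted(counts[counts >= MIN_MUTATED].index)
    print(f"{len(genes)} genes with >= {MIN_MUTATED} mutated de novo patients")

    binned, _ = bin_by_median(vafs[vafs["gene"].isin(genes)])
    effects = clinical_effects(cohort, "high_vs_low_vaf", units=genes,
                               vaf_bins=binned)
    effects += clinical_effects(cohort, "mutant_vs_wt", units=genes)
    eff = effects_to_frame(effects).sort_values("q_value")
    eff.to_csv(RESULTS / "vaf_effects.tsv", sep="\t", index=False)
    sig = eff[eff["q_value"] < 0.2]
    print(f"{len(sig)} clinical-feature associations at q<0.2")
    for _, r in sig.head(5).iterrows():
        print(f"  {r.grouping} / {r.feature}: d={r.cohens_d:.2f} (q={r.q_value:.3g})")

    surv = cohort.patients.set_index("patient_id")[["os_time", "os_event"]].dropna()
    rows = []
    for gene in genes:
        sub = (vafs[vafs["gene"] == gene].set_index("patient_id")
               .join(surv, how="inner").dropna())
        if len(sub) < 10 or sub["vaf"].nunique() < 2:
            continue
        try:
            thr = maxstat_cutpoint(sub["vaf"].to_numpy(), sub["os_time"].to_numpy(),
                                   sub["os_event"].to_numpy(), n_perm=2000,
                                   seed=stage_seed(f"maxstat:{gene}"), gene=gene)
        except ClonarchError as exc:
            warnings.warn(f"{gene}: {exc}")
            continue
        grp = (sub["vaf"] > thr.cutpoint).astype(int)
        res = cox_univariate(sub["os_time"], sub["os_event"], grp,
                             comparison=f"{gene} high vs low VAF")
        rows.append({"gene": gene, "cutpoint": thr.cutpoint,
                     "maxstat_p": thr.p_value, "n_high": thr.n_above,
                     "n_low": thr.n_below,
                     **{k: v for k, v in dataclasses.asdict(res).items()
                        if k in ("hr", "ci_low", "ci_high", "logrank_p")}})
    out = pd.DataFrame(rows).sort_values("maxstat_p")
    out.to_csv(RESULTS / "vaf_survival.tsv", sep="\t", index=False)
    hits = out[out["maxstat_p"] < 0.05]
    print(f"{len(hits)}/{len(out)} genes with a survival-stratifying VAF cutpoint "
          f"(permutation p<0.05)")
    for _, r in hits.iterrows():
        direction = "adverse" if r["hr"] > 1 else "favorable"
        print(f"  {r.gene}: cut={r.cutpoint:.3f} HR={r.hr:.2f} ({direction})")
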