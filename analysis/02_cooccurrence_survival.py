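"""Mutation co-occurrence, pairwise epistasis and triple-genotype survival.

Scans the de novo main cohort for co-occurring / mutually exclusive gene
pairs (Fisher exact + Bonferroni) and for 3-gene genotypes whose carriers
fare differently from exactly-double-mutated patients (Cox PH).
Writes results/cooccurrence.tsv and results/triple_genotypes.tsv.
"""

from common import RESULTS

from clonarch.assoc import cooccurrence_scan, pair_associations_to_frame, triple_genotype_scan
from clonarch.cohort import filter_subset, read_cohort

if __name__ == "__main__":
    cohort = filter_subset(
        read_cohort(RESULTS / "cohort_main" / "patients.tsv",
                    RESULTS / "cohort_main" / "variants.tsv"),
        "de_novo")
    print(f"de novo analysis set: {cohort.n_patients} patients")

    pairs = cooccurrence_scan(cohort, min_comut=5)
    pair_df = pair_associations_to_frame(pairs).sort_values("p_value")
    pair_df.to_csv(RESULTS / "cooccurrence.tsv", sep="\t", index=False)
    sig = pair_df[pair_df["q_value"] < 0.05]
    print(f"{len(pair_df)} gene pairs tested; {len(sig)} significant at q<0.05")
    if len(sig):
        top = sig.iloc[0]
        print(f"  strongest: {top.gene_a}:{top.gene_b} OR={top.odds_ratio:.2f} "
              f"({top.direction}, q={top.q_value:.3g})")

    triples = triple_genotype_scan(cohort, min_triple=10).sort_values("p")
    triples.to_csv(RESULTS / "triple_genotypes.tsv", sep="\t", index=False)
    print(f"{len(triples)} triple genotypes with >=10 carriers")
    if len(triples):
        top = triples.iloc[0]
        print(f"  strongest: {top.genotype} HR={top.hr:.2f} "
              f"[{top.ci_low:.2f}, {top.ci_high:.2f}] p={top.p:.3g}")
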