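"""Ex vivo drug-sensitivity screens on the drug subcohort.

Runs the binary mutant-vs-WT comparison, the VAF-dependent regression
screen with the sample/range inclusion filters, and a co-mutation
background screen (FLT3-ITD VAF within DNMT3A-mutant samples).
Writes results/drug_binary.tsv, results/drug_vaf_screen.tsv and
results/drug_context_screen.tsv.
"""

from common import RESULTS

from clonarch.cohort import read_cohort
from clonarch.drugs import binary_drug_scan, context_vaf_screen, screen_to_frame, vaf_screen

if __name__ == "__main__":
    cohort = read_cohort(RESULTS / "cohort_drug" / "patients.tsv",
                         RESULTS / "cohort_drug" / "variants.tsv",
                         drug_table=RESULTS / "cohort_drug" / "drugs.tsv")
    n_drugs = cohort.drugs["drug"].nunique()
    print(f"{cohort.n_patients} samples x {n_drugs} drugs")

    binary = binary_drug_scan(cohort, min_mut=5)
    binary.to_csv(RESULTS / "drug_binary.tsv", sep="\t", index=False)
    print(f"binary scan: {len(binary)} drug-gene pairs, "
          f"{(binary['call'] != 'none').sum()} calls at q<0.1")

    screen = vaf_screen(cohort, min_n=5, min_dvaf=0.25, min_dauc=75.0)
    screen_to_frame(screen).to_csv(RESULTS / "drug_vaf_screen.tsv",
                                   sep="\t", index=False)
    print(f"VAF screen: {len(screen)} pairs past filters")
    for r in screen:
        if r.call != "none":
            print(f"  {r.drug}/{r.unit}: slope={r.slope:.0f} AUC per unit VAF, "
                  f"r2={r.r2:.2f}, p={r.p:.3g} -> {r.call}")

    context = context_vaf_screen(cohort, "DNMT3A", "FLT3-ITD", min_n=5)
    screen_to_frame(context).to_csv(RESULTS / "drug_context_screen.tsv",
                                    sep="\t", index=False)
    for r in context:
        print(f"  context {r.unit}/{r.drug}: slope={r.slope:.0f}, "
              f"p={r.p:.3g} -> {r.call}")
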