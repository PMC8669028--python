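"""Generate the three synthetic study cohorts and write their tables.

Outputs (under results/):
  cohort_main/  patients.tsv variants.tsv truth.tsv   — 2000-patient panel cohort
  cohort_wes/   patients.tsv variants.tsv truth.tsv   — 500-patient WES subcohort
  cohort_drug/  patients.tsv variants.tsv drugs.tsv truth.tsv — 202-sample screen
"""

from common import RESULTS, drug_cohort_config, main_cohort_config, wes_cohort_config

from clonarch.cohort import write_cohort
from clonarch.simulate import simulate, write_pyclone_table, write_truth


def emit(name, config, pyclone=False):
    out = RESULTS / name
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate(config)
    write_cohort(cohort, out / "patients.tsv", out / "variants.tsv")
    if cohort.drugs is not None:
        cohort.drugs.to_csv(out / "drugs.tsv", sep="\t", index=False)
    if pyclone:
        write_pyclone_table(cohort, truth, out / "pyclone_loci.tsv")
    write_truth(truth, out / "truth.tsv")
    n_denovo = int((cohort.patients["subset"] == "de_novo").sum())
    print(f"{name}: {cohort.n_patients} patients ({n_denovo} de novo), "
          f"{len(cohort.variants)} variants")
    return cohort


if __name__ == "__main__":
    emit("cohort_main", main_cohort_config())
    emit("cohort_wes", wes_cohort_config(), pyclone=True)
    emit("cohort_drug", drug_cohort_config())
    print("cohort tables written under", RESULTS)
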