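"""Ground-truth recovery report: how well did each stage recover what the
generator planted?  Writes results/recovery.json.
"""

import json

from common import RESULTS, drug_cohort_config, main_cohort_config, wes_cohort_config

from clonarch.clonality import build_tree
from clonarch.drugs import vaf_screen
from clonarch.ordering import bt_rank, pairwise_dominance
from clonarch.simulate import clonal_models_from_truth, simulate, truth_check

if __name__ == "__main__":
    report = {}

    cohort, truth = simulate(main_cohort_config())
    fit = bt_rank(pairwise_dominance(cohort, margin=0.05), min_patients=2)
    report.update(truth_check(cohort, truth, bt_ranking=fit))

    wes, wes_truth = simulate(wes_cohort_config())
    models = clonal_models_from_truth(wes, wes_truth)
    for m in models.values():
        build_tree(m)
    report.update(truth_check(wes, wes_truth, arch_models=models))

    drug, drug_truth = simulate(drug_cohort_config())
    report.update(truth_check(drug, drug_truth,
                              screen_results=vaf_screen(drug)))

    with open(RESULTS / "recovery.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    for key, val in report.items():
        print(f"{key}: {val}")
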