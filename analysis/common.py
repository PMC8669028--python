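"""Shared study configuration for the numbered analysis scripts.

Three synthetic cohorts emulate the data structure of an aggregated AML
study: a large clinically annotated main cohort (targeted-panel depth),
a whole-exome subcohort for clonal modeling (passenger variants included,
higher depth), and an ex vivo drug-screen subcohort.  Effects planted in
the generator are what the downstream scripts aim to recover; they are
fixed here once so every script sees the same study.
"""

from __future__ import annotations

import sys
import zlib
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

sys.path.insert(0, str(ROOT / "src"))

from clonarch.simulate import SimConfig  # noqa: E402

SEED = 20260926
PANEL_GENES = None  # filled lazily from the default panel


def stage_seed(stage: str, seed: int = SEED) -> int:
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def main_cohort_config(seed: int = SEED) -> SimConfig:
    """Clinically annotated main cohort (targeted sequencing)."""
    return SimConfig(
        n_patients=2000,
        depth_mean=500.0,
        censor_frac=0.35,
        survival_effects=[
            ("vafgt:NRAS:0.30", float(np.log(1.6))),     # high NRAS VAF is adverse
            ("vafgt:GATA2:0.15", float(np.log(0.4))),    # high GATA2 VAF is favorable
            ("order:DNMT3A:NPM1", float(np.log(1.5))),   # epigenetic-first ordering
            ("triple:DNMT3A:FLT3-ITD:NPM1", float(np.log(1.8))),
        ],
        clinical_effects=[("TP53", "pb_blast_pct", 0.6), ("IDH2", "ldh", -0.5)],
        subset_probs={"de_novo": 0.72, "secondary": 0.18, "therapy_related": 0.10},
        seed=stage_seed("main", seed),
    )


def wes_cohort_config(seed: int = SEED) -> SimConfig:
    """Whole-exome subcohort for clonal architecture modeling."""
    return SimConfig(
        n_patients=500,
        depth_mean=1000.0,
        passenger_mut_mean=8.0,
        p_linear=0.65,
        censor_frac=0.25,
        survival_effects=[("arch:branched", float(np.log(0.55)))],
        subset_probs={"de_novo": 1.0},
        seed=stage_seed("wes", seed),
    )


def drug_cohort_config(seed: int = SEED) -> SimConfig:
    """Ex vivo drug-screen subcohort (AUC on a 0-300-type scale)."""
    return SimConfig(
        n_patients=202,
        depth_mean=500.0,
        drugs=["cytarabine", "quizartinib", "sorafenib"],
        drug_effects=[
            ("ponatinib", "IDH1", -363.0, 290.0, 25.0),   # VAF-dependent sensitivity
            ("pelitinib", "NRAS", 419.0, 80.0, 25.0),     # VAF-dependent resistance
            ("crizotinib", "FLT3-ITD", 350.0, 90.0, 25.0),
        ],
        subset_probs={"de_novo": 1.0},
        seed=stage_seed("drug", seed),
    )
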