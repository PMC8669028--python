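import numpy as np
import pandas as pd
import pytest

from clonarch.cohort import PATIENT_COLUMNS, cohort_from_frames


def patient_row(pid, **kw):
    row = {c: np.nan for c in PATIENT_COLUMNS}
    row.update(patient_id=pid, cohort="fix", subset="de_novo", sex="F",
               os_time=365.0, os_event=1, eln_risk="")
    row.update(kw)
    return row


def variant_row(pid, gene, vaf, variant_id=None, chrom="1", total_cn=2, multiplicity=1):
    return {
        "patient_id": pid, "gene": gene,
        "variant_id": variant_id or f"{pid}_{gene}",
        "chrom": chrom, "raw_vaf": vaf, "total_cn": total_cn,
        "multiplicity": multiplicity,
    }


def build_cohort(patient_rows, variant_rows, drugs=None):
    return cohort_from_frames(
        pd.DataFrame(patient_rows), pd.DataFrame(variant_rows),
        drugs=pd.DataFrame(drugs) if drugs is not None else None,
    )


@pytest.fixture
def tiny_cohort():
    """Two patients, three variants — the minimal valid cohort."""
    patients = [patient_row("p1", sex="M"), patient_row("p2")]
    variants = [
        variant_row("p1", "DNMT3A", 0.40),
        variant_row("p1", "NPM1", 0.20),
        variant_row("p2", "TP53", 0.35),
    ]
    return build_cohort(patients, variants)


@pytest.fixture
def mixed_subset_cohort():
    """3 de novo + 2 secondary patients."""
    patients = [
        patient_row("d1"), patient_row("d2"), patient_row("d3"),
        patient_row("s1", subset="secondary"), patient_row("s2", subset="secondary"),
    ]
    variants = [variant_row(p, "NPM1", 0.3) for p in ("d1", "d2", "d3", "s1", "s2")]
    return build_cohort(patients, variants)
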