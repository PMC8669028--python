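"""Cohort assembly: patient/variant tables, validation, and basic reshaping.

Input is the post-curation tabular form of an AML cohort: one delimited
table of patients (clinical covariates + overall survival) and one of
somatic variants (gene, raw VAF, copy number).  Tables are UTF-8 and
tab-delimited by default; a comma fallback is detected from the header.
Unknown columns are preserved as passthrough metadata.

Row-level schema violations (negative survival time, out-of-range
percentages or VAFs, unknown enum labels) are collected into a rejects
report rather than dropped silently; structural violations (missing
mandatory columns, duplicate variant ids, variants referencing unknown
patients) raise errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _config
from .errors import IntegrityError, SchemaError
from .vaf import correct_vaf_frame

PATIENT_COLUMNS = [
    "patient_id", "cohort", "subset", "sex", "age", "wbc", "hemoglobin",
    "platelets", "ldh", "bm_blast_pct", "pb_blast_pct", "os_time",
    "os_event", "eln_risk",
]
VARIANT_COLUMNS = ["patient_id", "gene", "variant_id", "chrom", "raw_vaf", "total_cn", "multiplicity"]

SUBSETS = {"de_novo", "secondary", "therapy_related", "unknown"}
SEXES = {"M", "F", "unknown"}

CLINICAL_FEATURES = ["age", "wbc", "hemoglobin", "platelets", "ldh", "bm_blast_pct", "pb_blast_pct"]


@dataclass
class PatientRecord:
    patient_id: str
    cohort: str = ""
    subset: str = "unknown"
    sex: str = "unknown"
    age: float = np.nan
    wbc: float = np.nan
    hemoglobin: float = np.nan
    platelets: float = np.nan
    ldh: float = np.nan
    bm_blast_pct: float = np.nan
    pb_blast_pct: float = np.nan
    os_time: float = np.nan
    os_event: int = 0
    eln_risk: str = ""


@dataclass
class VariantCall:
    patient_id: str
    gene: str
    variant_id: str
    chrom: str = "1"
    raw_vaf: float = np.nan
    total_cn: float | None = None
    multiplicity: int = 1
    is_x_nonpar: bool = False
    ccf: float = np.nan
    corrected_vaf: float = np.nan


@dataclass
class Cohort:
    """Validated cohort: patients + variants (+ optional drug matrix / clones)."""

    patients: pd.DataFrame
    variants: pd.DataFrame
    drugs: pd.DataFrame | None = None          # long form: patient_id, drug, auc
    clones: dict | None = None                 # patient_id -> ClonalModel
    category_map: dict = field(default_factory=lambda: dict(_config.DEFAULT_CATEGORY_MAP))
    settings: dict = field(default_factory=lambda: dict(_config.DEFAULT_SETTINGS))
    rejects: dict = field(default_factory=dict)  # table name -> rejected rows

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def genes(self) -> list[str]:
        return sorted(self.variants["gene"].unique())

    def patient_ids(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table; tab by default, comma detected from header."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"patient_id": str, "variant_id": str}, encoding="utf-8")


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing mandatory column(s): {', '.join(missing)}")


def _validate_patients(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    bad = pd.Series(False, index=df.index)
    reasons = pd.Series("", index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad, reasons
        mask = mask.fillna(False)
        reasons = reasons.where(~(mask & ~bad), reason)
        bad = bad | mask

    flag(pd.to_numeric(df["os_time"], errors="coerce") < 0, "os_time < 0")
    for col in ("bm_blast_pct", "pb_blast_pct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        flag((vals < 0) | (vals > 100), f"{col} outside [0, 100]")
    flag(~df["subset"].fillna("unknown").isin(SUBSETS), "unknown subset label")
    flag(~df["sex"].fillna("unknown").isin(SEXES), "unknown sex label")
    flag(~df["os_event"].isin([0, 1]) & df["os_event"].notna(), "os_event not in {0,1}")
    rejects = df[bad].assign(reject_reason=reasons[bad])
    return df[~bad].reset_index(drop=True), rejects.reset_index(drop=True)


def _validate_variants(df: pd.DataFrame, patient_ids: set[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    dup = df.duplicated(subset=["patient_id", "variant_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "variant_id"]].drop_duplicates().values.tolist()
        raise IntegrityError(f"duplicate (patient_id, variant_id) pairs: {pairs}")
    orphan = ~df["patient_id"].isin(patient_ids)
    if orphan.any():
        raise IntegrityError(
            f"variants reference unknown patients: {sorted(df.loc[orphan, 'patient_id'].unique())}"
        )
    vaf = pd.to_numeric(df["raw_vaf"], errors="coerce")
    bad = (vaf < 0) | (vaf > 1) | vaf.isna()
    rejects = df[bad].assign(reject_reason="raw_vaf outside [0, 1]")
    return df[~bad].reset_index(drop=True), rejects.reset_index(drop=True)


def cohort_from_frames(
    patients: pd.DataFrame,
    variants: pd.DataFrame,
    config: dict | None = None,
    drugs: pd.DataFrame | None = None,
) -> Cohort:
    """Validate and assemble a cohort from in-memory tables."""
    cfg = config if config is not None else _config.load_config(None)
    _require_columns(patients, PATIENT_COLUMNS, "patient")
    _require_columns(variants, [c for c in VARIANT_COLUMNS if c != "multiplicity"], "variant")
    variants = variants.copy()
    if "multiplicity" not in variants.columns:
        variants["multiplicity"] = 1

    patients, patient_rejects = _validate_patients(patients)
    variants, variant_rejects = _validate_variants(variants, set(patients["patient_id"]))

    sex_by_patient = patients.set_index("patient_id")["sex"]
    variants = correct_vaf_frame(variants, sex_by_patient)

    return Cohort(
        patients=patients,
        variants=variants,
        drugs=drugs,
        category_map=cfg["category_map"],
        settings=cfg["settings"],
        rejects={"patients": patient_rejects, "variants": variant_rejects},
    )


def read_cohort(
    patient_table: str | Path,
    variant_table: str | Path,
    config: str | Path | dict | None = None,
    drug_table: str | Path | None = None,
) -> Cohort:
    """Read, validate and assemble a cohort; corrected VAFs are computed."""
    cfg = config if isinstance(config, dict) else _config.load_config(config)
    patients = _read_table(patient_table)
    variants = _read_table(variant_table)
    cohort = cohort_from_frames(patients, variants, config=cfg)
    if drug_table is not None:
        cohort.drugs = read_drug_matrix(drug_table, set(cohort.patients["patient_id"]))
    return cohort


def read_drug_matrix(path: str | Path, patient_ids: set[str] | None = None) -> pd.DataFrame:
    """Read a drug-response table, wide (patient x drug) or long, to long form."""
    df = _read_table(path)
    if {"patient_id", "drug", "auc"}.issubset(df.columns):
        long = df[["patient_id", "drug", "auc"]].copy()
    else:
        if "patient_id" not in df.columns:
            raise SchemaError("drug table missing mandatory column(s): patient_id")
        long = df.melt(id_vars="patient_id", var_name="drug", value_name="auc")
    long = long.dropna(subset=["auc"]).reset_index(drop=True)
    if (long["auc"] < 0).any():
        raise SchemaError("negative AUC values in drug table")
    if patient_ids is not None:
        long = long[long["patient_id"].isin(patient_ids)].reset_index(drop=True)
    return long


def write_cohort(cohort: Cohort, patient_table: str | Path, variant_table: str | Path) -> None:
    """Write patient and variant tables as TSV (round-trips typed fields)."""
    cohort.patients.to_csv(patient_table, sep="\t", index=False)
    cohort.variants.to_csv(variant_table, sep="\t", index=False)


def filter_subset(cohort: Cohort, subset: str) -> Cohort:
    """Restrict the cohort to one disease subset (idempotent)."""
    if subset not in SUBSETS:
        raise SchemaError(f"unknown subset label {subset!r}")
    keep = cohort.patients["subset"] == subset
    if not keep.any():
        warnings.warn(f"filter_subset({subset!r}): no patients match")
    patients = cohort.patients[keep].reset_index(drop=True)
    ids = set(patients["patient_id"])
    variants = cohort.variants[cohort.variants["patient_id"].isin(ids)].reset_index(drop=True)
    drugs = None
    if cohort.drugs is not None:
        drugs = cohort.drugs[cohort.drugs["patient_id"].isin(ids)].reset_index(drop=True)
    clones = None
    if cohort.clones is not None:
        clones = {pid: m for pid, m in cohort.clones.items() if pid in ids}
    return Cohort(
        patients=patients,
        variants=variants,
        drugs=drugs,
        clones=clones,
        category_map=cohort.category_map,
        settings=cohort.settings,
        rejects=cohort.rejects,
    )


def max_vaf_per_gene(cohort: Cohort, scale: str = "corrected", unit: str = "gene") -> pd.DataFrame:
    """One row per (patient, unit) carrying the unit's largest VAF.

    For patients with several variants in one gene (or functional
    category), only the largest VAF represents the unit.  Ties break
    deterministically on lexicographic variant_id.  ``scale`` selects the
    ``corrected_vaf`` (het-autosomal, [0, 0.5]) or ``ccf`` column.
    """
    if scale not in ("corrected", "ccf"):
        raise SchemaError(f"unknown scale {scale!r}")
    if unit not in ("gene", "category"):
        raise SchemaError(f"unknown unit {unit!r}")
    col = "corrected_vaf" if scale == "corrected" else "ccf"
    df = cohort.variants[["patient_id", "gene", "variant_id", col]].copy()
    if unit == "category":
        df["gene"] = df["gene"].map(lambda g: _config.category_of(g, cohort.category_map))
    df = df.sort_values(
        ["patient_id", "gene", col, "variant_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    out = df.groupby(["patient_id", "gene"], sort=True, as_index=False).first()
    return out.rename(columns={col: "vaf"})[["patient_id", "gene", "vaf"]]


def mutation_matrix(cohort: Cohort, genes: list[str] | None = None) -> pd.DataFrame:
    """Binary patient x gene mutation indicator matrix (all patients kept)."""
    genes = genes if genes is not None else cohort.genes
    mat = pd.DataFrame(0, index=cohort.patient_ids(), columns=genes, dtype=int)
    hits = cohort.variants[cohort.variants["gene"].isin(genes)]
    for gene, sub in hits.groupby("gene"):
        mat.loc[mat.index.isin(sub["patient_id"]), gene] = 1
    mat.index.name = "patient_id"
    return mat
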