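"""Configuration: gene -> functional-category map and analysis knobs.

The default category map groups recurrently mutated AML genes into the
functional classes used throughout the ordering and multi-hit analyses
(DNA methylation, chromatin/cohesin, transcription factors, splicing,
NPM1, RAS/RTK signaling, tumor suppressors).  The assignments are the
field-standard ones; they are provisional and fully overridable through
the YAML config (``category_map:`` section).

FLT3-ITD and FLT3-TKD are carried as distinct gene symbols because their
clinical behaviour differs throughout the analyses.
"""

from __future__ import annotations

from pathlib import Path

import yaml

CATEGORIES = (
    "dna_methylation",
    "chromatin_cohesin",
    "transcription_factor",
    "splicing",
    "npm1",
    "ras_rtk_signaling",
    "tumor_suppressor",
    "other",
)

DEFAULT_CATEGORY_MAP: dict[str, str] = {
    # DNA methylation
    "DNMT3A": "dna_methylation",
    "TET2": "dna_methylation",
    "IDH1": "dna_methylation",
    "IDH2": "dna_methylation",
    # chromatin remodeling + cohesin complex
    "ASXL1": "chromatin_cohesin",
    "EZH2": "chromatin_cohesin",
    "BCOR": "chromatin_cohesin",
    "KMT2A": "chromatin_cohesin",
    "RAD21": "chromatin_cohesin",
    "STAG2": "chromatin_cohesin",
    "SMC1A": "chromatin_cohesin",
    "SMC3": "chromatin_cohesin",
    # transcription factors
    "RUNX1": "transcription_factor",
    "CEBPA": "transcription_factor",
    "GATA2": "transcription_factor",
    "ETV6": "transcription_factor",
    # spliceosome
    "SRSF2": "splicing",
    "SF3B1": "splicing",
    "U2AF1": "splicing",
    "ZRSR2": "splicing",
    # NPM1 is its own class
    "NPM1": "npm1",
    # RAS/RTK signaling
    "FLT3-ITD": "ras_rtk_signaling",
    "FLT3-TKD": "ras_rtk_signaling",
    "FLT3": "ras_rtk_signaling",
    "NRAS": "ras_rtk_signaling",
    "KRAS": "ras_rtk_signaling",
    "PTPN11": "ras_rtk_signaling",
    "CBL": "ras_rtk_signaling",
    "NF1": "ras_rtk_signaling",
    "KIT": "ras_rtk_signaling",
    "JAK2": "ras_rtk_signaling",
    # tumor suppressors
    "TP53": "tumor_suppressor",
    "WT1": "tumor_suppressor",
    "PHF6": "tumor_suppressor",
}

#: analysis knobs with their defaults; every key is overridable from YAML
DEFAULT_SETTINGS: dict = {
    "dominance_margin": 0.05,       # VAF points a mutation must lead by to be "earlier"
    "fixed_vaf_cutpoint": 0.30,     # heuristic high-VAF threshold (raw scale, strict >)
    "maxstat_min_prop": 0.10,       # minimum fraction of patients on each cutpoint side
    "maxstat_n_perm": 10000,        # permutations for the maxstat p-value
    "min_comut": 5,                 # pairwise co-occurrence floor
    "min_triple": 10,               # triple-genotype floor
    "min_per_arm": 5,               # ordering-survival per-direction floor
    "screen_min_n": 5,              # drug screen: mutated samples with drug data
    "screen_min_dvaf": 0.25,        # drug screen: required VAF dynamic range
    "screen_min_dauc": 75.0,        # drug screen: required AUC dynamic range
    "tree_z": 1.96,                 # clone-tree nesting margin in pooled-SE units
    "tree_eps": 0.05,               # clone-tree pigeonhole slack (CCF units)
}


def category_of(gene: str, category_map: dict[str, str] | None = None) -> str:
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    return cmap.get(gene, "other")


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config and merge it over the defaults.

    Recognised top-level keys: ``category_map`` (gene -> category),
    ``settings`` (any key of :data:`DEFAULT_SETTINGS`), ``seed``.
    Unknown settings keys raise ``KeyError`` so typos do not pass silently.
    """
    cfg = {
        "category_map": dict(DEFAULT_CATEGORY_MAP),
        "settings": dict(DEFAULT_SETTINGS),
        "seed": None,
    }
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cmap = user.get("category_map", {})
    for gene, cat in cmap.items():
        if cat not in CATEGORIES:
            raise KeyError(f"unknown category {cat!r} for gene {gene!r}")
        cfg["category_map"][gene] = cat
    for key, val in user.get("settings", {}).items():
        if key not in DEFAULT_SETTINGS:
            raise KeyError(f"unknown setting {key!r}")
        cfg["settings"][key] = val
    if "seed" in user:
        cfg["seed"] = user["seed"]
    return cfg
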