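"""Binary-genotype association statistics.

Pairwise co-occurrence / mutual exclusivity (two-sided Fisher exact test
with Haldane-Anscombe corrected odds ratios on zero cells), clinical
effect sizes (Cohen's d with pooled SD), triple-vs-double genotype
survival scans, and multi-hit (>= 2 mutations per gene or category)
comparisons.  Multiple testing is controlled by plain Bonferroni
correction, one scan table = one family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CLINICAL_FEATURES, Cohort, mutation_matrix
from .config import category_of
from .errors import ParameterError
from .survival import SurvivalResult, cox_univariate

Z95 = 1.959963984540054


@dataclass
class PairAssociation:
    gene_a: str
    gene_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_value: float
    q_value: float
    direction: str          # co_occurring | mutually_exclusive
    zero_cell: bool = False


@dataclass
class EffectSize:
    grouping: str
    feature: str
    cohens_d: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    p_value: float = np.nan
    q_value: float = np.nan


def bonferroni(p_values) -> np.ndarray:
    """q = min(1, p * family size); the family is the supplied vector."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def fisher_or(n11: int, n10: int, n01: int, n00: int) -> tuple[float, float, bool]:
    """Two-sided Fisher exact p and odds ratio for one 2x2 table.

    The point-estimate OR uses the Haldane-Anscombe +0.5 correction when
    any cell is zero (flagged); the p-value is the exact conditional one.
    """
    table = np.array([[n11, n10], [n01, n00]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    zero = (table == 0).any()
    if zero:
        a, b, c, d = (x + 0.5 for x in (n11, n10, n01, n00))
    else:
        a, b, c, d = float(n11), float(n10), float(n01), float(n00)
    return p, (a * d) / (b * c), bool(zero)


def cooccurrence_scan(
    cohort: Cohort, genes: list[str] | None = None, min_comut: int = 5
) -> list[PairAssociation]:
    """Co-occurrence / mutual-exclusivity scan over gene pairs.

    Pairs with fewer than ``min_comut`` co-mutated patients are not
    tested.  q-values are Bonferroni over the tested pairs.
    """
    genes = genes if genes is not None else cohort.genes
    missing = [g for g in genes if g not in cohort.genes]
    for g in missing:
        warnings.warn(f"cooccurrence_scan: gene {g} absent from cohort, skipped")
    genes = [g for g in genes if g in cohort.genes]
    mat = mutation_matrix(cohort, genes)
    rows = []
    for ga, gb in combinations(genes, 2):
        a, b = mat[ga].to_numpy(), mat[gb].to_numpy()
        n11 = int(((a == 1) & (b == 1)).sum())
        if n11 < min_comut:
            continue
        n10 = int(((a == 1) & (b == 0)).sum())
        n01 = int(((a == 0) & (b == 1)).sum())
        n00 = int(((a == 0) & (b == 0)).sum())
        p, orr, zero = fisher_or(n11, n10, n01, n00)
        rows.append(PairAssociation(
            gene_a=ga, gene_b=gb, n11=n11, n10=n10, n01=n01, n00=n00,
            odds_ratio=orr, p_value=p, q_value=np.nan,
            direction="co_occurring" if orr >= 1.0 else "mutually_exclusive",
            zero_cell=zero,
        ))
    if rows:
        qs = bonferroni([r.p_value for r in rows])
        for r, q in zip(rows, qs):
            r.q_value = float(q)
    return rows


def cohens_d(x1, x2) -> tuple[float, float, float]:
    """Cohen's d (pooled SD) with a normal-approximation 95% CI."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ParameterError("Cohen's d needs >= 2 observations per arm")
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0, 0.0, 0.0
    d = (x1.mean() - x2.mean()) / np.sqrt(sp2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2)))
    return float(d), float(d - Z95 * se), float(d + Z95 * se)


def _two_arm_masks(cohort: Cohort, grouping: str, unit: str, vaf_bins: pd.DataFrame | None):
    """Patient-level (arm1, arm2) boolean masks for a grouping rule."""
    pids = cohort.patients["patient_id"]
    if grouping == "mutant_vs_wt":
        mutated = set(cohort.variants.loc[cohort.variants["gene"] == unit, "patient_id"])
        arm1 = pids.isin(mutated)
        return arm1.to_numpy(), (~arm1).to_numpy()
    if grouping == "high_vs_low_vaf":
        if vaf_bins is None:
            raise ParameterError("high_vs_low_vaf grouping needs a binned VAF table")
        sub = vaf_bins[vaf_bins["gene"] == unit]
        hi = set(sub.loc[sub["bin"] == "high", "patient_id"])
        lo = set(sub.loc[sub["bin"] == "low", "patient_id"])
        return pids.isin(hi).to_numpy(), pids.isin(lo).to_numpy()
    if grouping == "multihit_vs_single":
        counts = cohort.variants[cohort.variants["gene"] == unit].groupby("patient_id").size()
        multi = set(counts[counts >= 2].index)
        single = set(counts[counts == 1].index)
        return pids.isin(multi).to_numpy(), pids.isin(single).to_numpy()
    raise ParameterError(f"unknown grouping {grouping!r}")


def clinical_effects(
    cohort: Cohort,
    grouping: str,
    units: list[str] | None = None,
    features: list[str] | None = None,
    vaf_bins: pd.DataFrame | None = None,
) -> list[EffectSize]:
    """Cohen's d of clinical features between two genotype-defined arms.

    ``grouping`` is one of ``mutant_vs_wt``, ``high_vs_low_vaf`` (needs
    ``vaf_bins`` from the vaf module) or ``multihit_vs_single``.  Missing
    clinical values are excluded pairwise, so each feature has its own n.
    Arms below 3 patients yield a record without CI, excluded from the
    testing family; Bonferroni q is per feature family across units.
    """
    units = units if units is not None else cohort.genes
    features = features if features is not None else CLINICAL_FEATURES
    records: list[EffectSize] = []
    for feature in features:
        values = pd.to_numeric(cohort.patients[feature], errors="coerce").to_numpy()
        fam: list[EffectSize] = []
        for unit in units:
            arm1, arm2 = _two_arm_masks(cohort, grouping, unit, vaf_bins)
            x1 = values[arm1 & ~np.isnan(values)]
            x2 = values[arm2 & ~np.isnan(values)]
            if len(x1) == 0 or len(x2) == 0:
                warnings.warn(f"clinical_effects: {unit}/{feature}: empty arm, skipped")
                continue
            label = f"{grouping}:{unit}"
            if len(x1) < 3 or len(x2) < 3:
                # record kept for auditability, no CI, outside the test family
                records.append(EffectSize(label, feature, np.nan, np.nan, np.nan, len(x1), len(x2)))
                continue
            d, lo, hi = cohens_d(x1, x2)
            p = float(stats.ttest_ind(x1, x2, equal_var=True).pvalue)
            rec = EffectSize(label, feature, d, lo, hi, len(x1), len(x2), p_value=p)
            records.append(rec)
            fam.append(rec)
        if fam:
            qs = bonferroni([r.p_value for r in fam])
            for r, q in zip(fam, qs):
                r.q_value = float(q)
    return records


def triple_genotype_scan(
    cohort: Cohort, genes: list[str] | None = None, min_triple: int = 10
) -> pd.DataFrame:
    """Survival of triple-mutant vs exactly-double-mutant genotypes.

    Enumerates 3-gene combinations with at least ``min_triple`` patients
    carrying all three mutations; the comparator arm carries exactly two
    of the three.  Returns a table with Cox HR, CI, log-rank p and
    Bonferroni q; empty when nothing passes.
    """
    genes = genes if genes is not None else cohort.genes
    mat = mutation_matrix(cohort, genes)
    surv = cohort.patients.set_index("patient_id")[["os_time", "os_event"]]
    rows = []
    for combo in combinations(genes, 3):
        k = mat[list(combo)].sum(axis=1)
        n_triple = int((k == 3).sum())
        if n_triple < min_triple:
            continue
        sel = k >= 2
        ids = mat.index[sel]
        sub = surv.loc[ids].dropna()
        grp = (k.loc[sub.index] == 3).astype(int).to_numpy()
        if grp.sum() == 0 or (1 - grp).sum() == 0:
            continue
        try:
            res = cox_univariate(sub["os_time"], sub["os_event"], grp,
                                 comparison=":".join(combo))
        except Exception as exc:  # degenerate arms in tiny fixtures
            warnings.warn(f"triple scan {combo}: {exc}")
            continue
        rows.append({
            "genotype": ":".join(combo), "n_triple": int(grp.sum()),
            "n_double": int((1 - grp).sum()), "hr": res.hr,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p": res.logrank_p, "q": np.nan,
        })
    df = pd.DataFrame(rows, columns=["genotype", "n_triple", "n_double", "hr",
                                     "ci_low", "ci_high", "p", "q"])
    if len(df):
        df["q"] = bonferroni(df["p"].to_numpy())
    return df


def multihit_compare(
    cohort: Cohort,
    unit: str = "gene",
    units: list[str] | None = None,
    features: list[str] | None = None,
) -> tuple[list[EffectSize], list[SurvivalResult]]:
    """Patients with >= 2 mutations in a unit vs exactly 1.

    ``unit`` is ``gene`` or ``category`` (two different genes of one
    functional category count as a multi-hit for the category).  Units
    with fewer than 3 multi-hit patients are skipped.
    """
    if unit not in ("gene", "category"):
        raise ParameterError(f"unknown unit {unit!r}")
    var = cohort.variants.copy()
    if unit == "category":
        var["unit"] = var["gene"].map(lambda g: category_of(g, cohort.category_map))
    else:
        var["unit"] = var["gene"]
    counts = var.groupby(["patient_id", "unit"]).size().rename("k").reset_index()
    features = features if features is not None else CLINICAL_FEATURES
    all_units = units if units is not None else sorted(counts["unit"].unique())
    surv = cohort.patients.set_index("patient_id")[["os_time", "os_event"]]
    effects: list[EffectSize] = []
    surv_results: list[SurvivalResult] = []
    for u in all_units:
        sub = counts[counts["unit"] == u]
        multi = set(sub.loc[sub["k"] >= 2, "patient_id"])
        single = set(sub.loc[sub["k"] == 1, "patient_id"])
        if len(multi) < 3:
            continue
        pids = cohort.patients["patient_id"]
        arm1, arm2 = pids.isin(multi).to_numpy(), pids.isin(single).to_numpy()
        for feature in features:
            vals = pd.to_numeric(cohort.patients[feature], errors="coerce").to_numpy()
            x1 = vals[arm1 & ~np.isnan(vals)]
            x2 = vals[arm2 & ~np.isnan(vals)]
            if len(x1) < 3 or len(x2) < 3:
                continue
            d, lo, hi = cohens_d(x1, x2)
            p = float(stats.ttest_ind(x1, x2, equal_var=True).pvalue)
            effects.append(EffectSize(f"multihit:{u}", feature, d, lo, hi, len(x1), len(x2), p_value=p))
        both = sorted(multi | single)
        sub_surv = surv.loc[surv.index.isin(both)].dropna()
        grp = sub_surv.index.isin(multi).astype(int)
        if grp.sum() >= 3 and (1 - grp).sum() >= 3 and sub_surv["os_event"].sum() > 0:
            try:
                surv_results.append(
                    cox_univariate(sub_surv["os_time"], sub_surv["os_event"], grp,
                                   comparison=f"multihit:{u}")
                )
            except Exception as exc:
                warnings.warn(f"multihit survival {u}: {exc}")
    if effects:
        fam: dict[str, list[EffectSize]] = {}
        for r in effects:
            fam.setdefault(r.feature, []).append(r)
        for recs in fam.values():
            qs = bonferroni([r.p_value for r in recs])
            for r, q in zip(recs, qs):
                r.q_value = float(q)
    return effects, surv_results


def pair_associations_to_frame(pairs: list[PairAssociation]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])


def effects_to_frame(effects: list[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in effects])
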