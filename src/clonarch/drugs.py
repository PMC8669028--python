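"""Ex vivo drug-sensitivity analytics.

Two complementary screens over a patient x drug AUC matrix (lower AUC =
greater ex vivo sensitivity):

* a binary mutant-vs-wild-type comparison per drug-gene pair (two-sided
  Wilcoxon rank-sum, Bonferroni-corrected, direction from the median
  difference), and
* a VAF-dependent screen — ordinary least squares of AUC on the
  copy-number-corrected VAF across mutant samples, restricted to
  drug-gene pairs with n >= 5 mutated samples, VAF dynamic range
  (max - min) >= 0.25 and AUC dynamic range >= 75.  A negative slope
  (higher VAF, lower AUC) is a *sensitive* call; a positive slope is
  *resistant*; calls require p < 0.05 with an additional Bonferroni
  q < 0.1 flag.

The same regression can be run inside a co-mutation background (e.g.
FLT3-ITD VAF among DNMT3A-mutant samples) via :func:`context_vaf_screen`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, max_vaf_per_gene
from .assoc import bonferroni
from .errors import DegenerateDataError


@dataclass
class ScreenResult:
    drug: str
    unit: str              # gene or "background:target" genotype context
    n: int
    delta_vaf: float
    delta_auc: float
    slope: float           # AUC units per unit VAF
    intercept: float
    r2: float
    p: float
    q: float
    call: str              # sensitive | resistant | none
    q_flag: bool = False   # q < q_threshold


def binary_drug_scan(
    cohort: Cohort,
    genes: list[str] | None = None,
    min_mut: int = 5,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Mutant vs wild-type AUC comparison for every drug-gene pair.

    Pairs with fewer than ``min_mut`` mutated samples holding drug data
    are skipped.  Returns a table with the two-sided rank-sum p,
    Bonferroni q over the scan, the mutant-minus-WT median AUC
    difference, and a sensitive/resistant call at q < ``q_threshold``.
    """
    if cohort.drugs is None:
        raise DegenerateDataError("cohort has no drug matrix")
    genes = genes if genes is not None else cohort.genes
    mutated = {g: set(cohort.variants.loc[cohort.variants["gene"] == g, "patient_id"])
               for g in genes}
    rows = []
    for drug, dsub in cohort.drugs.groupby("drug", sort=True):
        auc = dsub.set_index("patient_id")["auc"]
        for gene in genes:
            mut = auc[auc.index.isin(mutated[gene])]
            wt = auc[~auc.index.isin(mutated[gene])]
            if len(mut) < min_mut or len(wt) < 1:
                continue
            stat = stats.mannwhitneyu(mut, wt, alternative="two-sided",
                                      method="exact" if (len(mut) + len(wt)) <= 30 else "asymptotic")
            rows.append({
                "drug": drug, "gene": gene, "n_mut": len(mut), "n_wt": len(wt),
                "median_diff": float(mut.median() - wt.median()),
                "wilcoxon_p": float(stat.pvalue), "q": np.nan, "call": "none",
            })
    df = pd.DataFrame(rows, columns=["drug", "gene", "n_mut", "n_wt",
                                     "median_diff", "wilcoxon_p", "q", "call"])
    if len(df):
        df["q"] = bonferroni(df["wilcoxon_p"].to_numpy())
        sig = df["q"] < q_threshold
        df.loc[sig & (df["median_diff"] < 0), "call"] = "sensitive"
        df.loc[sig & (df["median_diff"] > 0), "call"] = "resistant"
    return df


def _regress_pair(drug: str, unit: str, vaf: np.ndarray, auc: np.ndarray) -> dict:
    fit = stats.linregress(vaf, auc)
    return {
        "drug": drug, "unit": unit, "n": len(vaf),
        "delta_vaf": float(vaf.max() - vaf.min()),
        "delta_auc": float(auc.max() - auc.min()),
        "slope": float(fit.slope), "intercept": float(fit.intercept),
        "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue),
    }


def vaf_screen(
    cohort: Cohort,
    genes: list[str] | None = None,
    min_n: int = 5,
    min_dvaf: float = 0.25,
    min_dauc: float = 75.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.1,
    restrict_patients: set[str] | None = None,
    unit_prefix: str = "",
) -> list[ScreenResult]:
    """OLS of drug AUC against corrected VAF over mutant samples.

    Only drug-gene pairs passing all three inclusion filters (sample
    count, VAF range, AUC range) are regressed; only mutant samples enter
    (wild-type samples carry no VAF).  Direction calls follow the sign of
    the slope at p < ``p_threshold``; the Bonferroni q < ``q_threshold``
    flag marks the stricter family-corrected hits.
    """
    if cohort.drugs is None:
        raise DegenerateDataError("cohort has no drug matrix")
    genes = genes if genes is not None else cohort.genes
    vafs = max_vaf_per_gene(cohort, scale="corrected")
    vafs = vafs[vafs["gene"].isin(genes)]
    if restrict_patients is not None:
        vafs = vafs[vafs["patient_id"].isin(restrict_patients)]
    rows = []
    for drug, dsub in cohort.drugs.groupby("drug", sort=True):
        auc = dsub.set_index("patient_id")["auc"]
        for gene, gsub in vafs.groupby("gene", sort=True):
            joined = gsub.set_index("patient_id").join(auc, how="inner").dropna()
            if len(joined) < min_n:
                continue
            v = joined["vaf"].to_numpy()
            a = joined["auc"].to_numpy()
            if v.max() - v.min() < min_dvaf or a.max() - a.min() < min_dauc:
                continue
            if np.unique(v).size < 2:
                raise DegenerateDataError(f"{drug}/{gene}: constant VAF after filters")
            rows.append(_regress_pair(drug, f"{unit_prefix}{gene}", v, a))
    results: list[ScreenResult] = []
    if rows:
        qs = bonferroni([r["p"] for r in rows])
        for r, q in zip(rows, qs):
            call = "none"
            if r["p"] < p_threshold:
                call = "sensitive" if r["slope"] < 0 else "resistant"
            results.append(ScreenResult(q=float(q), call=call, q_flag=bool(q < q_threshold), **r))
    return results


def context_vaf_screen(
    cohort: Cohort,
    background_gene: str,
    target_gene: str,
    min_n: int = 5,
    **kwargs,
) -> list[ScreenResult]:
    """VAF screen of ``target_gene`` restricted to ``background_gene``-mutant samples.

    The unit label is "background:target".  Subgroups below ``min_n``
    are skipped with a warning (empty result).
    """
    background = set(cohort.variants.loc[cohort.variants["gene"] == background_gene, "patient_id"])
    target = set(cohort.variants.loc[cohort.variants["gene"] == target_gene, "patient_id"])
    context = background & target
    if len(context) < min_n:
        warnings.warn(
            f"context_vaf_screen {background_gene}:{target_gene}: "
            f"{len(context)} samples < min_n={min_n}, skipped")
        return []
    return vaf_screen(
        cohort, genes=[target_gene], min_n=min_n,
        restrict_patients=context, unit_prefix=f"{background_gene}:",
        **kwargs,
    )


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
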