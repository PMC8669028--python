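"""VAF correction and high/low thresholding.

Raw variant allele frequencies are placed on a common clonal scale:

    ccf           = min(1, raw_vaf * total_cn / multiplicity)
    corrected_vaf = ccf / 2

so that a heterozygous autosomal mutation present in every tumor cell of a
pure diploid sample sits at corrected VAF 0.5 regardless of local copy
number, and a hemizygous X mutation in a male (effective CN 1) is put on
the same scale.  The CCF is capped at 1 (sequencing noise routinely pushes
raw VAFs above their theoretical maximum) and the cap is flagged rather
than treated as an error.

Three high/low binning rules are provided: per-gene median split, a fixed
cutpoint (default: strictly above 30% raw VAF), and survival-driven
maximally selected rank statistics with a permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InconsistencyError, ParameterError

__all__ = [
    "VafThreshold",
    "correct_vaf",
    "correct_vaf_frame",
    "bin_by_median",
    "bin_by_fixed",
    "maxstat_cutpoint",
    "logrank_scores",
]


@dataclass
class VafThreshold:
    """A per-gene high/low VAF cutpoint and how it was obtained."""

    gene: str
    method: str                      # median | fixed | maxstat
    cutpoint: float
    n_above: int
    n_below: int
    p_value: float | None = None     # permutation p (maxstat only)
    seed: int | None = None
    statistic: float | None = None   # |standardized log-rank| at the cutpoint


def correct_vaf(
    raw_vaf: float,
    total_cn: float | None = None,
    multiplicity: int = 1,
    is_x_nonpar: bool = False,
    sex: str = "F",
) -> tuple[float, float, bool]:
    """Correct one raw VAF for copy number and X-linkage.

    Returns ``(ccf, corrected_vaf, capped)``.  ``total_cn=None`` means "not
    measured" and defaults to 2, or to 1 on the non-pseudoautosomal X in
    males (hemizygous).
    """
    if not 0.0 <= raw_vaf <= 1.0:
        raise ParameterError(f"raw_vaf {raw_vaf} outside [0, 1]")
    if multiplicity < 1:
        raise ParameterError("multiplicity must be >= 1")
    if total_cn is None or (isinstance(total_cn, float) and np.isnan(total_cn)):
        total_cn = 1 if (is_x_nonpar and sex == "M") else 2
    if total_cn == 0:
        if raw_vaf > 0:
            raise InconsistencyError("total_cn=0 but raw_vaf > 0")
        return 0.0, 0.0, False
    ccf = raw_vaf * total_cn / multiplicity
    capped = ccf > 1.0
    ccf = min(1.0, ccf)
    return ccf, ccf / 2.0, capped


def correct_vaf_frame(variants: pd.DataFrame, sex_by_patient: pd.Series) -> pd.DataFrame:
    """Vectorized :func:`correct_vaf` over a variant table.

    Adds/overwrites ``ccf``, ``corrected_vaf`` and ``ccf_capped`` columns.
    ``is_x_nonpar`` is derived from ``chrom`` in {'X', 'chrX'} when absent.
    """
    out = variants.copy()
    if "is_x_nonpar" not in out.columns:
        out["is_x_nonpar"] = out["chrom"].astype(str).isin(["X", "chrX"])
    if "multiplicity" not in out.columns:
        out["multiplicity"] = 1
    sex = out["patient_id"].map(sex_by_patient).fillna("unknown")
    cn = pd.to_numeric(out.get("total_cn"), errors="coerce")
    default_cn = np.where(out["is_x_nonpar"] & (sex == "M"), 1.0, 2.0)
    cn = cn.to_numpy(dtype=float)
    cn = np.where(np.isnan(cn), default_cn, cn)
    raw = out["raw_vaf"].to_numpy(dtype=float)
    if ((cn == 0) & (raw > 0)).any():
        bad = out.loc[(cn == 0) & (raw > 0), "variant_id"].tolist()
        raise InconsistencyError(f"total_cn=0 with raw_vaf>0 for variants {bad}")
    mult = out["multiplicity"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ccf = np.where(cn == 0, 0.0, raw * cn / mult)
    out["ccf_capped"] = ccf > 1.0
    out["ccf"] = np.minimum(ccf, 1.0)
    out["corrected_vaf"] = out["ccf"] / 2.0
    return out


def _vaf_frame_check(vafs: pd.DataFrame, column: str) -> None:
    for col in ("patient_id", "gene", column):
        if col not in vafs.columns:
            raise ParameterError(f"VAF table lacks column {col!r}")


def bin_by_median(vafs: pd.DataFrame, column: str = "vaf") -> tuple[pd.DataFrame, list[VafThreshold]]:
    """Per-gene median split: high iff VAF strictly above the gene median.

    Exactly-median values bin low.  Genes with a single mutated patient are
    skipped with a warning (threshold undefined); genes whose VAFs are all
    equal come back all-low with a degenerate-threshold warning.
    """
    _vaf_frame_check(vafs, column)
    pieces, thresholds = [], []
    for gene, sub in vafs.groupby("gene", sort=True):
        if len(sub) < 2:
            warnings.warn(f"gene {gene}: <2 mutated patients, median threshold undefined; skipped")
            continue
        med = float(sub[column].median())
        if sub[column].nunique() == 1:
            warnings.warn(f"gene {gene}: all VAFs equal ({med}); degenerate threshold, all binned low")
        piece = sub.copy()
        piece["bin"] = np.where(piece[column] > med, "high", "low")
        pieces.append(piece)
        thresholds.append(
            VafThreshold(gene, "median", med, int((sub[column] > med).sum()), int((sub[column] <= med).sum()))
        )
    binned = pd.concat(pieces, ignore_index=True) if pieces else vafs.iloc[0:0].assign(bin=[])
    return binned, thresholds


def bin_by_fixed(vafs: pd.DataFrame, cutpoint: float = 0.30, column: str = "vaf") -> tuple[pd.DataFrame, list[VafThreshold]]:
    """Fixed cutpoint: high iff VAF strictly above ``cutpoint`` (default 30%)."""
    if not 0.0 <= cutpoint <= 1.0:
        raise ParameterError(f"cutpoint {cutpoint} outside [0, 1]")
    _vaf_frame_check(vafs, column)
    out = vafs.copy()
    out["bin"] = np.where(out[column] > cutpoint, "high", "low")
    thresholds = [
        VafThreshold(gene, "fixed", cutpoint, int((sub[column] > cutpoint).sum()), int((sub[column] <= cutpoint).sum()))
        for gene, sub in out.groupby("gene", sort=True)
    ]
    return out, thresholds


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Log-rank (Savage) scores: a_i = delta_i - NelsonAalen(t_i).

    The two-sample linear rank statistic built on these scores is the
    log-rank statistic, which makes a cutpoint scan and its permutation
    null cheap: scores are computed once per dataset.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    n = len(t_sorted)
    # Nelson-Aalen cumulative hazard at each (sorted, tied) time
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    cumhaz_at = {}
    cum = 0.0
    for u, fi in zip(uniq, first_idx):
        at_risk = n - fi
        deaths = int(e_sorted[(t_sorted == u)].sum())
        cum += deaths / at_risk
        cumhaz_at[u] = cum
    scores = event - np.array([cumhaz_at[t] for t in time])
    return scores


def _scan_statistics(
    a_sorted: np.ndarray, admissible: np.ndarray
) -> np.ndarray:
    """Standardized prefix-sum statistics for every split after index k.

    ``a_sorted`` are log-rank scores ordered by the scanned covariate;
    split k puts patients [0..k] in the low arm.  Returns |T_k| with
    non-admissible splits set to 0.
    """
    n = len(a_sorted)
    abar = a_sorted.mean()
    ss = ((a_sorted - abar) ** 2).sum()
    prefix = np.cumsum(a_sorted)[:-1]          # low-arm score sums, k = 0..n-2
    n_low = np.arange(1, n)
    var = n_low * (n - n_low) / (n * (n - 1)) * ss
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, (prefix - n_low * abar) / np.sqrt(var), 0.0)
    return np.where(admissible, np.abs(t), 0.0)


def maxstat_cutpoint(
    vafs: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    min_prop: float = 0.1,
    n_perm: int = 10000,
    seed: int | None = None,
    gene: str = "",
) -> VafThreshold:
    """Maximally selected log-rank cutpoint with a permutation p-value.

    Candidate cutpoints are the midpoints between adjacent distinct VAFs,
    restricted to the 10th-90th VAF percentiles with each arm holding at
    least ``min_prop`` of the patients.  At each candidate the standardized
    two-sample log-rank statistic is computed; the returned cutpoint
    maximizes |statistic|.  The p-value permutes the VAF labels against the
    survival data (``n_perm`` draws, seeded) and re-runs the same scan, so
    the selection multiplicity is accounted for exactly.
    """
    vafs = np.asarray(vafs, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(vafs)
    if n < 10:
        raise ParameterError(f"maxstat needs >= 10 patients, got {n}")
    if np.unique(vafs).size < 2:
        raise DegenerateDataError("all VAFs equal: no admissible cutpoint")

    order = np.argsort(vafs, kind="stable")
    v_sorted = vafs[order]
    scores = logrank_scores(time, event)
    a_sorted = scores[order]

    # split k (low arm = first k+1 patients) is admissible when it falls
    # between distinct VAFs, inside the percentile bounds, with both arms
    # large enough
    k = np.arange(1, n)
    distinct = v_sorted[1:] > v_sorted[:-1]
    lo_bound, hi_bound = np.quantile(vafs, [0.10, 0.90])
    mid = (v_sorted[:-1] + v_sorted[1:]) / 2.0
    size_ok = (k >= min_prop * n) & (n - k >= min_prop * n)
    admissible = distinct & size_ok & (mid >= lo_bound) & (mid <= hi_bound)
    if not admissible.any():
        raise DegenerateDataError("no admissible cutpoint under min_prop/percentile bounds")

    t_abs = _scan_statistics(a_sorted, admissible)
    best = int(np.argmax(t_abs))
    cut = float(mid[best])
    t_max = float(t_abs[best])

    p_value = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        chunk = max(1, min(n_perm, int(2_000_000 / max(n, 1))))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm = rng.permuted(np.broadcast_to(scores, (m, n)).copy(), axis=1)
            abar = scores.mean()
            ss = ((scores - abar) ** 2).sum()
            prefix = np.cumsum(perm, axis=1)[:, :-1]
            n_low = np.arange(1, n)
            var = n_low * (n - n_low) / (n * (n - 1)) * ss
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var > 0, (prefix - n_low * abar) / np.sqrt(var), 0.0)
            t = np.where(admissible, np.abs(t), 0.0)
            exceed += int((t.max(axis=1) >= t_max - 1e-12).sum())
            done += m
        p_value = (exceed + 1) / (n_perm + 1)

    return VafThreshold(
        gene=gene,
        method="maxstat",
        cutpoint=cut,
        n_above=int((vafs > cut).sum()),
        n_below=int((vafs <= cut).sum()),
        p_value=p_value,
        seed=seed,
        statistic=t_max,
    )


def thresholds_to_frame(thresholds: list[VafThreshold]) -> pd.DataFrame:
    """Flatten thresholds for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene": t.gene,
                "method": t.method,
                "cutpoint": t.cutpoint,
                "n_above": t.n_above,
                "n_below": t.n_below,
                "p_value": t.p_value,
                "seed": t.seed,
            }
            for t in thresholds
        ]
    )
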