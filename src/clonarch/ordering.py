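"""Mutation acquisition order from bulk VAFs.

Within one patient, a mutation is called earlier (clonally dominant) than
a co-occurring one when its copy-number-corrected VAF is higher by at
least a margin (default 5 percentage points, boundary inclusive); pairs
within the margin are ambiguous.  Where a patient carries several
variants of one gene or category, only the largest VAF represents the
unit.  Nonambiguous per-patient calls are pooled into a win matrix and a
Bradley-Terry model is fit by minorization-maximization to produce a
global acquisition ranking with Wald confidence intervals, and pairwise
orderings with enough patients in both directions are tested for a
survival difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .cohort import Cohort, max_vaf_per_gene
from .errors import DegenerateDataError, ParameterError
from .survival import SurvivalResult, cox_univariate

Z95 = 1.959963984540054


@dataclass
class OrderingCall:
    patient_id: str
    unit_a: str
    unit_b: str
    vaf_a: float
    vaf_b: float
    relation: str       # a_first | b_first | ambiguous
    margin: float


@dataclass
class BtRanking:
    units: list[str]
    ability: np.ndarray          # log-scale, sum-to-zero
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rank: np.ndarray             # 1 = earliest-acquired
    n_comparisons: np.ndarray
    wins: np.ndarray             # wins[i, j] = # patients with i before j
    separation: bool = False     # 0.5 pseudo-observations were added
    excluded_units: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": self.units, "ability": self.ability, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "rank": self.rank, "n_comparisons": self.n_comparisons,
        }).sort_values("rank").reset_index(drop=True)


def classify_pair(vaf_a: float, vaf_b: float, margin: float) -> str:
    # boundary-inclusive dominance; the epsilon keeps the >= rule stable
    # under binary float representation (0.35 - 0.30 < 0.05 in IEEE754)
    if vaf_a - vaf_b >= margin - 1e-12:
        return "a_first"
    if vaf_b - vaf_a >= margin - 1e-12:
        return "b_first"
    return "ambiguous"


def pairwise_dominance(
    cohort: Cohort, margin: float = 0.05, unit: str = "gene"
) -> list[OrderingCall]:
    """One dominance call per co-mutated (patient, unit pair).

    ``margin`` is on the corrected-VAF scale in absolute points and must
    lie in (0, 0.5); the 1-10% range is the documented sensitivity band.
    Units are compared in lexicographic order (unit_a < unit_b).
    """
    if not 0.0 < margin < 0.5:
        raise ParameterError(f"margin {margin} outside (0, 0.5)")
    vafs = max_vaf_per_gene(cohort, scale="corrected", unit=unit)
    calls: list[OrderingCall] = []
    for pid, sub in vafs.groupby("patient_id", sort=True):
        units = sub.sort_values("gene")
        recs = list(units.itertuples(index=False))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                calls.append(OrderingCall(
                    patient_id=pid, unit_a=a.gene, unit_b=b.gene,
                    vaf_a=float(a.vaf), vaf_b=float(b.vaf),
                    relation=classify_pair(a.vaf, b.vaf, margin),
                    margin=margin,
                ))
    return calls


def win_matrix(calls: list[OrderingCall]) -> tuple[list[str], np.ndarray]:
    """Ordered-pair win counts from nonambiguous calls (one per patient)."""
    units = sorted({c.unit_a for c in calls} | {c.unit_b for c in calls})
    idx = {u: i for i, u in enumerate(units)}
    w = np.zeros((len(units), len(units)), dtype=float)
    for c in calls:
        if c.relation == "a_first":
            w[idx[c.unit_a], idx[c.unit_b]] += 1
        elif c.relation == "b_first":
            w[idx[c.unit_b], idx[c.unit_a]] += 1
    return units, w


def bt_loglik(w: np.ndarray, log_ability: np.ndarray) -> float:
    """Bradley-Terry log-likelihood: sum w_ij * log(p_i / (p_i + p_j))."""
    p = np.exp(log_ability)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = w * (np.log(p)[:, None] - np.log(p[:, None] + p[None, :]))
    return float(np.nansum(np.where(w > 0, ll, 0.0)))


def bt_rank(
    calls: list[OrderingCall],
    min_patients: int = 2,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> BtRanking:
    """Bradley-Terry MLE over nonambiguous ordering calls.

    Fit is by the classical MM iteration; abilities are identified by a
    sum-to-zero constraint on the log scale and rank 1 is the unit
    acquired earliest.  Pairs compared fewer than ``min_patients`` times
    are dropped from the win matrix.  Complete separation (a unit winning
    or losing every comparison) is handled by adding 0.5 pseudo-
    observations in both directions of every compared pair, flagged on
    the result.  If the comparison graph is disconnected, the fit is
    restricted to the largest connected component and the excluded units
    are reported.
    """
    informative = [c for c in calls if c.relation != "ambiguous"]
    if not informative:
        raise DegenerateDataError("no nonambiguous ordering calls")
    units, w = win_matrix(informative)
    n_pair = w + w.T
    w = np.where(n_pair >= min_patients, w, 0.0)
    n_pair = w + w.T

    # connectivity on the compared-pair graph
    adj = csr_matrix((n_pair > 0).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    excluded: list[str] = []
    if n_comp > 1:
        sizes = np.bincount(labels)
        # units with no comparisons at all form singleton components; keep
        # the largest component that actually has edges
        with_edges = [c for c in range(n_comp) if n_pair[labels == c][:, labels == c].sum() > 0]
        if not with_edges:
            raise DegenerateDataError("comparison graph has no edges after min_patients filter")
        keep_label = max(with_edges, key=lambda c: sizes[c])
        keep = labels == keep_label
        excluded = [u for u, k in zip(units, keep) if not k]
        if excluded:
            warnings.warn(f"bt_rank: disconnected comparison graph; excluded {excluded}")
        units = [u for u, k in zip(units, keep) if k]
        w = w[np.ix_(keep, keep)]
        n_pair = w + w.T

    m = len(units)
    separation = False
    wins_tot = w.sum(axis=1)
    losses_tot = w.sum(axis=0)
    if ((wins_tot > 0) & (losses_tot == 0)).any() or ((losses_tot > 0) & (wins_tot == 0)).any():
        separation = True
        w = w + np.where(n_pair > 0, 0.5, 0.0)
        n_pair = w + w.T

    # MM iterations: p_i <- W_i / sum_j n_ij / (p_i + p_j)
    p = np.ones(m)
    trace = [bt_loglik(w, np.log(p))]
    wi = w.sum(axis=1)
    for _ in range(max_iter):
        denom = np.where(n_pair > 0, n_pair / (p[:, None] + p[None, :]), 0.0).sum(axis=1)
        p_new = np.where(denom > 0, wi / denom, p)
        p_new = p_new / np.exp(np.mean(np.log(p_new)))     # geometric-mean 1
        delta = np.max(np.abs(np.log(p_new) - np.log(p)))
        p = p_new
        trace.append(bt_loglik(w, np.log(p)))
        if delta < tol:
            break

    beta = np.log(p)
    beta -= beta.mean()          # sum-to-zero

    # observed information of the log-abilities; covariance via pseudo-inverse
    pi = np.exp(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_off = np.where(n_pair > 0, n_pair * pi[:, None] * pi[None, :] / (pi[:, None] + pi[None, :]) ** 2, 0.0)
    info = np.diag(h_off.sum(axis=1)) - h_off
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    order = np.argsort(-beta, kind="stable")     # highest ability = earliest
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)

    return BtRanking(
        units=units, ability=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        rank=rank, n_comparisons=n_pair.sum(axis=1).astype(int),
        wins=w, separation=separation, excluded_units=excluded,
        loglik_trace=trace,
    )


def ordering_survival(
    cohort: Cohort,
    unit_a: str,
    unit_b: str,
    margin: float = 0.05,
    unit: str = "gene",
    min_per_arm: int = 5,
    calls: list[OrderingCall] | None = None,
) -> SurvivalResult | None:
    """Cox comparison of patients with unit_a-first vs unit_b-first.

    Ambiguous patients are excluded; both directions must hold at least
    ``min_per_arm`` patients or the pair is skipped (None, with a
    warning carrying the counts).
    """
    if calls is None:
        calls = pairwise_dominance(cohort, margin=margin, unit=unit)
    lo, hi = sorted([unit_a, unit_b])
    flipped = (lo, hi) != (unit_a, unit_b)
    relevant = [c for c in calls if (c.unit_a, c.unit_b) == (lo, hi)]
    a_first = [c.patient_id for c in relevant
               if c.relation == ("b_first" if flipped else "a_first")]
    b_first = [c.patient_id for c in relevant
               if c.relation == ("a_first" if flipped else "b_first")]
    if len(a_first) < min_per_arm or len(b_first) < min_per_arm:
        warnings.warn(
            f"ordering_survival {unit_a}>{unit_b}: arms {len(a_first)}/{len(b_first)} "
            f"below min_per_arm={min_per_arm}, skipped"
        )
        return None
    surv = cohort.patients.set_index("patient_id")[["os_time", "os_event"]]
    ids = a_first + b_first
    sub = surv.loc[ids].dropna()
    grp = sub.index.isin(a_first).astype(int)
    return cox_univariate(sub["os_time"], sub["os_event"], grp,
                          comparison=f"{unit_a}_first_vs_{unit_b}_first")


def pairwise_vaf_relation(
    cohort: Cohort, gene_a: str, gene_b: str, min_pairs: int = 5
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Per-patient VAF pairs for two co-mutated genes + Spearman rho.

    Returns (table, rho, p); rho is None below ``min_pairs`` co-mutated
    patients or when a VAF column is constant (degenerate, flagged by a
    warning).
    """
    vafs = max_vaf_per_gene(cohort, scale="corrected")
    wide = vafs.pivot(index="patient_id", columns="gene", values="vaf")
    if gene_a not in wide.columns or gene_b not in wide.columns:
        return pd.DataFrame(columns=["patient_id", "vaf_a", "vaf_b"]), None, None
    sub = wide[[gene_a, gene_b]].dropna()
    table = sub.reset_index().rename(columns={gene_a: "vaf_a", gene_b: "vaf_b"})
    if len(sub) < min_pairs:
        return table, None, None
    if sub[gene_a].nunique() == 1 or sub[gene_b].nunique() == 1:
        warnings.warn(f"pairwise_vaf_relation {gene_a}/{gene_b}: constant VAF column, correlation undefined")
        return table, None, None
    rho, p = stats.spearmanr(sub[gene_a], sub[gene_b])
    return table, float(rho), float(p)


def calls_to_frame(calls: list[OrderingCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
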