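"""Clone clusters, clone trees and intratumoral heterogeneity metrics.

Cluster input is either a PyClone-style loci table (mutation -> cluster,
cellular prevalence) or a deterministic 1-D kernel-mode stand-in
clustering of per-variant CCFs.  A clone tree is then built under two
explicit constraints:

* strict nesting — a child's CCF must be below its parent's by at least
  ``z`` pooled standard errors, and
* an uncertainty-aware pigeonhole (sum) rule — a parent's children may
  not jointly exceed its CCF by more than ``eps`` plus ``z`` pooled
  standard errors.

Clusters are attached in descending CCF order to the deepest node
satisfying both constraints; a cluster that can nest nowhere becomes a
sibling at the shallowest node whose sum rule tolerates it, which is what
drives a *branched* call: statistically indistinguishable CCFs cannot
nest.  Architecture is branched iff any node acquires two or more
children, linear when the tree is a chain, unresolved when a cluster
cannot be placed at all.

Heterogeneity metrics: mutation and clonal burden, median mutations per
clone, Shannon diversity (natural log) over clone-exclusive cellular
fractions, and the MATH score (100 x 1.4826 x MAD / median of VAFs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DegenerateDataError, IntegrityError, ParameterError, SchemaError
from .survival import SurvivalResult, cox_univariate

DEFAULT_DEPTH = 500  # binomial fallback depth for cluster-CCF standard errors


@dataclass
class CloneCluster:
    cluster_id: str
    ccf: float
    se: float
    members: list[str] = field(default_factory=list)
    ccf_clamped: bool = False
    se_fallback: bool = False

    @property
    def n_mutations(self) -> int:
        return len(self.members)


@dataclass
class ClonalModel:
    patient_id: str
    clusters: dict[str, CloneCluster]
    tree_edges: list[tuple[str, str]] = field(default_factory=list)
    architecture: str = "unresolved"   # linear | branched | unresolved
    founder_id: str | None = None

    def children_of(self, node: str) -> list[str]:
        return [c for p, c in self.tree_edges if p == node]

    def parent_of(self, node: str) -> str | None:
        for p, c in self.tree_edges:
            if c == node:
                return p
        return None


@dataclass
class HeterogeneityMetrics:
    patient_id: str
    mutation_burden: int
    clonal_burden: int
    median_mut_per_clone: float
    shannon: float
    math_score: float
    shannon_method: str = "tree"   # tree | raw_ccf (unresolved fallback)


def read_pyclone(loci_table: str | Path, depth_default: int = DEFAULT_DEPTH) -> dict[str, ClonalModel]:
    """Read a PyClone-style loci table into per-sample clonal models.

    Required columns: mutation_id, sample_id, cluster_id,
    cellular_prevalence; cellular_prevalence_std is optional (binomial
    fallback ``sqrt(ccf(1-ccf)/depth_default)`` is used and flagged when
    absent).  Cellular prevalences above 1 are clamped and flagged;
    duplicate (mutation, sample) rows are an integrity error.
    """
    with open(loci_table, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(loci_table, sep=sep)
    required = ["mutation_id", "sample_id", "cluster_id", "cellular_prevalence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"loci table missing mandatory column(s): {', '.join(missing)}")
    if df.duplicated(subset=["mutation_id", "sample_id"]).any():
        raise IntegrityError("duplicate (mutation_id, sample_id) rows in loci table")
    has_std = "cellular_prevalence_std" in df.columns
    models: dict[str, ClonalModel] = {}
    for sample, sub in df.groupby("sample_id", sort=True):
        clusters: dict[str, CloneCluster] = {}
        for cid, csub in sub.groupby("cluster_id", sort=True):
            ccf = float(csub["cellular_prevalence"].mean())
            clamped = ccf > 1.0
            if clamped:
                warnings.warn(f"sample {sample} cluster {cid}: CCF {ccf:.3f} > 1, clamped")
                ccf = 1.0
            if has_std:
                se = float(csub["cellular_prevalence_std"].mean() / np.sqrt(len(csub)))
                fallback = False
            else:
                se = float(np.sqrt(max(ccf * (1.0 - ccf), 1e-12) / depth_default))
                fallback = True
            clusters[str(cid)] = CloneCluster(
                cluster_id=str(cid), ccf=ccf, se=se,
                members=sorted(csub["mutation_id"].astype(str)),
                ccf_clamped=clamped, se_fallback=fallback,
            )
        models[str(sample)] = ClonalModel(patient_id=str(sample), clusters=clusters)
    return models


def standin_cluster(
    ccfs, max_k: int = 6, seed: int | None = None, merge_distance: float = 0.10,
    bandwidth: float = 0.04,
) -> np.ndarray:
    """Deterministic 1-D Gaussian-kernel mode clustering of CCFs.

    Density modes on a fixed grid are merged while closer than
    ``merge_distance`` (and until at most ``max_k`` remain); points are
    assigned to the nearest surviving mode.  Returns integer labels in
    order of decreasing mode CCF (0 = highest).  ``seed`` is accepted for
    interface uniformity; the procedure is deterministic.
    """
    x = np.asarray(ccfs, dtype=float)
    if len(x) == 0:
        raise ParameterError("standin_cluster needs >= 1 CCF")
    if x.max() - x.min() <= merge_distance:
        return np.zeros(len(x), dtype=int)
    grid = np.arange(0.0, 1.05 + 1e-9, 0.0025)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2).sum(axis=1)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    modes = list(grid[1:-1][interior])
    if not modes:
        modes = [float(x.mean())]
    # merge closest modes until separated by > merge_distance and <= max_k
    modes.sort()
    def _closest(ms):
        gaps = np.diff(ms)
        i = int(np.argmin(gaps)) if len(gaps) else -1
        return i, (gaps[i] if i >= 0 else np.inf)
    while len(modes) > 1:
        i, gap = _closest(modes)
        if gap > merge_distance and len(modes) <= max_k:
            break
        # weight merged position by nearby point counts
        left_n = np.sum(np.abs(x - modes[i]) <= np.abs(x - modes[i + 1]))
        right_n = len(x) - left_n
        tot = max(left_n + right_n, 1)
        merged = (modes[i] * left_n + modes[i + 1] * right_n) / tot
        modes[i:i + 2] = [merged]
    modes = sorted(modes, reverse=True)
    labels = np.argmin(np.abs(x[:, None] - np.asarray(modes)[None, :]), axis=1)
    # relabel contiguously in case a mode captured no points
    uniq = sorted(set(labels.tolist()))
    remap = {u: k for k, u in enumerate(uniq)}
    return np.array([remap[l] for l in labels], dtype=int)


def model_from_assignments(
    patient_id: str, ccfs, labels, variant_ids=None, depth: int = DEFAULT_DEPTH
) -> ClonalModel:
    """Build a ClonalModel from per-variant CCFs + cluster labels."""
    ccfs = np.asarray(ccfs, dtype=float)
    labels = np.asarray(labels)
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(len(ccfs))]
    clusters: dict[str, CloneCluster] = {}
    for lab in sorted(set(labels.tolist()), key=str):
        mask = labels == lab
        ccf = float(np.clip(ccfs[mask].mean(), 0.0, 1.0))
        # binomial read noise acts on the raw-VAF scale; for a diploid het
        # site ccf = 2*vaf, so var(ccf) = 4 * vaf(1-vaf)/depth
        vaf_scale = ccf / 2.0
        se = float(2.0 * np.sqrt(max(vaf_scale * (1.0 - vaf_scale), 1e-12) / depth)
                   / np.sqrt(mask.sum()))
        clusters[str(lab)] = CloneCluster(
            cluster_id=str(lab), ccf=ccf, se=max(se, 1e-6),
            members=sorted(np.asarray(variant_ids)[mask].astype(str)),
            se_fallback=True,
        )
    return ClonalModel(patient_id=patient_id, clusters=clusters)


def _admissible_parent(node: CloneCluster, cand: CloneCluster, children_sum: float,
                       z: float, eps: float) -> tuple[bool, bool]:
    """(strict_nesting_ok, sum_ok) for attaching ``cand`` under ``node``."""
    pooled = np.sqrt(node.se ** 2 + cand.se ** 2)
    nesting = node.ccf - cand.ccf >= z * pooled
    sum_ok = children_sum + cand.ccf <= node.ccf + eps + z * pooled
    return bool(nesting), bool(sum_ok)


def build_tree(model: ClonalModel, z: float = 1.96, eps: float = 0.05) -> ClonalModel:
    """Attach clusters into a clone tree and classify the architecture.

    Deterministic and invariant to input order: clusters are processed in
    descending CCF (cluster_id tie-break); the founder is the max-CCF
    cluster.  See the module docstring for the attachment rule.
    """
    if not model.clusters:
        raise DegenerateDataError(f"patient {model.patient_id}: empty clonal model")
    order = sorted(model.clusters.values(), key=lambda c: (-c.ccf, c.cluster_id))
    founder = order[0]
    edges: list[tuple[str, str]] = []
    depth = {founder.cluster_id: 0}
    children_sum = {founder.cluster_id: 0.0}
    unresolved = False
    for cand in order[1:]:
        placed = [model.clusters[k] for k in depth]
        # deepest node satisfying both constraints (depth, then CCF, then id)
        best = None
        for node in placed:
            nest, s_ok = _admissible_parent(node, cand, children_sum[node.cluster_id], z, eps)
            if nest and s_ok:
                key = (depth[node.cluster_id], node.ccf, node.cluster_id)
                if best is None or key > best[0]:
                    best = (key, node)
        if best is None:
            # sibling fallback: shallowest node whose sum rule tolerates it
            for node in sorted(placed, key=lambda n: (depth[n.cluster_id], -n.ccf, n.cluster_id)):
                _, s_ok = _admissible_parent(node, cand, children_sum[node.cluster_id], z, eps)
                if s_ok and node.ccf >= cand.ccf:
                    best = (None, node)
                    break
        if best is None:
            unresolved = True
            warnings.warn(
                f"patient {model.patient_id}: cluster {cand.cluster_id} "
                f"(CCF {cand.ccf:.3f}) cannot be placed; architecture unresolved"
            )
            continue
        parent = best[1]
        edges.append((parent.cluster_id, cand.cluster_id))
        depth[cand.cluster_id] = depth[parent.cluster_id] + 1
        children_sum[cand.cluster_id] = 0.0
        children_sum[parent.cluster_id] += cand.ccf
    model.tree_edges = edges
    model.founder_id = founder.cluster_id
    if unresolved:
        model.architecture = "unresolved"
    else:
        n_children = {}
        for p, _ in edges:
            n_children[p] = n_children.get(p, 0) + 1
        model.architecture = "branched" if any(v >= 2 for v in n_children.values()) else "linear"
    return model


def exclusive_fractions(model: ClonalModel) -> dict[str, float]:
    """Clone-exclusive cellular fractions: node CCF minus children's sum."""
    out = {}
    for cid, cl in model.clusters.items():
        child_sum = sum(model.clusters[c].ccf for p, c in model.tree_edges if p == cid)
        out[cid] = max(cl.ccf - child_sum, 0.0)
    return out


def heterogeneity(
    model: ClonalModel, vafs, noise_floor: float = 0.01
) -> HeterogeneityMetrics:
    """Burden, Shannon diversity and MATH score for one patient.

    ``vafs`` are the patient's corrected VAFs (MATH input).  Shannon uses
    clone-exclusive fractions from the tree; for an unresolved tree it
    falls back to normalized raw CCFs, flagged via ``shannon_method``.
    """
    vafs = np.asarray(vafs, dtype=float)
    counts = [c.n_mutations for c in model.clusters.values()]
    mutation_burden = int(sum(counts))
    clonal_burden = int(sum(1 for c in model.clusters.values()
                            if c.n_mutations >= 1 and c.ccf > noise_floor))
    median_mut = float(np.median([n for n in counts])) if counts else 0.0

    if model.architecture == "unresolved" or not model.tree_edges and len(model.clusters) > 1:
        weights = np.array([c.ccf for c in model.clusters.values()], dtype=float)
        method = "raw_ccf"
    else:
        weights = np.array(list(exclusive_fractions(model).values()), dtype=float)
        method = "tree"
    weights = weights[weights > 0]
    if weights.size == 0 or weights.sum() == 0:
        shannon = 0.0
    else:
        f = weights / weights.sum()
        shannon = float(-(f * np.log(f)).sum())

    med = float(np.median(vafs)) if len(vafs) else np.nan
    if not len(vafs) or med == 0:
        math_score = np.nan
    else:
        mad = float(np.median(np.abs(vafs - med)))
        math_score = 100.0 * 1.4826 * mad / med

    return HeterogeneityMetrics(
        patient_id=model.patient_id, mutation_burden=mutation_burden,
        clonal_burden=clonal_burden, median_mut_per_clone=median_mut,
        shannon=shannon, math_score=math_score, shannon_method=method,
    )


def architecture_survival(
    cohort: Cohort,
    models: dict[str, ClonalModel],
    metrics: dict[str, HeterogeneityMetrics] | None = None,
    min_per_class: int = 10,
) -> dict[str, SurvivalResult]:
    """Survival by architecture class and burden strata.

    Returns Cox results for branched vs linear, plus high-vs-low
    mutational burden (cohort-median split) within each class and a
    high-vs-low median-mutations-per-clone comparison.  Classes below
    ``min_per_class`` patients are skipped with a warning.
    """
    surv = cohort.patients.set_index("patient_id")[["os_time", "os_event"]].dropna()
    arch = {pid: m.architecture for pid, m in models.items() if pid in surv.index}
    out: dict[str, SurvivalResult] = {}

    branched = [p for p, a in arch.items() if a == "branched"]
    linear = [p for p, a in arch.items() if a == "linear"]
    if len(branched) >= min_per_class and len(linear) >= min_per_class:
        ids = branched + linear
        sub = surv.loc[ids]
        grp = sub.index.isin(branched).astype(int)
        out["branched_vs_linear"] = cox_univariate(
            sub["os_time"], sub["os_event"], grp, comparison="branched_vs_linear")
    else:
        warnings.warn(
            f"architecture_survival: class sizes branched={len(branched)} "
            f"linear={len(linear)} below {min_per_class}; comparison skipped")

    if metrics:
        burdens = {p: metrics[p].mutation_burden for p in arch if p in metrics}
        mpc = {p: metrics[p].median_mut_per_clone for p in arch if p in metrics}
        if burdens:
            cohort_median = float(np.median(list(burdens.values())))
            for label, ids in (("branched", branched), ("linear", linear), ("all", list(arch))):
                ids = [p for p in ids if p in burdens]
                hi = [p for p in ids if burdens[p] > cohort_median]
                lo = [p for p in ids if burdens[p] <= cohort_median]
                if len(hi) >= min_per_class and len(lo) >= min_per_class:
                    sub = surv.loc[hi + lo]
                    grp = sub.index.isin(hi).astype(int)
                    out[f"high_vs_low_burden_{label}"] = cox_univariate(
                        sub["os_time"], sub["os_event"], grp,
                        comparison=f"high_vs_low_burden_{label}")
        if mpc:
            med = float(np.median(list(mpc.values())))
            hi = [p for p in mpc if mpc[p] > med]
            lo = [p for p in mpc if mpc[p] <= med]
            if len(hi) >= min_per_class and len(lo) >= min_per_class:
                sub = surv.loc[hi + lo]
                grp = sub.index.isin(hi).astype(int)
                out["high_vs_low_mut_per_clone"] = cox_univariate(
                    sub["os_time"], sub["os_event"], grp,
                    comparison="high_vs_low_mut_per_clone")
    return out


def models_to_frame(models: dict[str, ClonalModel]) -> pd.DataFrame:
    rows = []
    for pid, m in sorted(models.items()):
        for cid, cl in sorted(m.clusters.items()):
            rows.append({
                "patient_id": pid, "cluster_id": cid, "ccf": cl.ccf, "se": cl.se,
                "n_mutations": cl.n_mutations, "parent": m.parent_of(cid) or "",
                "architecture": m.architecture, "founder": cid == m.founder_id,
            })
    return pd.DataFrame(rows)
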