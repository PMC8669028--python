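"""Synthetic AML cohort generator with known ground truth.

Every downstream stage assumes a particular statistical structure in the
data; this module generates cohorts that have it, so that recovery tests
exercise the whole pipeline against a known answer:

* per patient, a clone tree (linear chain or branched) with cellular
  fractions respecting the nesting and pigeonhole constraints exactly;
* mutation acquisition order drawn from a Plackett-Luce model over
  per-gene ability scores, so the Bradley-Terry fit downstream is
  correctly specified; earlier mutations sit in ancestral clones and the
  founder clone always carries the first-acquired mutation;
* observed VAFs are binomially noised read counts at Poisson depth,
  after copy-number events and male-X hemizygosity;
* survival is exponential with a log-hazard that is a linear combination
  of configured binary features (mutation status, true high VAF,
  branched architecture, pairwise order), so Cox proportional hazards
  holds exactly; censoring is an independent exponential clock
  calibrated to the target censoring fraction;
* drug AUCs carry planted linear VAF dependence for configured
  drug-gene pairs and baseline noise elsewhere, on a 0-300-type scale.

Branched trees are generated with near-equal sibling cellular fractions
(competing subclones of comparable fitness).  This is deliberate: it is
the only branched configuration identifiable from single-sample bulk
data, where well-separated fractions always admit a nested chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clonality import ClonalModel, model_from_assignments
from .cohort import Cohort
from .config import DEFAULT_CATEGORY_MAP, DEFAULT_SETTINGS
from .errors import ParameterError

#: (gene, prevalence, bt_ability, category, chrom) — prevalences follow the
#: frequency ranking of recurrently mutated de novo AML genes; abilities
#: encode early epigenetic / late signaling acquisition on the log scale.
DEFAULT_GENE_PANEL: list[tuple[str, float, float, str, str]] = [
    ("DNMT3A",   0.26,  1.5, "dna_methylation",      "2"),
    ("NPM1",     0.28,  0.5, "npm1",                 "5"),
    ("FLT3-ITD", 0.22, -1.5, "ras_rtk_signaling",    "13"),
    ("NRAS",     0.12, -1.0, "ras_rtk_signaling",    "1"),
    ("TET2",     0.12,  1.2, "dna_methylation",      "4"),
    ("RUNX1",    0.10,  0.6, "transcription_factor", "21"),
    ("IDH2",     0.10,  1.0, "dna_methylation",      "15"),
    ("IDH1",     0.08,  1.0, "dna_methylation",      "2"),
    ("FLT3-TKD", 0.08, -1.3, "ras_rtk_signaling",    "13"),
    ("ASXL1",    0.08,  0.9, "chromatin_cohesin",    "20"),
    ("SRSF2",    0.08,  0.8, "splicing",             "17"),
    ("CEBPA",    0.08,  0.3, "transcription_factor", "19"),
    ("TP53",     0.08,  1.1, "tumor_suppressor",     "17"),
    ("WT1",      0.06, -0.5, "tumor_suppressor",     "11"),
    ("PTPN11",   0.06, -0.9, "ras_rtk_signaling",    "12"),
    ("STAG2",    0.06,  0.7, "chromatin_cohesin",    "X"),
    ("KRAS",     0.05, -1.2, "ras_rtk_signaling",    "12"),
    ("GATA2",    0.05,  0.2, "transcription_factor", "3"),
    ("U2AF1",    0.05,  0.8, "splicing",             "21"),
    ("BCOR",     0.05,  0.4, "chromatin_cohesin",    "X"),
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 500
    gene_panel: list[tuple[str, float, float, str, str]] = field(
        default_factory=lambda: list(DEFAULT_GENE_PANEL))
    p_linear: float = 0.65
    mean_clones: float = 3.0
    max_clones: int = 5
    depth_mean: float = 500.0
    passenger_mut_mean: float = 0.0   # extra WES-style passenger variants/patient
    cn_event_rate: float = 0.05
    survival_effects: list[tuple[str, float]] = field(default_factory=list)
    baseline_hazard: float = 1.0 / 700.0   # events per day; median OS ~485 d
    censor_frac: float = 0.30
    drug_effects: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    drugs: list[str] = field(default_factory=list)
    drug_baseline_auc: float = 150.0
    drug_baseline_sd: float = 40.0
    clinical_effects: list[tuple[str, str, float]] = field(default_factory=list)
    subset_probs: dict = field(default_factory=lambda: {
        "de_novo": 0.72, "secondary": 0.18, "therapy_related": 0.10})
    male_frac: float = 0.55
    seed: int = 0

    def __post_init__(self):
        for _, prev, *_ in self.gene_panel:
            if not 0.0 < prev < 1.0:
                raise ParameterError("gene prevalences must lie in (0, 1)")
        if self.depth_mean < 30:
            raise ParameterError("depth_mean must be >= 30")


@dataclass
class PatientTruth:
    patient_id: str
    architecture: str                      # realized: linear | branched
    clone_ccf: dict[int, float]            # clone index -> true CCF
    tree_edges: list[tuple[int, int]]
    mutation_order: list[str]              # genes in acquisition order
    clone_of_variant: dict[str, int]       # variant_id -> clone index
    true_ccf: dict[str, float]             # variant_id -> true CCF


@dataclass
class GroundTruth:
    config: SimConfig
    patients: dict[str, PatientTruth]
    abilities: dict[str, float]
    resampled: int = 0

    def architecture_of(self, pid: str) -> str:
        return self.patients[pid].architecture


# ---------------------------------------------------------------- clinical

_CLINICAL_BASE = {
    # feature: (mean, sd, low, high)
    "age": (58.0, 13.0, 18.0, 92.0),
    "wbc": (30.0, 28.0, 0.4, 300.0),
    "hemoglobin": (9.3, 1.8, 4.0, 17.0),
    "platelets": (70.0, 55.0, 3.0, 450.0),
    "ldh": (600.0, 420.0, 80.0, 4000.0),
    "bm_blast_pct": (55.0, 22.0, 20.0, 100.0),
    "pb_blast_pct": (35.0, 26.0, 0.0, 100.0),
}


def _sample_tree(k: int, branched: bool, rng: np.random.Generator):
    """Clone CCFs + edges honoring nesting/sum constraints exactly.

    Linear: a nested chain with well-separated fractions.  Branched: the
    founder splits into two near-equal siblings; extra clones chain below
    the larger sibling.
    """
    ccf = {0: float(rng.uniform(0.85, 1.0))}
    edges: list[tuple[int, int]] = []
    if not branched or k < 3:
        for i in range(1, k):
            ccf[i] = ccf[i - 1] * float(rng.uniform(0.50, 0.72))
            edges.append((i - 1, i))
        return ccf, edges
    # competing sibling subclones take equal shares of the parent stick:
    # only statistically indistinguishable sibling CCFs make a branch
    # identifiable from one bulk sample
    total = ccf[0] * float(rng.uniform(0.75, 0.92))
    ccf[1] = total * 0.5
    ccf[2] = total * 0.5
    edges += [(0, 1), (0, 2)]
    parent = 1
    for i in range(3, k):
        ccf[i] = ccf[parent] * float(rng.uniform(0.50, 0.72))
        edges.append((parent, i))
        parent = i
    return ccf, edges


def _realized_architecture(edges: list[tuple[int, int]]) -> str:
    n_children: dict[int, int] = {}
    for p, _ in edges:
        n_children[p] = n_children.get(p, 0) + 1
    return "branched" if any(v >= 2 for v in n_children.values()) else "linear"


def _plackett_luce_order(genes: list[str], abilities: dict[str, float],
                         rng: np.random.Generator) -> list[str]:
    remaining = list(genes)
    order = []
    while remaining:
        w = np.exp(np.array([abilities[g] for g in remaining]))
        pick = rng.choice(len(remaining), p=w / w.sum())
        order.append(remaining.pop(int(pick)))
    return order


def _topological_order(edges: list[tuple[int, int]], k: int) -> list[int]:
    children: dict[int, list[int]] = {}
    for p, c in edges:
        children.setdefault(p, []).append(c)
    out, queue = [], [0]
    while queue:
        node = queue.pop(0)
        out.append(node)
        queue.extend(sorted(children.get(node, [])))
    return out if len(out) == k else list(range(k))


def _feature_evaluator(truth: PatientTruth, genes: set[str],
                       vaf_true: dict[str, float]):
    """Binary feature vocabulary used by ``survival_effects``.

    Supported features: ``mut:GENE``, ``vafgt:GENE:cut`` (true corrected
    VAF above cut), ``arch:branched``, ``order:A:B`` (both mutated, A
    acquired before B), ``triple:A:B:C`` (all three mutated).
    """
    order_index = {g: i for i, g in enumerate(truth.mutation_order)}

    def evaluate(name: str) -> float:
        kind, *parts = name.split(":")
        if kind == "mut":
            return float(parts[0] in genes)
        if kind == "vafgt":
            g, cut = parts[0], float(parts[1])
            return float(vaf_true.get(g, 0.0) > cut)
        if kind == "arch":
            return float(truth.architecture == parts[0])
        if kind == "order":
            a, b = parts
            return float(a in order_index and b in order_index
                         and order_index[a] < order_index[b])
        if kind == "triple":
            return float(all(g in genes for g in parts))
        raise ParameterError(f"unknown survival feature {name!r}")

    return evaluate


def simulate(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth from ``config`` (seeded)."""
    rng = np.random.default_rng(config.seed)
    abilities = {g: a for g, _, a, _, _ in config.gene_panel}
    prevalence = {g: p for g, p, _, _, _ in config.gene_panel}
    chrom_of = {g: c for g, _, _, _, c in config.gene_panel}
    panel_genes = [g for g, *_ in config.gene_panel]
    subset_labels = list(config.subset_probs)
    subset_p = np.array([config.subset_probs[s] for s in subset_labels], dtype=float)
    subset_p = subset_p / subset_p.sum()

    patient_rows, variant_rows, drug_rows = [], [], []
    truths: dict[str, PatientTruth] = {}
    resampled = 0

    clin_shift = {}  # (gene, feature) -> cohens_d
    for gene, feature, d in config.clinical_effects:
        clin_shift[(gene, feature)] = d

    censor_rate = config.baseline_hazard * config.censor_frac / max(1e-9, 1.0 - config.censor_frac)

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        sex = "M" if rng.random() < config.male_frac else "F"
        subset = subset_labels[int(rng.choice(len(subset_labels), p=subset_p))]

        mutated = [g for g in panel_genes if rng.random() < prevalence[g]]
        if not mutated:
            w = np.array([prevalence[g] for g in panel_genes])
            mutated = [panel_genes[int(rng.choice(len(panel_genes), p=w / w.sum()))]]
            resampled += 1

        order = _plackett_luce_order(mutated, abilities, rng)
        n_pass = int(rng.poisson(config.passenger_mut_mean)) if config.passenger_mut_mean > 0 else 0
        # acquisition sequence: drivers by Plackett-Luce, then passengers
        sequence = [(g, f"{pid}_{g}") for g in order]
        sequence += [("PASSENGER", f"{pid}_PASS{j}") for j in range(n_pass)]
        n_mut = len(sequence)

        k = int(np.clip(rng.poisson(config.mean_clones), 1, min(n_mut, config.max_clones)))
        branched_intent = rng.random() >= config.p_linear
        ccf, edges = _sample_tree(k, branched_intent, rng)
        architecture = _realized_architecture(edges)

        # clone occupancy: one mutation each, remainder uniform; fill clones
        # in topological order with mutations in acquisition order (founder
        # always carries the first-acquired driver)
        counts = np.ones(k, dtype=int)
        for _ in range(n_mut - k):
            counts[int(rng.integers(k))] += 1
        topo = _topological_order(edges, k)
        clone_of: dict[str, int] = {}
        true_ccf: dict[str, float] = {}
        cursor = 0
        for clone in topo:
            for _ in range(counts[clone]):
                _, vid = sequence[cursor]
                clone_of[vid] = clone
                true_ccf[vid] = ccf[clone]
                cursor += 1

        vaf_true_corrected: dict[str, float] = {}
        vaf_obs_corrected: dict[str, float] = {}
        for gene, vid in sequence:
            c = true_ccf[vid]
            chrom = chrom_of.get(gene, "7")
            x_linked = chrom == "X" and sex == "M"
            if x_linked:
                cn = 1
            elif rng.random() < config.cn_event_rate:
                cn = int(rng.choice([1, 3, 4], p=[0.3, 0.6, 0.1]))
            else:
                cn = 2
            raw_true = min(1.0, c * 1.0 / cn)
            depth = max(30, int(rng.poisson(config.depth_mean)))
            alt = int(rng.binomial(depth, raw_true))
            raw_obs = alt / depth
            variant_rows.append({
                "patient_id": pid, "gene": gene, "variant_id": vid,
                "chrom": chrom, "raw_vaf": raw_obs, "total_cn": cn,
                "multiplicity": 1,
            })
            if gene != "PASSENGER":
                vaf_true_corrected[gene] = min(1.0, raw_true * cn) / 2.0
                vaf_obs_corrected[gene] = min(1.0, raw_obs * cn) / 2.0

        truth = PatientTruth(
            patient_id=pid, architecture=architecture,
            clone_ccf=ccf, tree_edges=edges, mutation_order=order,
            clone_of_variant=dict(clone_of),
            true_ccf=dict(true_ccf),
        )
        truths[pid] = truth

        gene_set = set(mutated)
        evaluate = _feature_evaluator(truth, gene_set, vaf_true_corrected)
        loghaz = sum(log_hr * evaluate(name) for name, log_hr in config.survival_effects)
        t_event = rng.exponential(1.0 / (config.baseline_hazard * np.exp(loghaz)))
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / censor_rate)
        else:
            t_cens = np.inf
        os_time = float(min(t_event, t_cens))
        os_event = int(t_event <= t_cens)

        clin = {}
        for feature, (mu, sd, lo, hi) in _CLINICAL_BASE.items():
            shift = sum(d * sd for (g, f), d in clin_shift.items()
                        if f == feature and g in gene_set)
            clin[feature] = float(np.clip(rng.normal(mu + shift, sd), lo, hi))

        patient_rows.append({
            "patient_id": pid, "cohort": "synthetic", "subset": subset, "sex": sex,
            **{k2: round(v, 3) for k2, v in clin.items()},
            "os_time": round(os_time, 3), "os_event": os_event, "eln_risk": "",
        })

        # drug responses
        all_drugs = list(dict.fromkeys(
            list(config.drugs) + [d for d, *_ in config.drug_effects]))
        for drug in all_drugs:
            planted = None
            for d, gene, slope, intercept, noise_sd in config.drug_effects:
                if d == drug and gene in gene_set:
                    planted = (gene, slope, intercept, noise_sd)
                    break
            if planted is not None:
                gene, slope, intercept, noise_sd = planted
                auc = intercept + slope * vaf_obs_corrected[gene] + rng.normal(0.0, noise_sd)
            else:
                auc = rng.normal(config.drug_baseline_auc, config.drug_baseline_sd)
            drug_rows.append({"patient_id": pid, "drug": drug,
                              "auc": float(max(0.0, auc))})

    patients = pd.DataFrame(patient_rows)
    variants = pd.DataFrame(variant_rows)
    from .vaf import correct_vaf_frame
    variants = correct_vaf_frame(variants, patients.set_index("patient_id")["sex"])
    drugs = pd.DataFrame(drug_rows) if drug_rows else None
    cohort = Cohort(
        patients=patients, variants=variants, drugs=drugs,
        category_map=dict(DEFAULT_CATEGORY_MAP), settings=dict(DEFAULT_SETTINGS),
    )
    return cohort, GroundTruth(config=config, patients=truths,
                               abilities=abilities, resampled=resampled)


def clonal_models_from_truth(cohort: Cohort, truth: GroundTruth,
                             depth: int | None = None) -> dict[str, ClonalModel]:
    """Per-patient clonal models using *true* cluster memberships but
    *observed* CCFs — what a well-behaved clustering step would output."""
    depth = int(depth if depth is not None else truth.config.depth_mean)
    models = {}
    for pid, pt in truth.patients.items():
        sub = cohort.variants[cohort.variants["patient_id"] == pid]
        if not len(sub):
            continue
        labels = [pt.clone_of_variant[v] for v in sub["variant_id"]]
        models[pid] = model_from_assignments(
            pid, sub["ccf"].to_numpy(), np.asarray(labels),
            variant_ids=sub["variant_id"].tolist(), depth=depth)
    return models


def write_pyclone_table(cohort: Cohort, truth: GroundTruth, path) -> None:
    """PyClone-style loci table: observed per-variant cellular prevalence
    with the generator's true cluster memberships — what a well-behaved
    mutation-cluster inference would hand to the tree builder."""
    depth = truth.config.depth_mean
    rows = []
    for _, row in cohort.variants.iterrows():
        pid = row["patient_id"]
        ccf = float(row["ccf"])
        vaf_scale = ccf / 2.0
        rows.append({
            "mutation_id": row["variant_id"], "sample_id": pid,
            "cluster_id": truth.patients[pid].clone_of_variant[row["variant_id"]],
            "cellular_prevalence": ccf,
            "cellular_prevalence_std":
                2.0 * np.sqrt(max(vaf_scale * (1.0 - vaf_scale), 1e-12) / depth),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truth: GroundTruth, path) -> None:
    """Ground truth as a flat TSV (one row per variant)."""
    rows = []
    for pid, pt in sorted(truth.patients.items()):
        for vid, clone in pt.clone_of_variant.items():
            gene = vid.split("_", 1)[1]
            rows.append({
                "patient_id": pid, "variant_id": vid, "clone": clone,
                "true_ccf": pt.true_ccf[vid], "architecture": pt.architecture,
                "acquisition_rank": (pt.mutation_order.index(gene)
                                     if gene in pt.mutation_order else -1),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def truth_check(
    cohort: Cohort,
    truth: GroundTruth,
    bt_ranking=None,
    maxstat_threshold=None, maxstat_true_cut: float | None = None,
    survival_result=None, true_hr: float | None = None,
    arch_models: dict[str, ClonalModel] | None = None,
    screen_results=None,
) -> dict:
    """Recovery report comparing pipeline outputs to the ground truth."""
    report: dict = {}
    if bt_ranking is not None:
        common = [u for u in bt_ranking.units if u in truth.abilities]
        if len(common) >= 3:
            est = [bt_ranking.ability[bt_ranking.units.index(u)] for u in common]
            tru = [truth.abilities[u] for u in common]
            rho = stats.spearmanr(est, tru).statistic
            report["bt_spearman"] = float(rho)
    if maxstat_threshold is not None and maxstat_true_cut is not None:
        report["maxstat_cutpoint"] = float(maxstat_threshold.cutpoint)
        report["maxstat_cut_error"] = float(abs(maxstat_threshold.cutpoint - maxstat_true_cut))
    if survival_result is not None and true_hr is not None:
        report["hr_estimate"] = float(survival_result.hr)
        report["hr_bias"] = float(np.log(survival_result.hr) - np.log(true_hr))
    if arch_models is not None:
        pids = [p for p in arch_models if p in truth.patients]
        confusion = {"linear": {"linear": 0, "branched": 0, "unresolved": 0},
                     "branched": {"linear": 0, "branched": 0, "unresolved": 0}}
        correct = 0
        for p in pids:
            t = truth.patients[p].architecture
            e = arch_models[p].architecture
            confusion[t][e] += 1
            correct += int(t == e)
        report["architecture_confusion"] = confusion
        report["architecture_accuracy"] = correct / len(pids) if pids else np.nan
    if screen_results is not None:
        planted = {(d, g) for d, g, *_ in truth.config.drug_effects}
        hits = {(r.drug, r.unit) for r in screen_results if r.call != "none"}
        tested = {(r.drug, r.unit) for r in screen_results}
        planted_tested = planted & tested
        if planted_tested:
            report["screen_power"] = len(planted & hits) / len(planted_tested)
        null_tested = tested - planted
        if null_tested:
            report["screen_size"] = len(hits - planted) / len(null_tested)
    mismatch = set(truth.patients) - set(cohort.patients["patient_id"])
    if mismatch:
        raise ParameterError(f"truth/cohort patient sets differ: {sorted(mismatch)[:5]}...")
    return report
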