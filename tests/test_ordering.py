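"""Pairwise clonal dominance and Bradley-Terry acquisition ranking."""

import numpy as np
import pytest
from scipy import stats

from clonarch.errors import ParameterError
from clonarch.ordering import (
    OrderingCall, bt_loglik, bt_rank, classify_pair, ordering_survival,
    pairwise_dominance, pairwise_vaf_relation, win_matrix,
)
from clonarch.simulate import SimConfig, simulate

from conftest import build_cohort, patient_row, variant_row


class TestDominanceRule:
    @pytest.mark.parametrize("va,vb,expected", [
        (0.40, 0.30, "a_first"),      # clear 10-point lead
        (0.33, 0.30, "ambiguous"),    # inside the 5-point margin
        (0.35, 0.30, "a_first"),      # boundary: >= 5 points is dominant
        (0.30, 0.35, "b_first"),
        (0.30, 0.30, "ambiguous"),
    ])
    def test_margin_rule(self, va, vb, expected):
        assert classify_pair(va, vb, 0.05) == expected

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            va, vb = rng.uniform(0, 0.5, 2)
            mirror = {"a_first": "b_first", "b_first": "a_first",
                      "ambiguous": "ambiguous"}
            assert classify_pair(va, vb, 0.05) == mirror[classify_pair(vb, va, 0.05)]

    def test_margin_domain_checked(self, tiny_cohort):
        with pytest.raises(ParameterError):
            pairwise_dominance(tiny_cohort, margin=0.7)

    def test_calls_use_max_vaf_per_unit(self):
        # second DNMT3A variant at 0.10 must not flip the call
        patients = [patient_row("p1")]
        variants = [variant_row("p1", "DNMT3A", 0.40, variant_id="a"),
                    variant_row("p1", "DNMT3A", 0.10, variant_id="b"),
                    variant_row("p1", "NPM1", 0.30)]
        calls = pairwise_dominance(build_cohort(patients, variants))
        assert len(calls) == 1
        assert calls[0].unit_a == "DNMT3A" and calls[0].relation == "a_first"


def _call(pid, a, b, va, vb, margin=0.05):
    return OrderingCall(pid, a, b, va, vb, classify_pair(va, vb, margin), margin)


class TestBradleyTerry:
    def test_forced_two_unit_ordering_sets_separation_flag(self):
        calls = [_call(f"p{i}", "A", "B", 0.4, 0.2) for i in range(10)]
        rank = bt_rank(calls)
        assert rank.separation
        assert rank.units[int(np.argmin(rank.rank))] == "A"

    def test_three_unit_fit_matches_grid_oracle(self):
        # wins: A>B 8/2, B>C 7/3, A>C 9/1; oracle maximizes the likelihood
        # over a grid of 2 free log-abilities (third fixed by sum-to-zero)
        calls = []
        k = 0
        for a, b, w_ab, w_ba in [("A", "B", 8, 2), ("B", "C", 7, 3), ("A", "C", 9, 1)]:
            for _ in range(w_ab):
                calls.append(_call(f"p{k}", a, b, 0.4, 0.2)); k += 1
            for _ in range(w_ba):
                calls.append(_call(f"p{k}", a, b, 0.2, 0.4)); k += 1
        fit = bt_rank(calls, min_patients=2)
        units, w = win_matrix([c for c in calls if c.relation != "ambiguous"])
        grid = np.linspace(-3, 3, 301)
        best, best_ll = None, -np.inf
        for ba in grid:
            for bb in grid:
                beta = np.array([ba, bb, -ba - bb])
                ll = bt_loglik(w, beta)
                if ll > best_ll:
                    best_ll, best = ll, beta
        order = [units.index(u) for u in fit.units]
        assert np.allclose(fit.ability, best[order], atol=1e-3 + 0.02)
        assert fit.loglik_trace[-1] >= best_ll - 1e-6

    def test_loglik_nondecreasing_across_mm_iterations(self):
        rng = np.random.default_rng(11)
        calls = []
        for i in range(60):
            a, b = sorted(rng.choice(["A", "B", "C", "D"], 2, replace=False))
            va, vb = rng.uniform(0, 0.5, 2)
            calls.append(_call(f"p{i}", a, b, va, vb))
        fit = bt_rank(calls, min_patients=1)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_duplicating_patients_preserves_order_shrinks_se(self):
        rng = np.random.default_rng(13)
        calls = []
        for i in range(80):
            a, b = sorted(rng.choice(["A", "B", "C"], 2, replace=False))
            offset = {"A": 0.12, "B": 0.06, "C": 0.0}
            va = offset[a] + rng.uniform(0, 0.3)
            vb = offset[b] + rng.uniform(0, 0.3)
            calls.append(_call(f"p{i}", a, b, va, vb))
        fit1 = bt_rank(calls, min_patients=1)
        doubled = calls + [OrderingCall("d" + c.patient_id, c.unit_a, c.unit_b,
                                        c.vaf_a, c.vaf_b, c.relation, c.margin)
                           for c in calls]
        fit2 = bt_rank(doubled, min_patients=1)
        assert list(fit1.rank) == list(fit2.rank)
        assert (fit2.se <= fit1.se + 1e-12).all()

    def test_disconnected_graph_restricted_to_largest_component(self):
        calls = [_call(f"p{i}", "A", "B", 0.4, 0.2) for i in range(3)]
        calls += [_call(f"q{i}", "A", "B", 0.2, 0.4) for i in range(3)]
        calls += [_call("r0", "C", "D", 0.4, 0.2), _call("r1", "C", "D", 0.2, 0.4)]
        with pytest.warns(UserWarning, match="disconnected"):
            fit = bt_rank(calls, min_patients=3)
        assert set(fit.units) == {"A", "B"}
        assert set(fit.excluded_units) == {"C", "D"}

    def test_simulation_recovers_ability_ranking(self):
        # 10 genes, n=500 patients, depth 500: Spearman(recovered, true) >= 0.8
        cfg = SimConfig(n_patients=500, seed=7, depth_mean=500,
                        subset_probs={"de_novo": 1.0})
        panel = [g for g in cfg.gene_panel][:10]
        cfg.gene_panel = [(g, max(p, 0.15), a, c, ch) for g, p, a, c, ch in panel]
        cohort, truth = simulate(cfg)
        calls = pairwise_dominance(cohort, margin=0.05)
        fit = bt_rank(calls, min_patients=2)
        est = {u: fit.ability[i] for i, u in enumerate(fit.units)}
        common = [u for u in est if u in truth.abilities]
        rho = stats.spearmanr([est[u] for u in common],
                              [truth.abilities[u] for u in common]).statistic
        assert len(common) >= 8
        assert rho >= 0.8

    def test_margin_insensitivity_on_well_separated_fixture(self):
        # noiseless, well-separated VAFs: rankings agree from 1% to 10%
        rng = np.random.default_rng(19)
        calls_by_margin = {}
        for margin in (0.01, 0.10):
            calls = []
            for i in range(60):
                a, b = sorted(rng.choice(["A", "B", "C"], 2, replace=False))
                high = {"A": 0.45, "B": 0.30, "C": 0.15}
                calls.append(_call(f"p{i}", a, b, high[a], high[b], margin))
            calls_by_margin[margin] = bt_rank(calls, min_patients=1)
            rng = np.random.default_rng(19)
        assert list(calls_by_margin[0.01].rank) == list(calls_by_margin[0.10].rank)


class TestOrderingSurvival:
    def _ordered_cohort(self, n_per_arm, hr, seed=23):
        rng = np.random.default_rng(seed)
        patients, variants = [], []
        for i in range(2 * n_per_arm):
            pid = f"p{i}"
            a_first = i < n_per_arm
            haz = 0.002 * (hr if a_first else 1.0)
            t = float(rng.exponential(1 / haz))
            patients.append(patient_row(pid, os_time=t, os_event=1))
            va, vb = (0.45, 0.2) if a_first else (0.2, 0.45)
            variants.append(variant_row(pid, "AAA", va))
            variants.append(variant_row(pid, "BBB", vb))
        return build_cohort(patients, variants)

    def test_planted_ordering_effect_recovered(self):
        cohort = self._ordered_cohort(40, hr=2.0)
        res = ordering_survival(cohort, "AAA", "BBB")
        assert res is not None
        assert 1.4 <= res.hr <= 2.9
        assert res.n_arm1 == res.n_arm2 == 40

    def test_symmetric_null_hr_near_one(self):
        cohort = self._ordered_cohort(60, hr=1.0, seed=29)
        res = ordering_survival(cohort, "AAA", "BBB")
        assert abs(np.log(res.hr)) < np.log(1.6)

    def test_small_arm_skipped(self):
        cohort = self._ordered_cohort(3, hr=1.0)
        with pytest.warns(UserWarning, match="skipped"):
            assert ordering_survival(cohort, "AAA", "BBB", min_per_arm=5) is None


class TestPairwiseVafRelation:
    def test_planted_inverse_clonality_detected(self):
        rng = np.random.default_rng(31)
        patients, variants = [], []
        for i in range(30):
            pid = f"p{i}"
            patients.append(patient_row(pid))
            va = float(rng.uniform(0.05, 0.45))
            vb = 0.5 - va + float(rng.normal(0, 0.01))   # anti-correlated subclones
            variants.append(variant_row(pid, "NRAS", va))
            variants.append(variant_row(pid, "KRAS", min(max(vb, 0.01), 0.5)))
        table, rho, p = pairwise_vaf_relation(build_cohort(patients, variants),
                                              "NRAS", "KRAS")
        assert len(table) == 30
        assert rho < -0.8 and p < 1e-4

    def test_identical_columns_rho_one(self):
        patients = [patient_row(f"p{i}") for i in range(6)]
        variants = []
        for i in range(6):
            v = 0.1 + 0.05 * i
            variants += [variant_row(f"p{i}", "A", v), variant_row(f"p{i}", "B", v)]
        _, rho, _ = pairwise_vaf_relation(build_cohort(patients, variants), "A", "B")
        assert rho == pytest.approx(1.0)

    def test_constant_column_flagged_undefined(self):
        patients = [patient_row(f"p{i}") for i in range(6)]
        variants = []
        for i in range(6):
            variants += [variant_row(f"p{i}", "A", 0.3),
                         variant_row(f"p{i}", "B", 0.1 + 0.05 * i)]
        with pytest.warns(UserWarning, match="constant"):
            _, rho, _ = pairwise_vaf_relation(build_cohort(patients, variants), "A", "B")
        assert rho is None

    def test_below_floor_correlation_omitted(self):
        patients = [patient_row(f"p{i}") for i in range(3)]
        variants = []
        for i in range(3):
            variants += [variant_row(f"p{i}", "A", 0.3), variant_row(f"p{i}", "B", 0.2)]
        table, rho, _ = pairwise_vaf_relation(build_cohort(patients, variants), "A", "B")
        assert len(table) == 3 and rho is None
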