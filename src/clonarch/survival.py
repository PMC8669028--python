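"""Survival primitives shared by every analysis stage.

Univariate Cox proportional-hazards regression on a binary group label is
fit by Newton iteration on the partial likelihood with Breslow handling of
tied event times (Efron available as an option); the Wald 95% CI comes
from the observed information.  Log-rank p-values and Kaplan-Meier
summaries are delegated to lifelines.

A group with zero events produces a monotone partial likelihood; the fit
is flagged and the corresponding CI bound reported as infinite rather
than erroring out, since sparse-arm comparisons are routine in cohort
scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DegenerateDataError, ParameterError

Z95 = 1.959963984540054


@dataclass
class SurvivalResult:
    comparison: str
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n_arm1: int          # group == 1
    n_arm2: int          # group == 0
    q_value: float | None = None
    beta: float = np.nan
    se: float = np.nan
    monotone: bool = False   # zero events in one arm; HR at the boundary


def _breslow_derivs(beta: float, d1: np.ndarray, d_tot: np.ndarray, n1: np.ndarray, n0: np.ndarray):
    """Log-likelihood, score and information at beta (Breslow ties).

    Arrays are per distinct event time: deaths in arm 1, total deaths,
    arm sizes at risk.
    """
    eb = np.exp(beta)
    s0 = n0 + n1 * eb
    s1 = n1 * eb
    frac = s1 / s0
    loglik = float(np.sum(d1 * beta - d_tot * np.log(s0)))
    score = float(np.sum(d1 - d_tot * frac))
    info = float(np.sum(d_tot * frac * (1.0 - frac)))
    return loglik, score, info


def _efron_derivs(beta: float, time, event, group):
    eb = np.exp(beta)
    loglik = score = info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        d1 = int((dead & (group == 1)).sum())
        r1 = int((at_risk & (group == 1)).sum())
        r0 = int(at_risk.sum()) - r1
        s0, s1 = r0 + r1 * eb, r1 * eb
        t0, t1 = d - d1 + d1 * eb, d1 * eb
        loglik += d1 * beta
        for j in range(d):
            den0 = s0 - j / d * t0
            den1 = s1 - j / d * t1
            frac = den1 / den0
            loglik -= np.log(den0)
            score += -frac
            info += frac * (1.0 - frac)
    score += float(event[group == 1].sum())   # the +x_i terms, all event times
    return loglik, score, info


def breslow_loglik(beta: float, time, event, group) -> float:
    """Breslow partial log-likelihood at ``beta`` (oracle-friendly entry)."""
    d1, d_tot, n1, n0 = _risk_tables(np.asarray(time, float), np.asarray(event, int), np.asarray(group, int))
    return _breslow_derivs(beta, d1, d_tot, n1, n0)[0]


def _risk_tables(time, event, group):
    ts = np.unique(time[event == 1])
    d1 = np.array([(event[(time == t) & (group == 1)]).sum() for t in ts], dtype=float)
    d_tot = np.array([(event[time == t]).sum() for t in ts], dtype=float)
    n1 = np.array([((time >= t) & (group == 1)).sum() for t in ts], dtype=float)
    n0 = np.array([((time >= t) & (group == 0)).sum() for t in ts], dtype=float)
    return d1, d_tot, n1, n0


def cox_univariate(
    time,
    event,
    group,
    comparison: str = "",
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SurvivalResult:
    """Univariate Cox PH fit of a binary group indicator.

    Returns the hazard ratio of group 1 vs group 0 with Wald 95% CI and a
    two-sided log-rank p-value.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if set(np.unique(group)) - {0, 1}:
        raise ParameterError("group must be binary 0/1")
    n1, n0 = int((group == 1).sum()), int((group == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("both arms must be nonempty")
    ev1 = int(event[group == 1].sum())
    ev0 = int(event[group == 0].sum())
    if ev1 + ev0 == 0:
        raise DegenerateDataError("no events in either arm")

    monotone = ev1 == 0 or ev0 == 0
    if monotone:
        warnings.warn(f"{comparison or 'cox_univariate'}: zero events in one arm, monotone likelihood")

    d1, d_tot, nr1, nr0 = _risk_tables(time, event, group)
    beta = 0.0
    for _ in range(max_iter):
        if ties == "breslow":
            _, score, info = _breslow_derivs(beta, d1, d_tot, nr1, nr0)
        elif ties == "efron":
            _, score, info = _efron_derivs(beta, time, event, group)
        else:
            raise ParameterError(f"unknown tie method {ties!r}")
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        beta = float(np.clip(beta, -20.0, 20.0))
        if abs(step) < tol or abs(beta) >= 20.0:
            break

    if ties == "breslow":
        _, _, info = _breslow_derivs(beta, d1, d_tot, nr1, nr0)
    else:
        _, _, info = _efron_derivs(beta, time, event, group)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf

    hr = float(np.exp(beta))

    def _exp(x: float) -> float:
        return float(np.exp(np.clip(x, -700.0, 700.0))) if np.isfinite(x) else np.inf

    if monotone:
        # boundary fit: the CI is open on the event-free side
        ci_low = 0.0 if ev1 == 0 else _exp(beta - Z95 * se)
        ci_high = np.inf if ev0 == 0 else _exp(beta + Z95 * se)
    else:
        ci_low = _exp(beta - Z95 * se)
        ci_high = _exp(beta + Z95 * se)

    p = logrank(time, event, group)
    return SurvivalResult(
        comparison=comparison, hr=hr, ci_low=ci_low, ci_high=ci_high,
        logrank_p=p, n_arm1=n1, n_arm2=n0, beta=float(beta), se=se,
        monotone=monotone,
    )


def logrank(time, event, group) -> float:
    """Two-sided log-rank p-value (chi-square, 1 df) between two arms."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if (group == 1).sum() == 0 or (group == 0).sum() == 0:
        raise DegenerateDataError("log-rank needs two nonempty arms")
    res = logrank_test(time[group == 1], time[group == 0], event[group == 1], event[group == 0])
    return float(res.p_value)


def logrank_statistic(time, event, group) -> float:
    """Observed-minus-expected log-rank chi-square statistic (1 df)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    res = logrank_test(time[group == 1], time[group == 0], event[group == 1], event[group == 0])
    return float(res.test_statistic)


def km_summary(time, event, group=None) -> dict:
    """Kaplan-Meier product-limit estimates with Greenwood CIs per arm.

    Returns {label: {"timeline", "survival", "ci_low", "ci_high",
    "median", "n"}}; the median is NaN when the curve never crosses 0.5.
    With ``group=None`` a single arm labelled "all" is summarized.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.zeros(len(time), dtype=int) if group is None else np.asarray(group)
    out = {}
    for label in np.unique(group):
        mask = group == label
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        ci = kmf.confidence_interval_survival_function_
        key = "all" if len(np.unique(group)) == 1 else label
        out[key] = {
            "timeline": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
            "median": float(kmf.median_survival_time_),
            "n": int(mask.sum()),
        }
    return out
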