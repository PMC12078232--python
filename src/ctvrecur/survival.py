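"""Local-control statistics: Kaplan–Meier, log-rank, univariate Cox, 2x2 tables.

The event of interest is local failure (recurrence inside the treated
region); times are months of follow-up, censoring indicator 0.  The
fixed-horizon "3-year local control rate" is read as the Kaplan–Meier
survival proportion at 36 months.  Kaplan–Meier and the log-rank test are
delegated to lifelines; the univariate Cox model for a binary covariate is
a direct Newton–Raphson maximization of the partial likelihood with
Breslow (default) or Efron tie handling, which keeps the likelihood
convention explicit and testable against brute-force maximization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "SurvivalSample",
    "KaplanMeierResult",
    "kaplan_meier",
    "lc_rate_at",
    "log_rank",
    "cox_partial_loglik",
    "cox_univariate_binary",
    "CoxResult",
    "contingency_2x2",
    "ContingencyResult",
]


@dataclass(frozen=True)
class SurvivalSample:
    """One subject: follow-up time (months), event flag, optional group."""

    time_months: float
    event: int
    group: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_months) or self.time_months < 0:
            raise ValueError("time_months must be finite and >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _arrays(samples: Sequence[SurvivalSample]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([s.time_months for s in samples], dtype=float)
    e = np.asarray([s.event for s in samples], dtype=int)
    return t, e


@dataclass
class KaplanMeierResult:
    """Product-limit estimate: right-continuous step function + risk table."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # subjects at risk entering each time
    n_events: np.ndarray       # events at each time

    def at(self, t: float) -> float:
        """S(t): value of the step function at horizon t (S(0)=1)."""
        if t < 0:
            raise ValueError("horizon must be >= 0")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(samples: Sequence[SurvivalSample]) -> KaplanMeierResult:
    """Kaplan–Meier product-limit estimator.

    Ties are handled the standard way: all events at a time point are
    processed before censorings at the same time.
    """
    if len(samples) == 0:
        raise ValueError("need at least one subject")
    t, e = _arrays(samples)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table
    rows = ev[ev["observed"] > 0]
    times = rows.index.to_numpy(dtype=float)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(tt).iloc[0]) for tt in times]
    )
    return KaplanMeierResult(
        times=times,
        survival=surv,
        at_risk=rows["at_risk"].to_numpy(dtype=int),
        n_events=rows["observed"].to_numpy(dtype=int),
    )


def lc_rate_at(km: KaplanMeierResult, horizon_months: float) -> float:
    """Local-control proportion at a horizon: the KM step value there."""
    return km.at(horizon_months)


def log_rank(
    samples_a: Sequence[SurvivalSample],
    samples_b: Sequence[SurvivalSample],
) -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance, chi-square df=1)."""
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _arrays(samples_a)
    tb, eb = _arrays(samples_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Univariate Cox for a binary covariate
# ---------------------------------------------------------------------------


def cox_partial_loglik(
    beta: float,
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Cox partial log-likelihood for a scalar covariate.

    Breslow: each tied death set shares the full risk-set denominator d
    times.  Efron: the denominator is progressively discounted by the mean
    contribution of the tied deaths.
    """
    ll = 0.0
    exb = np.exp(beta * x)
    for t in np.unique(times[events == 1]):
        deaths = (times == t) & (events == 1)
        risk = times >= t
        d = int(deaths.sum())
        s_risk = exb[risk].sum()
        s_death = exb[deaths].sum()
        ll += beta * x[deaths].sum()
        if ties == "breslow":
            ll -= d * math.log(s_risk)
        elif ties == "efron":
            for k in range(d):
                ll -= math.log(s_risk - k / d * s_death)
        else:
            raise ValueError("ties must be 'breslow' or 'efron'")
    return float(ll)


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    n_iter: int


def cox_univariate_binary(
    samples: Sequence[SurvivalSample],
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Hazard ratio for a binary group covariate by Newton–Raphson.

    Wald 95% CI = exp(beta ± 1.96 se) with se from the observed
    information.  Raises on non-convergence (e.g. monotone likelihood when
    all events in one group precede the other group's follow-up).
    """
    t, e = _arrays(samples)
    x = np.asarray([s.group for s in samples], dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("group covariate must be binary 0/1")
    if len(np.unique(x)) < 2:
        raise ValueError("both covariate levels must be present")
    for g in (0.0, 1.0):
        if e[x == g].sum() == 0:
            raise ValueError(f"no events in group {int(g)}; HR not estimable")

    event_times = np.unique(t[e == 1])
    exb = None
    beta = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        exb = np.exp(beta * x)
        score = 0.0
        info = 0.0
        for tt in event_times:
            deaths = (t == tt) & (e == 1)
            risk = t >= tt
            d = int(deaths.sum())
            s0 = exb[risk].sum()
            s1 = (exb[risk] * x[risk]).sum()
            sd0 = exb[deaths].sum()
            sd1 = (exb[deaths] * x[deaths]).sum()
            if ties == "breslow":
                mu = s1 / s0
                score += x[deaths].sum() - d * mu
                info += d * (mu - mu * mu)   # x binary: E[x^2] = E[x]
            elif ties == "efron":
                for k in range(d):
                    f = k / d
                    den = s0 - f * sd0
                    num = s1 - f * sd1
                    mu = num / den
                    info += mu - mu * mu
                score += x[deaths].sum()
                score -= sum(
                    (s1 - k / d * sd1) / (s0 - k / d * sd0) for k in range(d)
                )
            else:
                raise ValueError("ties must be 'breslow' or 'efron'")
        if info <= 0 or not math.isfinite(score):
            raise RuntimeError(
                "Cox model did not converge (flat or monotone partial likelihood)"
            )
        delta = score / info
        beta += delta
        if abs(delta) < tol:
            break
    else:
        raise RuntimeError(
            f"Cox Newton–Raphson did not converge in {max_iter} iterations "
            f"(|step|={abs(delta):.3g}); the partial likelihood may be monotone"
        )
    if abs(beta) > 50:
        raise RuntimeError("Cox estimate diverged (monotone likelihood)")
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return CoxResult(
        hr=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        p_value=float(p),
        beta=float(beta),
        se=float(se),
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# 2x2 contingency statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str  # "chi2_cc" or "fisher_exact"


def contingency_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Odds ratio ad/bc with Woolf CI and an association p-value.

    Layout: rows are exposure levels, columns outcome levels —
    [[a, b], [c, d]].  The p-value is the continuity-corrected chi-square
    unless any expected cell count is below 5, in which case Fisher's exact
    test is used.  Zero margins make everything undefined and raise.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: statistics undefined")
    if b * c == 0 or a * d == 0:
        raise ValueError("zero cell: odds ratio undefined (no correction applied)")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _or, p = stats.fisher_exact([[a, b], [c, d]])
        test = "fisher_exact"
    else:
        _chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=True)
        test = "chi2_cc"
    return ContingencyResult(or_, lo, hi, float(p), test)
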