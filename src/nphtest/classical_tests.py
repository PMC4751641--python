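"""Cox partial-likelihood test, logrank test, scaled Schoenfeld residuals,
the Grambsch-Therneau test of non-proportional hazards, and the joint test.

The Cox model here has the binary treatment arm as its only covariate, so
the partial likelihood is one-dimensional and is maximized by a dedicated
Newton iteration.  Breslow's tie convention is the default because it makes
the Cox score test at ``beta = 0`` algebraically identical to the logrank
statistic on tie-free data, an equivalence the test suite exploits; Efron's
convention is available as an option.

The Grambsch-Therneau (GT) statistic is the 1-df score test of zero slope
in a regression of the scaled Schoenfeld residuals on (a transform of) the
event times; under proportional hazards that slope is zero in population.
The joint test adds the GT chisquare to the Cox partial-likelihood-ratio
chisquare and refers the sum to chisquare with 2 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .survdata import SurvivalData, DataError

__all__ = [
    "CoxResult",
    "GTResult",
    "ConvergenceError",
    "logrank_test",
    "cox_fit",
    "cox_score_chi2",
    "schoenfeld_scaled_residuals",
    "grambsch_therneau",
    "joint_test",
]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass(frozen=True)
class CoxResult:
    beta: float          # log hazard ratio (research vs control)
    se: float
    hr: float
    chi2_plr: float      # partial-likelihood-ratio chisquare, 1 df
    p_cox: float
    info: float          # observed information at beta-hat
    n_events: int
    ties: str
    n_iter: int


@dataclass(frozen=True)
class GTResult:
    chi2_gt: float
    p_gt: float
    time_transform: str


def _risk_tables(data: SurvivalData):
    """Aggregate to distinct event times: events per arm and at-risk per arm."""
    order = np.argsort(data.time, kind="stable")
    t, e, z = data.time[order], data.event[order], data.arm[order]
    et = t[e == 1]
    zt = z[e == 1]
    utimes, start = np.unique(et, return_index=True)
    d = np.diff(np.concatenate([start, [et.size]]))
    # events in research arm per distinct time
    s = np.add.reduceat(zt.astype(float), start)
    pos = np.searchsorted(t, utimes, side="left")
    n_at = t.size - pos
    cum1 = np.concatenate([[0.0], np.cumsum(z)])
    n1_at = z.sum() - cum1[pos]
    return utimes, d.astype(float), s, n_at.astype(float), n1_at.astype(float)


def _breslow_derivs(beta, d, s, n_at, n1_at):
    """(loglik, score, information) for the Breslow partial likelihood."""
    eb = np.exp(beta)
    denom = (n_at - n1_at) + n1_at * eb
    p = n1_at * eb / denom
    ll = float(np.sum(beta * s - d * np.log(denom)))
    u = float(np.sum(s - d * p))
    i = float(np.sum(d * p * (1.0 - p)))
    return ll, u, i


def _efron_derivs(beta, d, s, n_at, n1_at):
    """Efron tie handling: average the tied events out of the risk set."""
    eb = np.exp(beta)
    ll = u = i = 0.0
    for dk, sk, nk, n1k in zip(d, s, n_at, n1_at):
        dk = int(dk)
        j = np.arange(dk)
        a = (nk - n1k - (dk - sk) * j / dk) + (n1k - sk * j / dk) * eb
        da = (n1k - sk * j / dk) * eb
        ll += beta * sk - float(np.sum(np.log(a)))
        u += sk - float(np.sum(da / a))
        i += float(np.sum(da / a - (da / a) ** 2))
    return ll, u, i


_DERIVS = {"breslow": _breslow_derivs, "efron": _efron_derivs}


def cox_fit(data: SurvivalData, ties: str = "breslow", tol: float = 1e-10, max_iter: int = 50) -> CoxResult:
    """Maximize the one-covariate Cox partial likelihood by Newton iteration.

    ``chi2_plr = 2 [loglik(beta-hat) - loglik(0)]`` is the likelihood-ratio
    chisquare on 1 df; its upper-tail probability is the (two-sided) Cox test
    P-value.  Convergence: successive change in beta below ``tol``.  Monotone
    likelihood (all events in one arm) raises :class:`ConvergenceError`.
    """
    if ties not in _DERIVS:
        raise ValueError(f"unknown tie convention {ties!r}")
    data.require_two_arms(min_events=1)
    utimes, d, s, n_at, n1_at = _risk_tables(data)
    total_e = d.sum()
    if s.sum() == 0 or s.sum() == total_e:
        # every event in one arm: the partial likelihood is monotone in beta
        raise ConvergenceError("monotone partial likelihood: all events in one arm")
    derivs = _DERIVS[ties]
    ll0, _, _ = derivs(0.0, d, s, n_at, n1_at)
    beta = 0.0
    for it in range(1, max_iter + 1):
        ll, u, i = derivs(beta, d, s, n_at, n1_at)
        if i <= 0:
            raise ConvergenceError("nonpositive information during Newton iteration")
        step = u / i
        # dampen absurd steps from poor curvature far from the optimum
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
    ll, u, i = derivs(beta, d, s, n_at, n1_at)
    chi2 = max(2.0 * (ll - ll0), 0.0)
    return CoxResult(
        beta=float(beta),
        se=float(1.0 / np.sqrt(i)),
        hr=float(np.exp(beta)),
        chi2_plr=float(chi2),
        p_cox=float(stats.chi2.sf(chi2, 1)),
        info=float(i),
        n_events=int(total_e),
        ties=ties,
        n_iter=it,
    )


def cox_score_chi2(data: SurvivalData, ties: str = "breslow") -> float:
    """Score-test chisquare of the treatment coefficient at ``beta = 0``."""
    data.require_two_arms(min_events=1)
    _, d, s, n_at, n1_at = _risk_tables(data)
    _, u, i = _DERIVS[ties](0.0, d, s, n_at, n1_at)
    return float(u * u / i)


def logrank_test(data: SurvivalData) -> tuple[float, float]:
    """Two-sample logrank chisquare (1 df, hypergeometric variance) and P-value."""
    data.require_two_arms(min_events=1)
    from lifelines.statistics import logrank_test as _ll_logrank

    a0, a1 = data.subset(0), data.subset(1)
    res = _ll_logrank(a0.time, a1.time, event_observed_A=a0.event, event_observed_B=a1.event)
    return float(res.test_statistic), float(res.p_value)


def schoenfeld_scaled_residuals(fit: CoxResult, data: SurvivalData):
    """Scaled Schoenfeld residuals, one per event, at the fitted ``beta``.

    Raw residual at an event: observed arm minus the risk-set expectation of
    the arm covariate; scaled residual: ``beta + n_events * info^{-1} * raw``.
    Returns ``(event_times, scaled, raw)``, event-time ascending.
    """
    order = np.argsort(data.time, kind="stable")
    t, e, z = data.time[order], data.event[order], data.arm[order]
    ev = e == 1
    if ev.sum() < 2:
        raise DataError("need at least 2 events for Schoenfeld residuals")
    utimes, d, s, n_at, n1_at = _risk_tables(data)
    eb = np.exp(fit.beta)
    p = n1_at * eb / ((n_at - n1_at) + n1_at * eb)  # risk-set expectation of z
    expect = p[np.searchsorted(utimes, t[ev])]
    raw = z[ev].astype(float) - expect
    scaled = fit.beta + fit.n_events * raw / fit.info
    return t[ev], scaled, raw


def _gt_statistic(g: np.ndarray, raw: np.ndarray, n_events: int, info: float) -> float:
    """GT score chisquare from transformed event times and raw residuals."""
    gc = g - g.mean()
    ss = float(np.sum(gc * gc))
    if ss == 0:
        raise DataError("zero variance of the time transform (all events at one time?)")
    num = float(np.sum(gc * raw))
    return n_events / info * num * num / ss


_TRANSFORMS = ("identity", "rank", "km")


def grambsch_therneau(
    fit: CoxResult, data: SurvivalData, time_transform: str = "identity"
) -> GTResult:
    """Grambsch-Therneau 1-df score test for non-proportional hazards.

    Regresses the scaled Schoenfeld residuals on transformed event time and
    tests zero slope.  Transforms: ``identity`` (raw time, the default),
    ``rank`` (rank of the event among events), ``km`` (1 minus the pooled
    Kaplan-Meier survival just before the event, which spaces events by
    observed information).
    """
    if time_transform not in _TRANSFORMS:
        raise ValueError(f"unknown time_transform {time_transform!r}")
    times, _, raw = schoenfeld_scaled_residuals(fit, data)
    if time_transform == "identity":
        g = times.astype(float)
    elif time_transform == "rank":
        g = stats.rankdata(times, method="average")
    else:
        from .km_rmst import kaplan_meier

        km = kaplan_meier(data)
        # S just before each event time: left-continuous evaluation
        idx = np.searchsorted(km.times, times, side="left")
        s_prev = np.concatenate([[1.0], km.surv])[idx]
        g = 1.0 - s_prev
    chi2 = _gt_statistic(g, raw, fit.n_events, fit.info)
    return GTResult(float(chi2), float(stats.chi2.sf(chi2, 1)), time_transform)


def joint_test(cox: CoxResult, gt: GTResult) -> tuple[float, float]:
    """Joint test: Cox LR chisquare plus GT chisquare, referred to chi2(2).

    The 2-df upper tail is ``exp(-chi2/2)``.
    """
    chi2 = cox.chi2_plr + gt.chi2_gt
    return float(chi2), float(np.exp(-chi2 / 2.0))
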