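"""Flexible parametric (spline-on-log-cumulative-hazard) survival models:
fitting, simulation, and the four trial scenarios.

The model places a restricted cubic spline ``s(x)`` in log time
``x = ln t`` on the log cumulative hazard scale:
``ln H(t) = s(ln t)``, so ``S(t) = exp(-exp(s(ln t)))``.  With no interior
knots (df = 1) the model is Weibull (``s = g0 + g1 x``); added knots let the
cumulative hazard bend.  Restricted cubic splines are linear beyond the
boundary knots, which keeps tail extrapolation sane and makes inversion
sampling cheap.

Scenarios for simulation studies of two-arm trials:

- **A** (global null): one dataset from a single model, split at random 1:1;
- **B** (proportional hazards): research-arm log cumulative hazard equals
  the control's plus a constant ``ln HR`` (default ln 0.75);
- **C** (early effect): independent control and research models, the
  research model built to have a hazard ratio well below 1 early in
  follow-up and above 1 later;
- **D** (late effect): the control log cumulative hazard perturbed by a
  decreasing logistic function of log time, giving HR(t) = 1 up to about
  one time unit and < 1 thereafter.

Censoring is simulated from its own model (fitted to the data with the
event indicator reversed, or specified directly) and applied as
``min(event time, censoring time)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .survdata import SurvivalData, DataError

__all__ = [
    "RPModel",
    "LateEffectModel",
    "PointMassCensoring",
    "UniformAccrualCensoring",
    "ScenarioSpec",
    "FitError",
    "fit_rp",
    "fit_censoring_model",
    "simulate_survival",
    "apply_ph_shift",
    "apply_late_effect",
    "default_control_model",
    "make_early_effect_models",
    "scenario_generate",
]


class FitError(RuntimeError):
    """Maximum-likelihood fit failed or produced a nonmonotone cumulative hazard."""


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline design matrix: columns ``1, x, v_1..v_m``.

    ``knots[0]`` and ``knots[-1]`` are boundary knots; the basis is linear
    outside them.
    """
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    cube = lambda u: np.maximum(u, 0.0) ** 3
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        cols.append(cube(x - kj) - lam * cube(x - kmin) - (1 - lam) * cube(x - kmax))
    return np.column_stack(cols)


def rcs_basis_deriv(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(x), np.ones_like(x)]
    sq = lambda u: np.maximum(u, 0.0) ** 2
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        cols.append(3.0 * (sq(x - kj) - lam * sq(x - kmin) - (1 - lam) * sq(x - kmax)))
    return np.column_stack(cols)


def _bisect_monotone(f, target: np.ndarray, lo: np.ndarray, hi: np.ndarray, tol: float = 1e-10):
    """Vectorized bisection for a monotone-increasing f; brackets given per element."""
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        high = f(mid) > target
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class RPModel:
    """Restricted-cubic-spline model of the log cumulative hazard on log time.

    ``coef`` has length df + 1: intercept, linear term, and one coefficient
    per interior knot.  The implied cumulative hazard must be nondecreasing
    over the support between the boundary knots (checked numerically).
    """

    knots: np.ndarray   # log-time scale, ascending; first/last are boundary knots
    coef: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        coef = np.asarray(self.coef, dtype=float)
        if knots.size < 2 or (np.diff(knots) <= 0).any():
            raise ValueError("knots must be ascending with distinct boundary knots")
        if coef.size != knots.size:
            # m interior knots -> m + 2 coefficients == len(knots) when m >= 0? no:
            # len(knots) = m + 2 boundary-inclusive, basis size = m + 2. They match.
            raise ValueError(f"expected {knots.size} coefficients, got {coef.size}")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "coef", coef)

    @property
    def df(self) -> int:
        return self.coef.size - 1

    # spline and derived quantities ------------------------------------
    def s(self, x):
        out = rcs_basis(np.atleast_1d(x), self.knots) @ self.coef
        return float(out[0]) if np.ndim(x) == 0 else out

    def s_prime(self, x):
        out = rcs_basis_deriv(np.atleast_1d(x), self.knots) @ self.coef
        return float(out[0]) if np.ndim(x) == 0 else out

    def log_cum_hazard(self, t):
        return self.s(np.log(np.asarray(t, dtype=float)))

    def cum_hazard(self, t):
        return np.exp(self.log_cum_hazard(t))

    def survival(self, t):
        return np.exp(-self.cum_hazard(t))

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        x = np.log(t)
        return np.exp(self.s(x)) * self.s_prime(x) / t

    def check_monotone(self, n_grid: int = 200) -> None:
        """Verify the cumulative hazard is nondecreasing over the knot span."""
        xs = np.linspace(self.knots[0], self.knots[-1], n_grid)
        sp = self.s_prime(xs)
        if sp.min() < -1e-9:
            bad = float(np.exp(xs[int(np.argmin(sp))]))
            raise FitError(f"nonmonotone cumulative hazard near t = {bad:.4g}")

    # sampling ----------------------------------------------------------
    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inversion sampling: solve ``s(ln t) = ln(-ln U)`` per draw.

        The spline is linear beyond the boundary knots, so tail draws invert
        in closed form; interior draws use bisection to 1e-10 in ``ln t``.
        """
        u = rng.uniform(size=n)
        target = np.log(-np.log(u))
        k0, k1 = self.knots[0], self.knots[-1]
        s0, s1 = float(self.s(np.array([k0]))[0]), float(self.s(np.array([k1]))[0])
        slope_lo = float(self.s_prime(np.array([k0]))[0])
        slope_hi = float(self.s_prime(np.array([k1]))[0])
        if slope_lo <= 0 or slope_hi <= 0:
            raise FitError("spline slope nonpositive at a boundary knot; cannot invert")
        x = np.empty(n)
        left = target < s0
        right = target > s1
        mid = ~(left | right)
        x[left] = k0 + (target[left] - s0) / slope_lo
        x[right] = k1 + (target[right] - s1) / slope_hi
        if mid.any():
            x[mid] = _bisect_monotone(
                self.s, target[mid], np.full(mid.sum(), k0), np.full(mid.sum(), k1)
            )
        return np.exp(x)

    # serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"knots": self.knots.tolist(), "coef": self.coef.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RPModel":
        obj = json.loads(text)
        return cls(np.asarray(obj["knots"]), np.asarray(obj["coef"]))


def default_control_model(rate: float = 0.25) -> RPModel:
    """Exponential control distribution expressed exactly as a df = 1 model.

    ``s(x) = ln(rate) + x`` gives ``H(t) = rate * t``.  The default rate of
    0.25 per year puts the median near 2.8 years, a typical maturity for an
    overall-survival outcome in an oncology trial.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    # boundary knots span the 0.1 % to 99.95 % quantiles; the spline is
    # globally linear here, so they only delimit the inversion bracket
    return RPModel(np.log([0.001 / rate, 7.6 / rate]), np.array([np.log(rate), 1.0]))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _neg_loglik(coef, basis_all, basis_ev, dbasis_ev, x_ev):
    s_all = basis_all @ coef
    s_ev = basis_ev @ coef
    sp_ev = dbasis_ev @ coef
    pen = 0.0
    grad_pen = np.zeros_like(coef)
    bad = sp_ev <= 1e-10
    if bad.any():
        v = np.minimum(sp_ev - 1e-10, 0.0)
        pen = 1e6 * float(v @ v)
        grad_pen = 1e6 * 2.0 * (v[:, None] * dbasis_ev).sum(axis=0)
        sp_ev = np.maximum(sp_ev, 1e-10)
    H = np.exp(np.clip(s_all, -700, 700))
    ll = float(np.sum(s_ev + np.log(sp_ev) - x_ev) - np.sum(H))
    grad = (
        basis_ev.sum(axis=0)
        + (dbasis_ev / sp_ev[:, None]).sum(axis=0)
        - (H[:, None] * basis_all).sum(axis=0)
    )
    return -(ll - pen), -(grad - grad_pen)


def _place_knots(x_events: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at min/max of the log event times, interior knots at
    equally spaced centiles (df = 3: the 33rd and 67th)."""
    qs = np.linspace(0, 100, df + 1)[1:-1]
    interior = np.percentile(x_events, qs) if df > 1 else np.array([])
    return np.concatenate([[x_events.min()], np.atleast_1d(interior), [x_events.max()]])


def fit_rp(data: SurvivalData, df: int = 3) -> RPModel:
    """Fit the spline model to one sample (no covariates) by maximum likelihood.

    The likelihood uses the event contribution ``ln h(t) + ln S(t)`` and the
    censoring contribution ``ln S(t)``.  Initial values come from a least
    squares fit of the spline to the log Nelson-Aalen cumulative hazard.
    The fitted cumulative hazard is verified nondecreasing before returning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    ev_times = data.time[data.event == 1]
    if np.unique(ev_times).size < df + 2:
        raise DataError(f"need at least {df + 2} distinct uncensored event times for df={df}")
    x_ev = np.log(ev_times)
    knots = _place_knots(x_ev, df)
    if np.unique(knots).size != knots.size:
        raise DataError("degenerate knot placement (too many tied event times)")
    x_all = np.log(data.time)
    basis_all = rcs_basis(x_all, knots)
    basis_ev = rcs_basis(x_ev, knots)
    dbasis_ev = rcs_basis_deriv(x_ev, knots)

    # Nelson-Aalen based least squares start
    order = np.argsort(data.time, kind="stable")
    t_s, e_s = data.time[order], data.event[order]
    at_risk = t_s.size - np.arange(t_s.size)
    na = np.cumsum(np.where(e_s == 1, 1.0 / at_risk, 0.0))
    mask = (e_s == 1) & (na > 0)
    b0 = rcs_basis(np.log(t_s[mask]), knots)
    coef0, *_ = np.linalg.lstsq(b0, np.log(na[mask]), rcond=None)

    res = optimize.minimize(
        _neg_loglik,
        coef0,
        args=(basis_all, basis_ev, dbasis_ev, x_ev),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-7, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        raise FitError("likelihood maximization diverged")
    model = RPModel(knots, res.x)
    model.check_monotone()
    return model


@dataclass(frozen=True)
class PointMassCensoring:
    """Administrative censoring at a single fixed time."""

    time: float

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, float(self.time))


@dataclass(frozen=True)
class UniformAccrualCensoring:
    """Staggered entry: uniform accrual over ``accrual``, analysis at ``duration``.

    A subject entering at ``u ~ U(0, accrual)`` is administratively censored
    at follow-up ``duration - u``.
    """

    accrual: float
    duration: float

    def __post_init__(self) -> None:
        if not 0 < self.accrual <= self.duration:
            raise ValueError("need 0 < accrual <= duration")

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.duration - rng.uniform(0.0, self.accrual, size=n)


def fit_censoring_model(data: SurvivalData, df: int = 3):
    """Model the time-to-censoring distribution by reversing the event indicator.

    Returns ``None`` when nothing is censored, a :class:`PointMassCensoring`
    when all censoring happens at (essentially) one time, and otherwise a
    fitted :class:`RPModel` (with ``df`` reduced if there are too few
    distinct censoring times to support it).
    """
    cens_times = data.time[data.event == 0]
    if cens_times.size == 0:
        return None
    distinct = np.unique(cens_times)
    if distinct.size == 1 or np.ptp(distinct) < 1e-12:
        return PointMassCensoring(float(distinct[0]))
    df_eff = min(df, max(1, distinct.size - 2))
    flipped = SurvivalData(data.time, 1 - data.event, data.arm)
    return fit_rp(flipped, df=df_eff)


def simulate_survival(model, n: int, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` event times from any model exposing ``simulate(n, rng)``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return model.simulate(n, rng)


def apply_ph_shift(model: RPModel, ln_hr: float) -> RPModel:
    """Add ``ln_hr`` to the spline intercept: the cumulative (and therefore
    instantaneous) hazard is multiplied by ``exp(ln_hr)`` exactly."""
    coef = model.coef.copy()
    coef[0] += ln_hr
    return RPModel(model.knots, coef)


@dataclass(frozen=True)
class LateEffectModel:
    """Research arm for the late-effect scenario.

    The control log cumulative hazard is perturbed by a decreasing logistic
    function of log time:
    ``ln H1(t) = s0(ln t) + c(ln t)`` with
    ``c(x) = -theta * expit((x - ln t0) / tau)``, so the perturbation is
    ~0 for small t (no early effect) and tends to ``-theta`` late.  The
    hazard ratio follows analytically from the spline derivatives:
    ``HR(t) = exp(c) * (1 + c'(x) / s0'(x))``.
    """

    control: RPModel
    theta: float = 0.4
    t0: float = 3.2
    tau: float = 0.22

    def _c(self, x):
        return -self.theta * special.expit((x - np.log(self.t0)) / self.tau)

    def _c_prime(self, x):
        sig = special.expit((x - np.log(self.t0)) / self.tau)
        return -self.theta / self.tau * sig * (1.0 - sig)

    def s(self, x):
        return self.control.s(x) + self._c(x)

    def log_cum_hazard(self, t):
        return self.s(np.log(np.asarray(t, dtype=float)))

    def cum_hazard(self, t):
        return np.exp(self.log_cum_hazard(t))

    def survival(self, t):
        return np.exp(-self.cum_hazard(t))

    def hr_function(self, t):
        """Research/control hazard ratio as a function of time (analytic)."""
        x = np.log(np.asarray(t, dtype=float))
        return np.exp(self._c(x)) * (1.0 + self._c_prime(x) / self.control.s_prime(x))

    def validate(self, t_lo: float = 0.02, t_hi: float = 50.0, n_grid: int = 400) -> None:
        """Reject parameter sets whose implied hazard would go nonpositive."""
        t = np.geomspace(t_lo, t_hi, n_grid)
        hr = self.hr_function(t)
        if hr.min() <= 0:
            bad = float(t[int(np.argmin(hr))])
            raise ValueError(f"late-effect parameters give nonpositive hazard at t = {bad:.4g}")

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(size=n)
        target = np.log(-np.log(u))
        lo = np.full(n, self.control.knots[0] - 5.0)
        hi = np.full(n, self.control.knots[-1] + 5.0)
        # expand brackets geometrically until they straddle every target
        step = 5.0
        for _ in range(60):
            low_bad = self.s(lo) > target
            high_bad = self.s(hi) < target
            if not (low_bad.any() or high_bad.any()):
                break
            lo = np.where(low_bad, lo - step, lo)
            hi = np.where(high_bad, hi + step, hi)
            step *= 2.0
        else:
            raise FitError("could not bracket the inversion root")
        return np.exp(_bisect_monotone(self.s, target, lo, hi))


def apply_late_effect(
    control: RPModel,
    theta: float = 0.4,
    t0: float = 3.2,
    tau: float = 0.22,
    validate: bool = True,
) -> LateEffectModel:
    """Build the late-effect research model; defaults are calibrated so that
    (against the default exponential control) the hazard ratio stays within
    2 % of 1 for t <= 1 and falls below 0.8 by t = 3."""
    model = LateEffectModel(control, theta, t0, tau)
    if validate:
        model.validate()
    return model


def make_early_effect_models(
    rate: float = 0.25,
    hr_early: float = 0.5,
    hr_late: float = 1.2,
    changepoint: float | None = None,
    df: int = 3,
) -> tuple[RPModel, RPModel]:
    """Canned control/research model pair with a qualitative early effect.

    The control is exponential; the research arm targets a hazard of
    ``hr_early`` times control before the control median (default
    changepoint) and ``hr_late`` times after, smoothed by projecting the
    piecewise log cumulative hazard onto the spline basis by least squares.
    """
    control = default_control_model(rate)
    cp = changepoint if changepoint is not None else np.log(2.0) / rate
    t = np.geomspace(cp / 50.0, cp * 12.0, 400)
    h1 = np.where(
        t <= cp, hr_early * rate * t, hr_early * rate * cp + hr_late * rate * (t - cp)
    )
    x = np.log(t)
    knots = np.concatenate(
        [[x[0]], np.log([cp * 0.6, cp * 2.0])[: max(df - 1, 0)], [x[-1]]]
    )
    basis = rcs_basis(x, knots)
    coef, *_ = np.linalg.lstsq(basis, np.log(h1), rcond=None)
    research = RPModel(knots, coef)
    research.check_monotone()
    return control, research


# ---------------------------------------------------------------------------
# Scenario machinery


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one simulated trial scenario (A, B, C or D)."""

    scenario: str
    n: int
    control: RPModel = field(default_factory=default_control_model)
    allocation: float = 0.5
    ln_hr: float = float(np.log(0.75))
    research: object | None = None          # scenario C: independent research model
    theta: float = 0.4                      # scenario D perturbation
    t0: float = 3.2
    tau: float = 0.22
    censoring: object | None = None         # anything with simulate(n, rng)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation must lie in (0, 1)")


def _research_model(spec: ScenarioSpec):
    if spec.scenario == "B":
        return apply_ph_shift(spec.control, spec.ln_hr)
    if spec.scenario == "C":
        if spec.research is not None:
            return spec.research
        if spec.control.df == 1 and np.isclose(spec.control.coef[1], 1.0):
            return make_early_effect_models(rate=float(np.exp(spec.control.coef[0])))[1]
        raise ValueError("scenario C needs an explicit research model for this control")
    if spec.scenario == "D":
        return apply_late_effect(spec.control, spec.theta, spec.t0, spec.tau)
    raise AssertionError(spec.scenario)


def scenario_generate(spec: ScenarioSpec) -> SurvivalData:
    """Simulate one trial replicate under the given scenario.

    Scenario A draws the whole sample from the control model and splits it
    at random (exchangeable null); B-D draw each arm from its own model and
    concatenate.  Censoring, when specified, is drawn independently and
    applied as ``min(T, C)``.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n * spec.allocation))
    n0 = spec.n - n1
    if spec.scenario == "A":
        time = spec.control.simulate(spec.n, rng)
        arm = rng.permutation(np.repeat([0, 1], [n0, n1]))
    else:
        research = _research_model(spec)
        time = np.concatenate(
            [spec.control.simulate(n0, rng), research.simulate(n1, rng)]
        )
        arm = np.repeat([0, 1], [n0, n1])
    event = np.ones(spec.n, dtype=int)
    if spec.censoring is not None:
        cens = np.asarray(spec.censoring.simulate(spec.n, rng), dtype=float)
        event = (time <= cens).astype(int)
        time = np.maximum(np.minimum(time, cens), np.finfo(float).tiny)
    return SurvivalData(time, event, arm)
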