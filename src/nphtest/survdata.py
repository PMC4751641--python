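"""Subject-level survival data: container, delimited-text I/O, and parametric fixtures.

The universal input to every test in this package is a set of subject records
``(time, event, arm)``: a positive follow-up time, a binary event indicator
(1 = event observed, 0 = censored) and a binary treatment arm (0 = control,
1 = research).  Times are taken at face value in whatever unit the caller
uses (typically years); the package never rescales them.

The fixture generator draws event times from simple parametric families
(exponential, Weibull, piecewise exponential) with an optional two-piece
hazard-ratio pattern between arms, and applies administrative and/or
staggered-entry censoring.  It stands in for real trial data in all tests
and simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalData",
    "FixtureSpec",
    "read_survival",
    "write_survival",
    "make_fixture",
]


class DataError(ValueError):
    """Raised when subject records violate the container invariants."""


@dataclass(frozen=True)
class SurvivalData:
    """Immutable subject-level records ``(time, event, arm)``.

    Invariants: all times strictly positive and finite; ``event`` and ``arm``
    take values in {0, 1} only.  Row order is preserved exactly as given.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        arm = np.asarray(self.arm)
        if not (time.shape == event.shape == arm.shape) or time.ndim != 1:
            raise DataError("time, event and arm must be 1-d arrays of equal length")
        bad = ~np.isfinite(time) | (time <= 0)
        if bad.any():
            raise DataError(f"nonpositive or non-finite time at row {int(np.flatnonzero(bad)[0])}")
        for name, col in (("event", event), ("arm", arm)):
            vals = np.asarray(col, dtype=float)
            ok = (vals == 0) | (vals == 1)
            if not ok.all():
                raise DataError(f"non-binary {name} at row {int(np.flatnonzero(~ok)[0])}")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))
        object.__setattr__(self, "arm", arm.astype(np.int8))
        self.time.setflags(write=False)
        self.event.setflags(write=False)
        self.arm.setflags(write=False)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, arm: int) -> "SurvivalData":
        """Records of a single treatment arm."""
        mask = self.arm == arm
        return SurvivalData(self.time[mask], self.event[mask], self.arm[mask])

    def with_arm(self, arm: np.ndarray) -> "SurvivalData":
        """Same times and events under a different arm labelling (permutations)."""
        return SurvivalData(self.time, self.event, arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})

    def require_two_arms(self, min_events: int = 2) -> None:
        """Validate the extra invariants demanded by the two-sample tests."""
        for a in (0, 1):
            if (self.arm == a).sum() < 1:
                raise DataError(f"arm {a} contains no subjects")
        if self.n_events < min_events:
            raise DataError(f"need at least {min_events} pooled events, found {self.n_events}")


def read_survival(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SurvivalData:
    """Read delimited text (comma or tab, header required) into :class:`SurvivalData`.

    ``columns`` remaps file column names onto the canonical ``time``, ``event``,
    ``arm``; ``sep=None`` sniffs comma versus tab from the header line.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    colmap = {"time": "time", "event": "event", "arm": "arm"}
    if columns:
        colmap.update(columns)
    missing = [v for v in colmap.values() if v not in frame.columns]
    if missing:
        raise DataError(f"missing column(s) {missing} in {path}")
    return SurvivalData(
        frame[colmap["time"]].to_numpy(dtype=float),
        frame[colmap["event"]].to_numpy(),
        frame[colmap["arm"]].to_numpy(),
    )


def write_survival(data: SurvivalData, path: str | Path, sep: str = ",") -> None:
    """Write records as delimited text with a header row; inverse of :func:`read_survival`."""
    data.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Parametric fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic two-arm trial dataset.

    ``family`` names the control-arm event-time distribution; the research arm
    multiplies the control hazard by a two-piece function determined by
    ``effect``:

    - ``"null"``  — multiplier 1 throughout (identical distributions);
    - ``"ph"``    — constant multiplier ``hr`` (proportional hazards);
    - ``"early"`` — ``hr_early`` before ``changepoint``, ``hr_late`` after
      (treatment benefit that dwindles, the 'early effect');
    - ``"late"``  — 1 before ``changepoint``, ``hr_late`` after (benefit that
      emerges only later).

    ``changepoint`` defaults to the control-arm median.  Censoring: an
    administrative horizon ``censor_horizon`` and/or staggered entry (entry
    uniform on ``(0, accrual)``, administrative censoring at
    ``duration - entry``, mimicking recruitment at a uniform rate).
    """

    family: str = "exponential"
    n_per_arm: int = 100
    effect: str = "null"
    rate: float | Sequence[float] = 1.0
    shape: float = 1.0
    cutpoints: Sequence[float] = field(default_factory=tuple)
    hr: float = 0.75
    hr_early: float = 0.5
    hr_late: float = 1.1
    changepoint: float | None = None
    censor_horizon: float | None = None
    accrual: float | None = None
    duration: float | None = None
    seed: int = 0

    _FAMILIES = ("exponential", "weibull", "piecewise-exponential")
    _EFFECTS = ("null", "ph", "early", "late")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.effect not in self._EFFECTS:
            raise ValueError(f"unknown effect tag {self.effect!r}")
        if self.n_per_arm < 2:
            raise ValueError("need n >= 2 per arm")
        rates = np.atleast_1d(np.asarray(self.rate, dtype=float))
        if (rates <= 0).any() or self.shape <= 0:
            raise ValueError("hazard parameters must be strictly positive")


def _control_cuthaz(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Control-arm hazard as (cut times, piecewise rates); Weibull handled separately."""
    if spec.family == "exponential":
        return np.array([0.0]), np.array([float(np.atleast_1d(spec.rate)[0])])
    if spec.family == "piecewise-exponential":
        rates = np.atleast_1d(np.asarray(spec.rate, dtype=float))
        cuts = np.concatenate([[0.0], np.asarray(spec.cutpoints, dtype=float)])
        if cuts.size != rates.size or (np.diff(cuts) <= 0).any():
            raise ValueError("cutpoints must be increasing and one shorter than the rate list")
        return cuts, rates
    raise AssertionError(spec.family)


def _pw_cumhaz_inverse(cuts: np.ndarray, rates: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Invert the cumulative hazard of a piecewise-exponential distribution."""
    seg = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(cuts))]) if cuts.size > 1 else np.array([0.0])
    i = np.clip(np.searchsorted(seg, h, side="right") - 1, 0, rates.size - 1)
    return cuts[i] + (h - seg[i]) / rates[i]


def _sample_arm(spec: FixtureSpec, multipliers: tuple[float, float], cp: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inversion sampling of event times with hazard = multiplier(t) * control hazard."""
    m1, m2 = multipliers
    u = rng.uniform(size=n)
    target = -np.log(u)
    if spec.family == "weibull":
        # H0(t) = (rate * t)^shape; fold the two-piece multiplier into H piecewise
        lam = float(np.atleast_1d(spec.rate)[0])
        k = spec.shape
        h0 = lambda t: (lam * t) ** k
        h0inv = lambda h: np.power(h, 1.0 / k) / lam
        h_cp = m1 * h0(cp)
        below = target <= h_cp
        out = np.empty(n)
        out[below] = h0inv(target[below] / m1)
        out[~below] = h0inv(h0(cp) + (target[~below] - h_cp) / m2)
        return out
    cuts, rates = _control_cuthaz(spec)
    # splice the changepoint into the grid, then scale rates by the multiplier
    grid = np.unique(np.concatenate([cuts, [cp]]))
    idx = np.clip(np.searchsorted(cuts, grid, side="right") - 1, 0, rates.size - 1)
    r = rates[idx] * np.where(grid < cp, m1, m2)
    return _pw_cumhaz_inverse(grid, r, target)


def _control_median(spec: FixtureSpec) -> float:
    ln2 = np.log(2.0)
    if spec.family == "weibull":
        lam = float(np.atleast_1d(spec.rate)[0])
        return float(ln2 ** (1.0 / spec.shape) / lam)
    cuts, rates = _control_cuthaz(spec)
    return float(_pw_cumhaz_inverse(cuts, rates, np.array([ln2]))[0])


_EFFECT_MULTIPLIERS = {
    "null": lambda s: (1.0, 1.0),
    "ph": lambda s: (s.hr, s.hr),
    "early": lambda s: (s.hr_early, s.hr_late),
    "late": lambda s: (1.0, s.hr_late),
}


def make_fixture(spec: FixtureSpec) -> SurvivalData:
    """Draw a reproducible two-arm dataset according to ``spec``.

    Event times come from the named family per arm; censoring is applied as
    ``min(event time, censoring time)`` with the indicator set accordingly.
    A fixed seed yields bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cp = spec.changepoint if spec.changepoint is not None else _control_median(spec)
    n = spec.n_per_arm
    t0 = _sample_arm(spec, (1.0, 1.0), cp, n, rng)
    t1 = _sample_arm(spec, _EFFECT_MULTIPLIERS[spec.effect](spec), cp, n, rng)
    time = np.concatenate([t0, t1])
    arm = np.repeat([0, 1], n)
    cens = np.full(2 * n, np.inf)
    if spec.accrual is not None:
        if spec.duration is None or spec.duration < spec.accrual:
            raise ValueError("staggered entry needs duration >= accrual")
        entry = rng.uniform(0.0, spec.accrual, size=2 * n)
        cens = spec.duration - entry
    if spec.censor_horizon is not None:
        cens = np.minimum(cens, spec.censor_horizon)
    event = (time <= cens).astype(int)
    time = np.minimum(time, cens)
    # guard against zero observed times from pathological censoring input
    time = np.maximum(time, np.finfo(float).tiny)
    return SurvivalData(time, event, arm)
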