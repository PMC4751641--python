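"""Simulation-study orchestration: type-1-error and power tables.

A study is a list of named scenarios, a replicate count, the nominal
significance levels of interest, and the tests to tabulate.  Each replicate
is generated by :func:`nphtest.rp_sim.scenario_generate` with a seed
derived deterministically from the master seed, so a study is exactly
reproducible and independent of execution order.  Replicates on which a
test's preconditions fail (e.g. a Cox fit with every event in one arm) are
counted and reported separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .survdata import SurvivalData, DataError
from .classical_tests import cox_fit, grambsch_therneau, joint_test, ConvergenceError
from .combined_test import run_combined_test
from . import rp_sim

__all__ = ["StudyConfig", "StudyResult", "run_study", "config_from_yaml"]

TESTS = ("cox", "joint", "perm", "combined")


@dataclass(frozen=True)
class StudyConfig:
    scenarios: Sequence[tuple[str, rp_sim.ScenarioSpec]]
    replicates: int = 2000
    alphas: Sequence[float] = (0.05,)
    tests: Sequence[str] = TESTS
    seed: int = 0
    n_t: int = 10
    variance_method: str = "asymptotic"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        unknown = set(self.tests) - set(TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")


@dataclass(frozen=True)
class StudyResult:
    """Empirical rejection percentages per scenario x test x alpha."""

    table: pd.DataFrame        # scenario, test, alpha, rejections, replicates, percent, se_percent
    failures: pd.DataFrame     # scenario, test, count of precondition failures
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _replicate_pvalues(data: SurvivalData, tests, n_t, variance_method):
    """P-value of each requested test on one dataset (NaN on failure)."""
    out = {}
    need_combined = {"perm", "combined"} & set(tests)
    try:
        if need_combined:
            res = run_combined_test(data, n_t=n_t, variance_method=variance_method)
            cox = res.cox
            out["perm"] = res.p_perm
            out["combined"] = res.p_comb
        else:
            cox = cox_fit(data)
        if "cox" in tests:
            out["cox"] = cox.p_cox
        if "joint" in tests:
            gt = grambsch_therneau(cox, data)
            out["joint"] = joint_test(cox, gt)[1]
    except (ConvergenceError, DataError):
        for t in tests:
            out.setdefault(t, np.nan)
    return out


def run_study(config: StudyConfig) -> StudyResult:
    """Run every scenario and tabulate empirical rejection fractions.

    Percentages come with the binomial standard error
    ``100 * sqrt(p (1-p) / replicates)``.
    """
    rows, fail_rows = [], []
    root = np.random.SeedSequence(config.seed)
    scen_seeds = root.spawn(len(config.scenarios))
    for (name, spec), ss in zip(config.scenarios, scen_seeds):
        seeds = ss.generate_state(config.replicates) % (2**31)
        pvals = {t: np.full(config.replicates, np.nan) for t in config.tests}
        for i in range(config.replicates):
            data = rp_sim.scenario_generate(replace(spec, seed=int(seeds[i])))
            res = _replicate_pvalues(data, config.tests, config.n_t, config.variance_method)
            for t in config.tests:
                pvals[t][i] = res.get(t, np.nan)
        for t in config.tests:
            p = pvals[t]
            ok = ~np.isnan(p)
            fail_rows.append({"scenario": name, "test": t, "failures": int((~ok).sum())})
            for alpha in config.alphas:
                nrej = int((p[ok] <= alpha).sum())
                nrep = int(ok.sum())
                frac = nrej / nrep if nrep else np.nan
                rows.append(
                    {
                        "scenario": name,
                        "test": t,
                        "alpha": alpha,
                        "rejections": nrej,
                        "replicates": nrep,
                        "percent": 100.0 * frac,
                        "se_percent": 100.0 * np.sqrt(frac * (1 - frac) / nrep) if nrep else np.nan,
                    }
                )
    return StudyResult(pd.DataFrame(rows), pd.DataFrame(fail_rows), config.seed)


# ---------------------------------------------------------------------------
# YAML study configuration


def _censoring_from_config(obj):
    if obj is None:
        return None
    kind = obj.get("kind")
    if kind == "point":
        return rp_sim.PointMassCensoring(float(obj["time"]))
    if kind == "uniform-accrual":
        return rp_sim.UniformAccrualCensoring(float(obj["accrual"]), float(obj["duration"]))
    if kind == "model":
        return rp_sim.RPModel.from_json(yaml.safe_dump(obj["model"]))
    raise ValueError(f"unknown censoring kind {kind!r}")


def config_from_yaml(path: str | Path) -> StudyConfig:
    """Load a study configuration from YAML.

    Top-level keys: ``replicates``, ``alphas``, ``tests``, ``seed``, ``n_t``,
    and ``scenarios`` — a list of mappings with ``name``, ``scenario``,
    ``n`` and optional ``rate`` (exponential control), ``ln_hr``, late-effect
    parameters and a ``censoring`` block.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scenarios = []
    for sc in raw["scenarios"]:
        control = rp_sim.default_control_model(float(sc.get("rate", 0.25)))
        kwargs = {
            k: sc[k] for k in ("allocation", "ln_hr", "theta", "t0", "tau") if k in sc
        }
        spec = rp_sim.ScenarioSpec(
            scenario=sc["scenario"],
            n=int(sc["n"]),
            control=control,
            censoring=_censoring_from_config(sc.get("censoring")),
            **kwargs,
        )
        scenarios.append((sc.get("name", sc["scenario"]), spec))
    return StudyConfig(
        scenarios=scenarios,
        replicates=int(raw.get("replicates", 2000)),
        alphas=tuple(raw.get("alphas", [0.05])),
        tests=tuple(raw.get("tests", TESTS)),
        seed=int(raw.get("seed", 0)),
        n_t=int(raw.get("n_t", 10)),
    )
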