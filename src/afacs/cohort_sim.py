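"""Monte Carlo cohort simulator — the stochastic oracle for the analytic model.

Simulates per-patient 30-day outcomes for two regimen arms at a given
CHA2DS2-VASc score and PCI complexity, with event probabilities taken
from the risk engine, so every analytic quantity (absolute risks, risk
differences, NNTBs) can be recovered empirically and checked for
convergence at a known 1/sqrt(n) rate.

Model: each patient experiences each endpoint as an independent
Bernoulli draw over the single 30-day horizon — there is no within-month
time structure and no competing-risk interaction between endpoints,
matching the additive way the analytic model treats endpoint families.
Per-arm event counts are drawn as binomial variates (exactly the
distribution of n independent per-patient draws) from one named,
seedable generator per simulation; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, UnknownRegimenError
from .nntb import NntbResult, nntb_between
from .regimens import Regimen, get_regimen
from .risk_engine import (
    AcsMultiplier,
    CoronaryRiskTable,
    PciComplexity,
    STANDARD_PCI,
    StrokeRiskTable,
    coronary_risk_30d,
    default_coronary_table,
    stroke_risk_30d,
)

ENDPOINTS = ("stroke", "coronary")


def arm_probability(
    endpoint: str,
    score: int,
    regimen: Regimen | str,
    complexity: PciComplexity = STANDARD_PCI,
    stroke_table: StrokeRiskTable | None = None,
    coronary_table: CoronaryRiskTable | None = None,
    mult: AcsMultiplier = AcsMultiplier(),
) -> float:
    """Per-patient 30-day event probability (per 100) for one arm.

    Stroke risks resolve for any registered regimen; coronary risks
    resolve for the three DAPT regimens (and DAT-clopidogrel, whose
    antiplatelet component matches the clopidogrel reference).
    """
    regimen = get_regimen(regimen)
    if endpoint == "stroke":
        table = stroke_table if stroke_table is not None else StrokeRiskTable.extended()
        return stroke_risk_30d(table, score, regimen, mult)
    if endpoint == "coronary":
        ctable = coronary_table if coronary_table is not None else default_coronary_table()
        name = regimen.name
        if name == "DAT-clopidogrel":
            name = "DAPT-clopidogrel"
        return coronary_risk_30d(ctable, score, name, complexity)
    raise DomainError(f"unknown endpoint {endpoint!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """One two-arm simulation scenario.

    ``probabilities`` optionally bypasses the risk engine with explicit
    per-arm, per-endpoint event probabilities (per 100) — useful for
    simulating hypothetical scenarios the analytic tables do not cover.
    """

    n_patients: int
    score: int
    arms: tuple[str, str]
    endpoints: tuple[str, ...] = ENDPOINTS
    complexity: PciComplexity = STANDARD_PCI
    seed: int = 0
    replicates: int = 1
    mult: AcsMultiplier = AcsMultiplier()
    probabilities: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DomainError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.replicates < 1:
            raise DomainError(f"replicates must be >= 1, got {self.replicates}")
        if len(self.arms) != 2:
            raise DomainError("exactly two arms are required")


@dataclass(frozen=True)
class ArmResult:
    regimen: str
    n: int
    counts: Mapping[str, int]            # events per endpoint
    probabilities: Mapping[str, float]   # model probabilities per 100

    def empirical_risk(self, endpoint: str) -> float:
        """Empirical risk per 100: exactly 100 * count / n."""
        return 100.0 * self.counts[endpoint] / self.n

    def binomial_se(self, endpoint: str) -> float:
        """Binomial standard error of the empirical risk, per 100."""
        p = self.counts[endpoint] / self.n
        return 100.0 * math.sqrt(p * (1.0 - p) / self.n)


@dataclass(frozen=True)
class CohortResult:
    """Simulated two-arm outcome with full provenance (seed, n, config)."""

    config: SimulationConfig
    arms: tuple[ArmResult, ArmResult]
    seed: int

    def empirical_arr(self, endpoint: str) -> float:
        """Empirical risk difference (arm 1 minus arm 0), per 100."""
        a, b = self.arms
        return b.empirical_risk(endpoint) - a.empirical_risk(endpoint)

    def arr_se(self, endpoint: str) -> float:
        a, b = self.arms
        return math.hypot(a.binomial_se(endpoint), b.binomial_se(endpoint))


def simulate_cohort(config: SimulationConfig) -> CohortResult:
    """Run one two-arm cohort simulation; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    arm_results = []
    for arm in config.arms:
        if config.probabilities is not None:
            probs = {e: float(config.probabilities[arm][e]) for e in config.endpoints}
        else:
            probs = {
                endpoint: arm_probability(
                    endpoint, config.score, arm, config.complexity, mult=config.mult
                )
                for endpoint in config.endpoints
            }
        counts = {
            endpoint: int(rng.binomial(config.n_patients, p / 100.0))
            for endpoint, p in probs.items()
        }
        arm_results.append(
            ArmResult(get_regimen(arm).name, config.n_patients, counts, probs)
        )
    return CohortResult(config, (arm_results[0], arm_results[1]), config.seed)


@dataclass(frozen=True)
class EmpiricalNntb:
    """Empirical NNTB with a delta-method standard error on the unrounded value."""

    result: NntbResult
    se_unrounded: float
    n_per_arm: int
    seed: int


def empirical_nntb(result: CohortResult, endpoint: str = "stroke") -> EmpiricalNntb:
    """NNTB from simulated counts: floor(100/|empirical ARR|) + delta-method SE.

    The delta method gives SE(100/ARR) = 100 * SE(ARR) / ARR^2. A zero
    empirical ARR yields the infinite sentinel (SE undefined -> inf).
    """
    if endpoint not in result.config.endpoints:
        raise DomainError(f"endpoint {endpoint!r} was not simulated")
    a, b = result.arms
    nn = nntb_between(
        a.empirical_risk(endpoint),
        b.empirical_risk(endpoint),
        regimen_a=a.regimen,
        regimen_b=b.regimen,
        endpoint=endpoint,
        score=result.config.score,
    )
    arr = result.empirical_arr(endpoint)
    se = math.inf if arr == 0 else 100.0 * result.arr_se(endpoint) / arr**2
    return EmpiricalNntb(nn, abs(se), result.config.n_patients, result.seed)


def convergence_sweep(
    config: SimulationConfig, sizes: Sequence[int], endpoint: str = "stroke"
) -> list[tuple[int, float]]:
    """Absolute error of the empirical ARR vs the analytic ARR across n.

    Returns (n, |empirical - analytic|) pairs; errors shrink ~ 1/sqrt(n).
    Seeds for the sweep are derived from the config seed.
    """
    analytic = arm_probability(
        endpoint, config.score, config.arms[1], config.complexity, mult=config.mult
    ) - arm_probability(
        endpoint, config.score, config.arms[0], config.complexity, mult=config.mult
    )
    out = []
    for i, n in enumerate(sizes):
        cfg = SimulationConfig(
            n_patients=int(n),
            score=config.score,
            arms=config.arms,
            endpoints=(endpoint,),
            complexity=config.complexity,
            seed=(config.seed + 1000003 * (i + 1)) % (2**31),
            mult=config.mult,
        )
        res = simulate_cohort(cfg)
        out.append((int(n), abs(res.empirical_arr(endpoint) - analytic)))
    return out
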