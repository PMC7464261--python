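"""Monte Carlo simulator: determinism, parameter recovery, convergence."""

import math

import numpy as np
import pytest

from afacs.cohort_sim import (
    SimulationConfig,
    arm_probability,
    convergence_sweep,
    empirical_nntb,
    simulate_cohort,
)
from afacs.errors import DomainError
from afacs.risk_engine import COMPLEX_PCI


def three_se_interval(p_per_100, n):
    se = 100.0 * math.sqrt((p_per_100 / 100) * (1 - p_per_100 / 100) / n)
    return 3.0 * se


class TestDeterminism:
    def test_same_seed_identical_results(self):
        cfg = SimulationConfig(n_patients=50_000, score=3, endpoints=("stroke",),
                               arms=("OAC", "DAPT-clopidogrel"), seed=42)
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_different_seeds_differ(self):
        base = dict(n_patients=50_000, score=3, endpoints=("stroke",),
                    arms=("OAC", "DAPT-clopidogrel"))
        a = simulate_cohort(SimulationConfig(seed=1, **base))
        b = simulate_cohort(SimulationConfig(seed=2, **base))
        assert a.arms[0].counts != b.arms[0].counts

    def test_seed_recorded_in_output(self):
        cfg = SimulationConfig(n_patients=10, score=2, endpoints=("stroke",),
                               arms=("OAC", "DAPT-clopidogrel"), seed=7)
        assert simulate_cohort(cfg).seed == 7


class TestParameterRecovery:
    @pytest.mark.parametrize("score", [2, 3])
    @pytest.mark.parametrize("endpoint, arms", [
        ("stroke", ("OAC", "DAPT-clopidogrel")),
        ("coronary", ("DAPT-ticagrelor", "DAPT-clopidogrel")),
    ])
    def test_empirical_risks_within_three_se_at_1e6(self, score, endpoint, arms):
        cfg = SimulationConfig(
            n_patients=1_000_000, score=score, arms=arms,
            endpoints=(endpoint,), seed=20_000 + score,
        )
        res = simulate_cohort(cfg)
        for arm in res.arms:
            analytic = arm.probabilities[endpoint]
            tol = three_se_interval(analytic, cfg.n_patients)
            assert abs(arm.empirical_risk(endpoint) - analytic) <= tol

    def test_empirical_arr_within_three_se_score3(self):
        # analytic DAPT-vs-OAC stroke risk difference at score 3: 0.497/100
        cfg = SimulationConfig(
            n_patients=1_000_000, score=3, arms=("OAC", "DAPT-clopidogrel"),
            endpoints=("stroke",), seed=11,
        )
        res = simulate_cohort(cfg)
        analytic = 1.18732 - 0.69030
        assert abs(res.empirical_arr("stroke") - analytic) <= 3 * res.arr_se("stroke")

    def test_zero_probability_never_fires(self):
        cfg = SimulationConfig(
            n_patients=100_000, score=0, arms=("A", "B"), endpoints=("stroke",),
            seed=5, probabilities={"A": {"stroke": 0.0}, "B": {"stroke": 50.0}},
        )
        res = simulate_cohort(cfg)
        assert res.arms[0].counts["stroke"] == 0
        assert res.arms[1].counts["stroke"] > 0

    def test_complex_pci_raises_coronary_counts(self):
        base = dict(n_patients=500_000, score=3,
                    arms=("DAPT-ticagrelor", "DAPT-clopidogrel"),
                    endpoints=("coronary",), seed=99)
        std = simulate_cohort(SimulationConfig(**base))
        cplx = simulate_cohort(SimulationConfig(complexity=COMPLEX_PCI, **base))
        for a_std, a_cplx in zip(std.arms, cplx.arms):
            assert a_cplx.counts["coronary"] > a_std.counts["coronary"]


class TestEmpiricalNntb:
    def test_score2_stroke_nntb_brackets_analytic(self):
        cfg = SimulationConfig(
            n_patients=10_000_000, score=2, arms=("OAC", "DAPT-clopidogrel"),
            endpoints=("stroke",), seed=2024,
        )
        emp = empirical_nntb(simulate_cohort(cfg), "stroke")
        assert 300 <= emp.result.nntb <= 345  # analytic 320.8 +- sampling

    def test_extreme_arms_give_nntb_one(self):
        from afacs.cohort_sim import ArmResult, CohortResult

        cfg = SimulationConfig(n_patients=100, score=2,
                               arms=("OAC", "DAPT-clopidogrel"), seed=0)
        res = CohortResult(
            cfg,
            (
                ArmResult("OAC", 100, {"stroke": 0}, {"stroke": 0.0}),
                ArmResult("DAPT-clopidogrel", 100, {"stroke": 100}, {"stroke": 100.0}),
            ),
            seed=0,
        )
        assert empirical_nntb(res, "stroke").result.nntb == 1

    def test_zero_arr_gives_infinite_sentinel(self):
        from afacs.cohort_sim import ArmResult, CohortResult

        cfg = SimulationConfig(n_patients=100, score=2,
                               arms=("OAC", "DAPT-clopidogrel"), seed=0)
        res = CohortResult(
            cfg,
            (
                ArmResult("OAC", 100, {"stroke": 5}, {"stroke": 5.0}),
                ArmResult("DAPT-clopidogrel", 100, {"stroke": 5}, {"stroke": 5.0}),
            ),
            seed=0,
        )
        emp = empirical_nntb(res, "stroke")
        assert emp.result.infinite and math.isinf(emp.se_unrounded)

    def test_unsimulated_endpoint_rejected(self):
        cfg = SimulationConfig(n_patients=100, score=2,
                               arms=("OAC", "DAPT-clopidogrel"),
                               endpoints=("stroke",), seed=0)
        with pytest.raises(DomainError):
            empirical_nntb(simulate_cohort(cfg), "coronary")


class TestConvergence:
    def test_arr_error_shrinks_with_n(self):
        # averaged over a few seeds the error at n=1e6 must be well below
        # the error at n=1e4 (theoretical ratio 1/10)
        errs_small, errs_big = [], []
        for offset in range(5):
            sweep = dict(convergence_sweep(
                SimulationConfig(n_patients=1, score=3,
                                 arms=("OAC", "DAPT-clopidogrel"),
                                 seed=314 + offset),
                sizes=[10_000, 1_000_000],
            ))
            errs_small.append(sweep[10_000])
            errs_big.append(sweep[1_000_000])
        assert np.mean(errs_big) < np.mean(errs_small) / 3

    def test_probabilities_match_risk_engine(self, scenario):
        assert arm_probability("stroke", 3, "OAC",
                               stroke_table=scenario.stroke_table_extended
                               ) == pytest.approx(0.69030, abs=5e-6)
        assert arm_probability("coronary", 3, "DAPT-clopidogrel",
                               coronary_table=scenario.coronary_table
                               ) == pytest.approx(5.952, abs=5e-3)
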