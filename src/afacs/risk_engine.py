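"""Absolute 30-day event risks for AF patients early after an ACS.

The engine composes three ingredients on the probability scale:

1. a **baseline rate table** per endpoint, indexed by the CHA2DS2-VASc
   score (annual stroke/systemic-embolism rates per 100 patient-years;
   30-day coronary event rates per 100 patients under clopidogrel DAPT);
2. an **early post-ACS multiplier** for the cardioembolic endpoint
   (default 3.9), reflecting the excess stroke hazard in the first weeks
   after the coronary event;
3. a chain of **multiplicative relative effects** (relative risk
   reductions or risk ratios) turning the untreated risk into the risk
   under a given regimen.

All risks are expressed per 100 patients. Annual rates convert to monthly
risks by plain division by 12 and "one month" and "30 days" denote the
same horizon; in the small-probability regime of this model the
distinction between hazard ratios and risk ratios is ignored. These are
deliberate modelling conventions, documented in the methods note.

The 30-day coronary rate table under the clopidogrel-DAPT reference is
not observable directly; :func:`calibrate_coronary_table` recovers it by
inverting published numbers-needed-to-treat for the modern P2Y12
inhibitors versus clopidogrel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import (
    CalibrationError,
    ChainMismatchError,
    DomainError,
    MissingScoreError,
    UnknownRegimenError,
)
from .regimens import (
    DAPT_CLOPIDOGREL,
    DAPT_PRASUGREL,
    DAPT_TICAGRELOR,
    Regimen,
    get_regimen,
)

logger = logging.getLogger(__name__)

SCORE_MIN, SCORE_MAX = 0, 9

Endpoint = Literal["stroke", "coronary", "bleeding"]
Measure = Literal["relative_risk_reduction", "risk_ratio"]


def validate_score(score: int) -> int:
    """Validate a CHA2DS2-VASc score (integer in 0..9)."""
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise DomainError(f"CHA2DS2-VASc score must be an integer, got {score!r}")
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise DomainError(f"CHA2DS2-VASc score must be in [0, 9], got {score}")
    return int(score)


def _check_rate_table(rates: Mapping[int, float], name: str) -> dict[int, float]:
    out: dict[int, float] = {}
    for score, rate in sorted(rates.items()):
        validate_score(score)
        if rate <= 0:
            raise DomainError(f"{name}: rate at score {score} must be > 0, got {rate}")
        out[int(score)] = float(rate)
    scores = sorted(out)
    for lo, hi in zip(scores, scores[1:]):
        if out[hi] < out[lo]:
            raise DomainError(
                f"{name}: rates must be non-decreasing in score "
                f"({out[lo]} at {lo} > {out[hi]} at {hi})"
            )
    return out


@dataclass(frozen=True)
class StrokeRiskTable:
    """Annual stroke/systemic-embolism rates per 100 patient-years by score.

    The default covers scores 2 and 3 only, the two values with direct
    support (3.7 and 5.9 per 100 patient-years in non-anticoagulated AF
    patients). :meth:`extended` adds the remaining scores from a large
    Danish nationwide AF cohort (Olesen et al., BMJ 2011) — an extension
    the trade-off analysis across the full score range requires; its
    score-4 value of 9.27 is consistent with the third reported monthly
    risk of 0.8/100 (9.27/12 = 0.77).
    """

    annual_rate_per_100: Mapping[int, float] = field(
        default_factory=lambda: {2: 3.7, 3: 5.9}
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "annual_rate_per_100",
            _check_rate_table(self.annual_rate_per_100, "stroke table"),
        )

    def annual_rate(self, score: int) -> float:
        validate_score(score)
        try:
            return self.annual_rate_per_100[score]
        except KeyError:
            raise MissingScoreError(score, "stroke table") from None

    @property
    def scores(self) -> list[int]:
        return sorted(self.annual_rate_per_100)

    @classmethod
    def extended(cls) -> "StrokeRiskTable":
        """Full 0..9 table: default entries plus the Danish-cohort extension."""
        return cls(
            {
                0: 0.78,
                1: 2.01,
                2: 3.7,
                3: 5.9,
                4: 9.27,
                5: 15.26,
                6: 19.74,
                7: 21.50,
                8: 22.38,
                9: 23.64,
            }
        )


@dataclass(frozen=True)
class AcsMultiplier:
    """Multiplier on the monthly cardioembolic risk early after an ACS."""

    factor: float = 3.9

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise DomainError(f"ACS multiplier must be >= 1, got {self.factor}")


@dataclass(frozen=True)
class TreatmentEffect:
    """A relative effect of ``regimen`` versus ``comparator`` on one endpoint.

    ``relative_risk_reduction`` v multiplies the comparator risk by (1 - v);
    ``risk_ratio`` v multiplies it by v.
    """

    endpoint: Endpoint
    regimen: Regimen
    comparator: Regimen
    measure: Measure
    value: float

    def __post_init__(self) -> None:
        if self.measure == "relative_risk_reduction":
            if self.value >= 1:
                raise DomainError(
                    f"relative risk reduction must be < 1, got {self.value}"
                )
        elif self.measure == "risk_ratio":
            if self.value <= 0:
                raise DomainError(f"risk ratio must be > 0, got {self.value}")
        else:
            raise DomainError(f"unknown effect measure {self.measure!r}")

    @property
    def multiplier(self) -> float:
        """Factor applied to the comparator's absolute risk."""
        if self.measure == "relative_risk_reduction":
            return 1.0 - self.value
        return self.value


@dataclass(frozen=True)
class PciComplexity:
    """Procedural complexity: 'complex' means >= 3 high-risk features
    (long, bifurcated, eccentric, thrombotic, tortuous, angulated or
    calcified lesions, left main, multivessel PCI)."""

    flag: Literal["standard", "complex"] = "standard"

    def __post_init__(self) -> None:
        if self.flag not in ("standard", "complex"):
            raise DomainError(f"PCI complexity must be standard|complex, got {self.flag!r}")

    @property
    def is_complex(self) -> bool:
        return self.flag == "complex"


STANDARD_PCI = PciComplexity("standard")
COMPLEX_PCI = PciComplexity("complex")

#: Risk ratio for early stent thrombosis with >= 3 vs one high-risk
#: procedural feature, applied to the 30-day coronary probability.
COMPLEX_PCI_RISK_RATIO = 3.4

#: Default effect sizes (see methods note for provenance and units).
OAC_STROKE_RRR = 0.64            # full anticoagulation vs no anticoagulation
DAPT_VS_OAC_STROKE_RR = 1.72     # aspirin+clopidogrel DAPT vs full OAC
CORONARY_RRR = {                 # modern P2Y12 DAPT vs clopidogrel DAPT, first month
    "ticagrelor": 0.12,
    "prasugrel": 0.22,
}


def oac_effect() -> TreatmentEffect:
    from .regimens import OAC, UNTREATED

    return TreatmentEffect("stroke", OAC, UNTREATED, "relative_risk_reduction", OAC_STROKE_RRR)


def dapt_vs_oac_effect() -> TreatmentEffect:
    from .regimens import OAC

    return TreatmentEffect("stroke", DAPT_CLOPIDOGREL, OAC, "risk_ratio", DAPT_VS_OAC_STROKE_RR)


def monthly_stroke_risk(table: StrokeRiskTable, score: int) -> float:
    """Monthly stroke/systemic-embolism risk per 100 patients: annual rate / 12."""
    return table.annual_rate(score) / 12.0


def acs_adjusted_risk(base: float, mult: AcsMultiplier | float = AcsMultiplier()) -> float:
    """Scale a monthly risk by the early post-ACS multiplier, capped at 100/100."""
    if base < 0:
        raise DomainError(f"risk must be >= 0, got {base}")
    factor = mult.factor if isinstance(mult, AcsMultiplier) else AcsMultiplier(mult).factor
    out = base * factor
    if out > 100.0:
        logger.warning(
            "ACS-adjusted risk %.4g/100 exceeds certainty; capped at 100/100", out
        )
        return 100.0
    return out


def risk_under_regimen(
    untreated: float,
    effect_chain: Sequence[TreatmentEffect],
    reference: Regimen | str | None = None,
) -> float:
    """Apply an ordered chain of relative effects to an untreated risk.

    Each effect's comparator must equal the regimen produced by the
    preceding element (the first comparator must equal ``reference`` when
    one is given). Composition is multiplicative on the probability
    scale, capped at 100/100.
    """
    if untreated < 0 or untreated > 100:
        raise DomainError(f"risk must be in [0, 100] per 100, got {untreated}")
    expected = get_regimen(reference) if reference is not None else None
    risk = float(untreated)
    for effect in effect_chain:
        if expected is not None and effect.comparator != expected:
            raise ChainMismatchError(expected.name, effect.comparator.name)
        risk *= effect.multiplier
        expected = effect.regimen
    if risk > 100.0:
        logger.warning("composed risk %.4g/100 exceeds certainty; capped at 100/100", risk)
        return 100.0
    return risk


@dataclass(frozen=True)
class CoronaryRiskTable:
    """30-day coronary event risk per 100 patients under clopidogrel DAPT.

    Calibrated, not observed: see :func:`calibrate_coronary_table`.
    """

    rate_30d_per_100: Mapping[int, float]
    anchors: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "rate_30d_per_100",
            _check_rate_table(self.rate_30d_per_100, "coronary table"),
        )

    def reference_rate(self, score: int) -> float:
        validate_score(score)
        try:
            return self.rate_30d_per_100[score]
        except KeyError:
            raise MissingScoreError(score, "coronary table") from None

    @property
    def scores(self) -> list[int]:
        return sorted(self.rate_30d_per_100)


def _p2y12_of(regimen: Regimen | str) -> str:
    regimen = get_regimen(regimen)
    if regimen == DAPT_CLOPIDOGREL:
        return "clopidogrel"
    if regimen == DAPT_TICAGRELOR:
        return "ticagrelor"
    if regimen == DAPT_PRASUGREL:
        return "prasugrel"
    raise UnknownRegimenError(regimen.name)


def coronary_risk_30d(
    table: CoronaryRiskTable,
    score: int,
    regimen: Regimen | str = DAPT_CLOPIDOGREL,
    complexity: PciComplexity = STANDARD_PCI,
) -> float:
    """30-day coronary risk per 100 for a DAPT regimen and PCI complexity.

    The clopidogrel reference rate is multiplied by (1 - RRR) for
    ticagrelor (0.12) or prasugrel (0.22), and by the complex-PCI risk
    ratio (3.4) for procedures with >= 3 high-risk features.
    """
    p2y12 = _p2y12_of(regimen)
    risk = table.reference_rate(score)
    if p2y12 != "clopidogrel":
        risk *= 1.0 - CORONARY_RRR[p2y12]
    if complexity.is_complex:
        risk *= COMPLEX_PCI_RISK_RATIO
    if risk > 100.0:
        logger.warning("coronary risk %.4g/100 capped at 100/100", risk)
        return 100.0
    return risk


def calibrate_coronary_table(
    nntb_anchors: Iterable[tuple[int, str, float]],
    fill_scores: Iterable[int] | None = None,
) -> CoronaryRiskTable:
    """Recover the clopidogrel-reference coronary rate table from NNTB anchors.

    Each anchor ``(score, p2y12, nntb)`` states the published 30-day
    number needed to treat of switching clopidogrel for that P2Y12
    inhibitor at that score. Since NNTB = 1 / (r * RRR) with r the
    per-patient reference risk, the reference rate per 100 patients is
    ``r = 100 / (nntb * RRR)``. Interior scores are filled by linear
    interpolation in score between anchors; the result must be monotone
    non-decreasing.

    Parameters
    ----------
    nntb_anchors
        At least two anchors at distinct scores.
    fill_scores
        Scores to tabulate (default: every integer between the lowest
        and highest anchor score).
    """
    anchors = sorted(
        (validate_score(s), str(p), float(n)) for s, p, n in nntb_anchors
    )
    if len({s for s, _, _ in anchors}) < 2:
        raise CalibrationError("need anchors at >= 2 distinct scores")
    by_score: dict[int, list[float]] = {}
    for score, p2y12, nntb in anchors:
        if p2y12 not in CORONARY_RRR:
            raise UnknownRegimenError(p2y12)
        if nntb <= 0:
            raise CalibrationError(f"NNTB anchors must be > 0, got {nntb}")
        rate = 100.0 / (nntb * CORONARY_RRR[p2y12])
        by_score.setdefault(score, []).append(rate)
    xs = sorted(by_score)
    ys = [float(np.mean(by_score[s])) for s in xs]
    for lo, hi in zip(ys, ys[1:]):
        if hi < lo:
            raise CalibrationError(
                f"anchors imply a non-monotone reference rate: {lo:.4g} then {hi:.4g}"
            )
    if fill_scores is None:
        fill_scores = range(xs[0], xs[-1] + 1)
    scores = sorted(validate_score(s) for s in fill_scores)
    rates = np.interp(scores, xs, ys)
    return CoronaryRiskTable(
        dict(zip(scores, rates.tolist())), anchors=tuple(anchors)
    )


#: Published 30-day NNTB anchors for modern DAPT vs clopidogrel DAPT.
#: Scores 1 and 9 bracket the range; the score-3 values pin the interior.
DEFAULT_CORONARY_ANCHORS: tuple[tuple[int, str, float], ...] = (
    (1, "ticagrelor", 179.0),
    (3, "ticagrelor", 140.0),
    (9, "ticagrelor", 105.0),
)

#: Prasugrel-derived anchors, used as an independent calibration cross-check.
PRASUGREL_CORONARY_ANCHORS: tuple[tuple[int, str, float], ...] = (
    (1, "prasugrel", 97.0),
    (9, "prasugrel", 57.0),
)


def default_coronary_table() -> CoronaryRiskTable:
    """Bundled coronary table calibrated from the ticagrelor NNTB anchors."""
    return calibrate_coronary_table(DEFAULT_CORONARY_ANCHORS)


def untreated_monthly_stroke_risk(
    table: StrokeRiskTable,
    score: int,
    mult: AcsMultiplier = AcsMultiplier(),
) -> float:
    """Monthly post-ACS stroke risk per 100 with no antithrombotic therapy."""
    return acs_adjusted_risk(monthly_stroke_risk(table, score), mult)


def stroke_risk_30d(
    table: StrokeRiskTable,
    score: int,
    regimen: Regimen | str,
    mult: AcsMultiplier = AcsMultiplier(),
) -> float:
    """30-day post-ACS stroke risk per 100 under a named regimen.

    Regimens containing an anticoagulant (OAC, any TAT or DAT) get the
    full-anticoagulation effect; DAPT regimens get the DAPT-vs-OAC excess
    on top of it. UNTREATED returns the unmodified post-ACS risk.
    """
    regimen = get_regimen(regimen)
    untreated = untreated_monthly_stroke_risk(table, score, mult)
    if regimen.name == "UNTREATED":
        return untreated
    chain = [oac_effect()]
    if regimen.name.startswith("DAPT"):
        chain.append(dapt_vs_oac_effect())
    risk = untreated
    for eff in chain:
        risk *= eff.multiplier
    return min(risk, 100.0)
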