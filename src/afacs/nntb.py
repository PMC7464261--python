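"""Numbers needed to treat and the stroke-vs-coronary trade-off curves.

The number needed to treat for benefit (NNTB) between two arms with
absolute risks r_a and r_b (per 100 patients) is 100 / |r_b - r_a|,
floored to an integer; the favored regimen is the lower-risk arm. The
floor convention is the one consistent with the unrounded values this
model produces (320.83 -> 320, 201.17 -> 201); unrounded values are
always carried alongside.

The trade-off analysis tabulates, per CHA2DS2-VASc score:

* the **stroke NNTB** of adding an OAC to aspirin+clopidogrel DAPT
  (i.e. DAT/TAT vs DAPT) during the first month after an ACS, and
* the **coronary NNTB** of using modern DAPT (ticagrelor or prasugrel)
  instead of the clopidogrel-based regimen over the same month,

and locates the *equipoise score*: the smallest score at which the
stroke NNTB drops to or below the coronary NNTB, i.e. where
anticoagulation's embolic protection becomes at least as cheap as the
coronary protection forgone by giving up a modern P2Y12 inhibitor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .errors import DomainError, InsufficientRangeError
from .regimens import (
    DAPT_CLOPIDOGREL,
    DAPT_PRASUGREL,
    DAPT_TICAGRELOR,
    OAC,
    Regimen,
    get_regimen,
)
from .risk_engine import (
    AcsMultiplier,
    CoronaryRiskTable,
    PciComplexity,
    STANDARD_PCI,
    StrokeRiskTable,
    coronary_risk_30d,
    dapt_vs_oac_effect,
    default_coronary_table,
    monthly_stroke_risk,
    oac_effect,
    risk_under_regimen,
    untreated_monthly_stroke_risk,
    validate_score,
)

HORIZON_DAYS = 30

#: Sentinel score meaning "the curves never cross on the tabulated range".
NO_CROSSING: int | None = None


@dataclass(frozen=True)
class NntbResult:
    """NNTB between two arms at a fixed 30-day horizon.

    ``nntb`` is ``floor(100 / |arr_per_100|)``; infinite (equal risks) is
    flagged rather than raised, with ``nntb = None``.
    """

    endpoint: str
    regimen_favored: Regimen | None
    regimen_other: Regimen | None
    score: int | None
    arr_per_100: float
    unrounded_nntb: float
    nntb: int | None
    horizon_days: int = HORIZON_DAYS

    @property
    def infinite(self) -> bool:
        return math.isinf(self.unrounded_nntb)


def nntb_between(
    risk_a: float,
    risk_b: float,
    *,
    regimen_a: Regimen | str | None = None,
    regimen_b: Regimen | str | None = None,
    endpoint: str = "",
    score: int | None = None,
) -> NntbResult:
    """NNTB between arm A and arm B (risks per 100 over 30 days).

    arr = risk_b - risk_a; the favored regimen is the lower-risk arm.
    Equal risks yield the infinite sentinel, never a division crash.
    """
    for r in (risk_a, risk_b):
        if not 0 <= r <= 100:
            raise DomainError(f"risk must be in [0, 100] per 100, got {r}")
    ra = get_regimen(regimen_a) if regimen_a is not None else None
    rb = get_regimen(regimen_b) if regimen_b is not None else None
    arr = risk_b - risk_a
    if arr == 0:
        return NntbResult(endpoint, None, None, score, 0.0, math.inf, None)
    unrounded = 100.0 / abs(arr)
    if math.isinf(unrounded):  # ARR below float resolution: treat as zero
        return NntbResult(endpoint, None, None, score, arr, math.inf, None)
    favored, other = (ra, rb) if arr > 0 else (rb, ra)
    # floor after rounding at the 9th decimal: absorbs float round-off so
    # an exactly-recoverable integer NNTB (e.g. from calibration
    # inversion) never floors to n-1
    return NntbResult(
        endpoint, favored, other, score, arr, unrounded, math.floor(round(unrounded, 9))
    )


def stroke_nntb_oac_vs_dapt(
    score: int,
    table: StrokeRiskTable | None = None,
    mult: AcsMultiplier = AcsMultiplier(),
) -> NntbResult:
    """30-day NNTB of adding OAC versus aspirin+clopidogrel DAPT alone.

    Pipeline: annual rate -> /12 -> x ACS multiplier -> OAC arm
    (x 0.36) and DAPT arm (OAC x 1.72), then the risk difference.
    """
    table = table if table is not None else StrokeRiskTable()
    untreated = untreated_monthly_stroke_risk(table, score, mult)
    oac_risk = risk_under_regimen(untreated, [oac_effect()], reference="UNTREATED")
    dapt_risk = risk_under_regimen(
        untreated, [oac_effect(), dapt_vs_oac_effect()], reference="UNTREATED"
    )
    return nntb_between(
        oac_risk,
        dapt_risk,
        regimen_a=OAC,
        regimen_b=DAPT_CLOPIDOGREL,
        endpoint="stroke",
        score=score,
    )


_P2Y12_REGIMEN = {"ticagrelor": DAPT_TICAGRELOR, "prasugrel": DAPT_PRASUGREL}


def coronary_nntb_modern_dapt(
    score: int,
    p2y12: Literal["ticagrelor", "prasugrel"],
    complexity: PciComplexity = STANDARD_PCI,
    table: CoronaryRiskTable | None = None,
) -> NntbResult:
    """30-day NNTB of modern DAPT versus the clopidogrel-based regimen."""
    if p2y12 not in _P2Y12_REGIMEN:
        raise DomainError(f"p2y12 must be ticagrelor|prasugrel, got {p2y12!r}")
    table = table if table is not None else default_coronary_table()
    modern = _P2Y12_REGIMEN[p2y12]
    risk_modern = coronary_risk_30d(table, score, modern, complexity)
    risk_clop = coronary_risk_30d(table, score, DAPT_CLOPIDOGREL, complexity)
    return nntb_between(
        risk_modern,
        risk_clop,
        regimen_a=modern,
        regimen_b=DAPT_CLOPIDOGREL,
        endpoint="coronary",
        score=score,
    )


def complex_pci_nntb_reduction(risk_ratio: float = 3.4) -> float:
    """Percent reduction in coronary NNTBs under complex PCI.

    A risk ratio k on the baseline risk scales every absolute risk
    difference by k, hence divides the NNTB by k: the reduction is
    (1 - 1/k) x 100. For k = 3.4 this is 70.6%.
    """
    if risk_ratio <= 1:
        raise DomainError(f"risk ratio must be > 1, got {risk_ratio}")
    return (1.0 - 1.0 / risk_ratio) * 100.0


@dataclass(frozen=True)
class TradeoffPoint:
    score: int
    stroke_nntb: NntbResult
    coronary_nntb_ticagrelor: NntbResult
    coronary_nntb_prasugrel: NntbResult


@dataclass(frozen=True)
class TradeoffCurve:
    """Per-score stroke and coronary NNTBs at one PCI complexity level."""

    points: tuple[TradeoffPoint, ...]
    complexity: PciComplexity = STANDARD_PCI

    @property
    def scores(self) -> list[int]:
        return [p.score for p in self.points]

    def point(self, score: int) -> TradeoffPoint:
        for p in self.points:
            if p.score == score:
                return p
        raise KeyError(score)


def build_tradeoff_curve(
    scores: Sequence[int] | None = None,
    stroke_table: StrokeRiskTable | None = None,
    coronary_table: CoronaryRiskTable | None = None,
    complexity: PciComplexity = STANDARD_PCI,
    mult: AcsMultiplier = AcsMultiplier(),
) -> TradeoffCurve:
    """Tabulate the stroke-vs-coronary NNTB trade-off across scores.

    Defaults to the intersection of the extended stroke table and the
    calibrated coronary table (scores 1..9).
    """
    stroke_table = stroke_table if stroke_table is not None else StrokeRiskTable.extended()
    coronary_table = coronary_table if coronary_table is not None else default_coronary_table()
    if scores is None:
        scores = sorted(set(stroke_table.scores) & set(coronary_table.scores))
    points = []
    for score in scores:
        validate_score(score)
        points.append(
            TradeoffPoint(
                score=score,
                stroke_nntb=stroke_nntb_oac_vs_dapt(score, stroke_table, mult),
                coronary_nntb_ticagrelor=coronary_nntb_modern_dapt(
                    score, "ticagrelor", complexity, coronary_table
                ),
                coronary_nntb_prasugrel=coronary_nntb_modern_dapt(
                    score, "prasugrel", complexity, coronary_table
                ),
            )
        )
    return TradeoffCurve(tuple(points), complexity)


def equipoise_score(
    curve: TradeoffCurve, p2y12: Literal["ticagrelor", "prasugrel"]
) -> int | None:
    """Smallest score at which the stroke NNTB <= the coronary NNTB.

    Below this score the coronary cost of forgoing modern DAPT is the
    cheaper event to prevent (DAPT favored); from this score upward the
    stroke benefit of anticoagulation is at least as cheap. Decided on
    unrounded NNTBs; returns ``None`` (:data:`NO_CROSSING`) when the
    curves never cross on the tabulated range.
    """
    if len(curve.points) < 2:
        raise InsufficientRangeError(
            f"need >= 2 scores to locate equipoise, got {len(curve.points)}"
        )
    attr = f"coronary_nntb_{p2y12}"
    for p in curve.points:
        coronary: NntbResult = getattr(p, attr)
        if p.stroke_nntb.unrounded_nntb <= coronary.unrounded_nntb:
            return p.score
    return NO_CROSSING
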