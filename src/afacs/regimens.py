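"""Antithrombotic regimen identities.

A :class:`Regimen` is a named drug combination used as a node identity
throughout the package: in treatment-effect chains, in the coronary risk
engine, and in the bleeding hazard-ratio network. Equality is by name, so
regimens loaded from config interoperate with the built-in registry.

Naming convention (used by the bundled data files):

* ``TAT-<oac>`` — triple therapy: OAC + aspirin + P2Y12 inhibitor
* ``DAT-<oac>-<dose>`` — dual therapy: OAC + single P2Y12 inhibitor
* ``DAPT-<p2y12>`` — aspirin + P2Y12 inhibitor, no anticoagulant
* ``OAC`` / ``UNTREATED`` — full anticoagulation alone / no therapy
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Regimen:
    """A named antithrombotic strategy.

    Parameters
    ----------
    name
        Unique label within a scenario (e.g. ``"DAPT-ticagrelor"``).
    components
        Non-empty set of drug labels, dose qualifiers allowed
        (e.g. ``{"aspirin", "ticagrelor"}``).
    qualitative_only
        True for regimens that participate in qualitative, directional
        arguments but carry no composable numeric effect (e.g. the
        edoxaban-based DAT node of the bleeding network).
    """

    name: str
    components: frozenset[str] = field(default_factory=frozenset)
    qualitative_only: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("regimen name must be non-empty")
        if not self.components:
            raise ValueError(f"regimen {self.name!r} must list at least one component")

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Regimen):
            return self.name == other.name
        if isinstance(other, str):
            return self.name == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.name)

    def __str__(self) -> str:
        return self.name


def _r(name: str, *components: str, qualitative: bool = False) -> Regimen:
    return Regimen(name, frozenset(components), qualitative_only=qualitative)


#: Regimens referenced by the bundled defaults.
UNTREATED = _r("UNTREATED", "none")
OAC = _r("OAC", "oral anticoagulant")
DAPT_CLOPIDOGREL = _r("DAPT-clopidogrel", "aspirin", "clopidogrel")
DAPT_TICAGRELOR = _r("DAPT-ticagrelor", "aspirin", "ticagrelor")
DAPT_PRASUGREL = _r("DAPT-prasugrel", "aspirin", "prasugrel")
TAT_WARFARIN = _r("TAT-warfarin", "warfarin", "aspirin", "P2Y12 inhibitor")
DAT_DABIGATRAN_110 = _r("DAT-dabigatran-110", "dabigatran 110 bid", "P2Y12 inhibitor")
DAT_DABIGATRAN_150 = _r("DAT-dabigatran-150", "dabigatran 150 bid", "P2Y12 inhibitor")
DAT_RIVAROXABAN_15 = _r("DAT-rivaroxaban-15", "rivaroxaban 15 od", "P2Y12 inhibitor")
DAT_APIXABAN_5 = _r("DAT-apixaban-5-bid", "apixaban 5 bid", "P2Y12 inhibitor")
DAT_EDOXABAN_60 = _r(
    "DAT-edoxaban-60", "edoxaban 60 od", "P2Y12 inhibitor", qualitative=True
)
DAT_CLOPIDOGREL = _r("DAT-clopidogrel", "oral anticoagulant", "clopidogrel")

REGISTRY: dict[str, Regimen] = {
    r.name: r
    for r in (
        UNTREATED,
        OAC,
        DAPT_CLOPIDOGREL,
        DAPT_TICAGRELOR,
        DAPT_PRASUGREL,
        TAT_WARFARIN,
        DAT_DABIGATRAN_110,
        DAT_DABIGATRAN_150,
        DAT_RIVAROXABAN_15,
        DAT_APIXABAN_5,
        DAT_EDOXABAN_60,
        DAT_CLOPIDOGREL,
    )
}


def get_regimen(name: str | Regimen) -> Regimen:
    """Resolve a regimen by name, creating an ad-hoc node for unknown names.

    Unknown names are allowed in the bleeding network (any node label is a
    valid comparison arm); modules that require a *registered* regimen
    (e.g. the coronary risk engine) perform their own membership checks.
    """
    if isinstance(name, Regimen):
        return name
    return REGISTRY.get(name, Regimen(name, frozenset({name})))
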