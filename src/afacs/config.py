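"""Scenario configuration: plain-text (YAML) model inputs, fail-fast validated.

A :class:`Scenario` bundles every model input — the stroke rate table and
its extension, the treatment-effect constants, the coronary NNTB
calibration anchors, and the bleeding-network edge list — so a run is
fully reproducible and diffable from one file. The package ships its
defaults as ``data/defaults.yaml``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .bleeding_network import HRGraph
from .errors import ScenarioValidationError
from .regimens import get_regimen
from .risk_engine import (
    AcsMultiplier,
    CoronaryRiskTable,
    StrokeRiskTable,
    calibrate_coronary_table,
)


def _data_path(name: str) -> Path:
    return Path(resources.files("afacs.data") / name)


@dataclass(frozen=True)
class Scenario:
    """Validated model inputs for one analysis run."""

    name: str
    raw: dict[str, Any] = field(repr=False)

    stroke_table: StrokeRiskTable
    stroke_table_extended: StrokeRiskTable
    acs_multiplier: AcsMultiplier
    oac_rrr: float
    dapt_vs_oac_rr: float

    coronary_anchors: tuple[tuple[int, str, float], ...]
    crosscheck_anchors: tuple[tuple[int, str, float], ...]
    coronary_table: CoronaryRiskTable
    complex_pci_risk_ratio: float

    graph: HRGraph = field(repr=False)

    sample_size: dict[str, float] = field(default_factory=dict)

    @property
    def scenario_hash(self) -> str:
        """Stable content hash of the raw config, for run manifests."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(raw: dict, problems: list[str], *keys: str) -> Any:
    node: Any = raw
    for key in keys:
        if not isinstance(node, dict) or key not in node:
            problems.append("missing key: " + ".".join(keys))
            return None
        node = node[key]
    return node


def load_scenario(path: str | Path | None = None) -> Scenario:
    """Load and validate a scenario file (the bundled defaults when None).

    Validation is fail-fast and exhaustive: every missing or malformed
    key is collected and reported at once, and all referenced tables are
    built before anything executes.
    """
    if path is None:
        path = _data_path("defaults.yaml")
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ScenarioValidationError([f"{path} does not contain a mapping"])

    problems: list[str] = []
    rates = _require(raw, problems, "stroke", "annual_rate_per_100")
    ext = raw.get("stroke", {}).get("extension_annual_rate_per_100", {}) or {}
    mult = _require(raw, problems, "stroke", "acs_multiplier")
    oac_rrr = _require(raw, problems, "stroke", "oac_rrr")
    dapt_rr = _require(raw, problems, "stroke", "dapt_vs_oac_rr")
    anchors = _require(raw, problems, "coronary", "nntb_anchors")
    crosscheck = raw.get("coronary", {}).get("crosscheck_anchors", []) or []
    complex_rr = _require(raw, problems, "coronary", "complex_pci_risk_ratio")
    edges_csv = _require(raw, problems, "bleeding", "edges_csv")

    edges_path: Path | None = None
    if edges_csv is not None:
        edges_path = Path(edges_csv)
        if not edges_path.is_absolute():
            candidate = path.parent / edges_path
            edges_path = candidate if candidate.exists() else _data_path(str(edges_csv))
        if not edges_path.exists():
            problems.append(f"bleeding edge list not found: {edges_csv}")
    if problems:
        raise ScenarioValidationError(problems)

    stroke_table = StrokeRiskTable({int(k): float(v) for k, v in rates.items()})
    merged = dict(stroke_table.annual_rate_per_100)
    merged.update({int(k): float(v) for k, v in ext.items()})
    stroke_ext = StrokeRiskTable(merged)
    anchor_tuples = tuple((int(s), str(p), float(n)) for s, p, n in anchors)
    graph = HRGraph.from_csv(edges_path)
    for node in raw.get("bleeding", {}).get("qualitative_nodes", []) or []:
        graph._g.add_node(get_regimen(node))

    return Scenario(
        name=str(raw.get("name", path.stem)),
        raw=raw,
        stroke_table=stroke_table,
        stroke_table_extended=stroke_ext,
        acs_multiplier=AcsMultiplier(float(mult)),
        oac_rrr=float(oac_rrr),
        dapt_vs_oac_rr=float(dapt_rr),
        coronary_anchors=anchor_tuples,
        crosscheck_anchors=tuple((int(s), str(p), float(n)) for s, p, n in crosscheck),
        coronary_table=calibrate_coronary_table(anchor_tuples),
        complex_pci_risk_ratio=float(complex_rr),
        graph=graph,
        sample_size=dict(raw.get("sample_size", {}) or {}),
    )
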