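"""Indirect comparison of 30-day bleeding risk via a hazard-ratio network.

No randomized trial compares OAC-based combination therapy head-to-head
with modern (ticagrelor/prasugrel) DAPT on bleeding. The network therefore
composes *direct* pairwise hazard ratios — each from one trial or registry
— along paths through shared comparators: if A vs B has HR h1 and B vs C
has HR h2, the indirect A-vs-C estimate is h1 * h2 (Bucher-style
point-estimate composition; no uncertainty propagation).

Edges are directed (from, to, hr) but traversable both ways: walking an
edge against its direction contributes 1/hr. Composition is done in log
space and exponentiated, so reversing a path yields exactly the
reciprocal. The bundled edge list is a tree (each trial contributes one
comparison), so every indirect HR is path-unique.

Edge schema accepts an optional standard-error column for forward
compatibility; it is currently unused (the analysis composes point
estimates only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import DomainError, NoPathError, PathBrokenError
from .regimens import Regimen, get_regimen


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of reported 2-dp HRs)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HREdge:
    """A direct bleeding comparison: hazard of ``from_regimen`` relative
    to ``to_regimen``, with its source study label."""

    from_regimen: Regimen
    to_regimen: Regimen
    hr: float
    source: str = ""
    se_log_hr: float | None = None  # accepted but unused (point estimates only)

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise DomainError(f"hazard ratio must be > 0, got {self.hr}")


class HRGraph:
    """Directed hazard-ratio graph over antithrombotic regimens."""

    def __init__(self, edges: Iterable[HREdge] = (), extra_nodes: Iterable[Regimen] = ()):
        self._g = nx.Graph()
        self._edges: list[HREdge] = []
        for node in extra_nodes:
            self._g.add_node(get_regimen(node))
        for edge in edges:
            self.add_edge(edge)

    def add_edge(self, edge: HREdge) -> None:
        u, v = edge.from_regimen, edge.to_regimen
        if self._g.has_edge(u, v):
            raise DomainError(
                f"duplicate direct comparison between {u.name!r} and {v.name!r}"
            )
        # store log-HR oriented from 'from_regimen' so reverse traversal
        # is an exact sign flip
        self._g.add_edge(u, v, log_hr=math.log(edge.hr), origin=u, edge=edge)
        self._edges.append(edge)

    @property
    def nodes(self) -> list[Regimen]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[HREdge]:
        return list(self._edges)

    def _step_log_hr(self, a: Regimen, b: Regimen) -> float:
        if not self._g.has_edge(a, b):
            raise PathBrokenError(a.name, b.name)
        data = self._g.edges[a, b]
        return data["log_hr"] if data["origin"] == a else -data["log_hr"]

    def compose_path(self, path: Sequence[Regimen | str]) -> float:
        """Composed HR along an explicit regimen path (reverse edges inverted)."""
        path = [get_regimen(p) for p in path]
        if len(path) < 1:
            raise DomainError("path must contain at least one regimen")
        log_hr = 0.0
        for a, b in zip(path, path[1:]):
            log_hr += self._step_log_hr(a, b)
        return math.exp(log_hr)

    def indirect_hr(self, regimen_a: Regimen | str, regimen_b: Regimen | str) -> float:
        """Indirect HR of ``regimen_a`` vs ``regimen_b`` via shortest paths.

        If several shortest paths disagree by more than 1% a consistency
        warning is raised (the bundled graph is a tree, so paths are
        unique there).
        """
        a, b = get_regimen(regimen_a), get_regimen(regimen_b)
        for node in (a, b):
            if node not in self._g:
                raise NoPathError(f"regimen {node.name!r} not in graph")
        if a == b:
            return 1.0
        try:
            paths = list(nx.all_shortest_paths(self._g, a, b))
        except nx.NetworkXNoPath:
            raise NoPathError(
                f"no connecting comparisons between {a.name!r} and {b.name!r}"
            ) from None
        hrs = [self.compose_path(p) for p in paths]
        if max(hrs) / min(hrs) > 1.01:
            warnings.warn(
                f"shortest paths between {a.name!r} and {b.name!r} disagree by "
                f">1% ({min(hrs):.4g} vs {max(hrs):.4g}); network is inconsistent",
                stacklevel=2,
            )
        return hrs[0]

    def all_pairwise(self, nodes: Sequence[Regimen | str] | None = None) -> pd.DataFrame:
        """Full matrix M of indirect HRs: M[a, b] * M[b, a] = 1, diagonal 1.

        Qualitative-only nodes (no composable estimate) are excluded.
        """
        if nodes is None:
            nodes = [
                n for n in self._g.nodes
                if not n.qualitative_only and self._g.degree(n) > 0
            ]
        nodes = [get_regimen(n) for n in nodes]
        names = [n.name for n in nodes]
        mat = pd.DataFrame(1.0, index=names, columns=names)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                hr = self.indirect_hr(a, b)
                mat.loc[a.name, b.name] = hr
                mat.loc[b.name, a.name] = 1.0 / hr
        return mat

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "from": e.from_regimen.name,
                    "to": e.to_regimen.name,
                    "hr": e.hr,
                    "source": e.source,
                }
                for e in self._edges
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HRGraph":
        edges = [
            HREdge(
                get_regimen(row["from"]),
                get_regimen(row["to"]),
                float(row["hr"]),
                str(row.get("source", "") or ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(edges)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HRGraph":
        return cls.from_frame(pd.read_csv(path))


def bundled_edges_path() -> Path:
    return Path(resources.files("afacs.data") / "bleeding_edges.csv")


def default_graph() -> HRGraph:
    """The bundled direct-comparison network.

    One edge per study: the registry anchor (warfarin TAT vs clopidogrel
    DAPT), each NOAC-DAT trial vs warfarin TAT, and the two modern-DAPT
    trials vs clopidogrel DAPT. The edoxaban-based DAT is present as a
    qualitative node only: its trial supports a directional statement
    (higher early bleeding than DAPT) but no composable point estimate.
    """
    graph = HRGraph.from_csv(bundled_edges_path())
    graph._g.add_node(get_regimen("DAT-edoxaban-60"))
    return graph
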