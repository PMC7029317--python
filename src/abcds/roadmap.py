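"""Hypothetical disease-progression roadmap over patient subgroups.

Nodes are subgroups (or merged cross-stratum groups) carrying their median
(ADL, BPSD, CF) vector and median TDD; they are ordered top-to-bottom by
descending median TDD, the overall-severity statistic (lower = more
severe).  Directed edges represent plausible progression steps and are
color-classified by which domains deteriorate from source to destination:

* ``red``    -- ADL, BPSD, and CF all deteriorate;
* ``blue``   -- ADL and/or CF deteriorate, BPSD does not;
* ``yellow`` -- only BPSD deteriorates;
* ``green``  -- BPSD and CF deteriorate, ADL does not;
* ``orange`` -- ADL and BPSD deteriorate, CF does not.

A domain "deteriorates" when its median drops by more than ``delta_tol``
points (default 1.0, operationalizing "almost unchanged").  Every edge
must strictly decrease median TDD — severity is monotone along the
roadmap, which makes the graph acyclic by construction.

The published edge set is expert judgment, not a computed object; it ships
here as a data fixture (:func:`default_edge_list`) and the module
validates and classifies it.  An experimental discovery mode proposes all
monotone-TDD edges between successive severity layers instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from abcds.profiles import MergedGroup, SubgroupProfile, merge_similar

__all__ = [
    "EDGE_COLORS",
    "RoadmapNode",
    "RoadmapEdge",
    "RoadmapGraph",
    "classify_edge",
    "build_roadmap",
    "discover_edges",
    "export_graph",
    "import_graph_json",
    "default_nodes",
    "default_edge_list",
]

EDGE_COLORS = ("blue", "red", "yellow", "green", "orange")

#: progression steps named in the study's narrative, terminal paths included
DEFAULT_EDGE_LIST: tuple[tuple[str, str], ...] = (
    ("C1.1", "GI"),
    ("C1.1", "C1.3"),
    ("GI", "C1.3"),
    ("GI", "GII"),
    ("GI", "C2.4"),
    ("C2.4", "GIII"),
    ("C2.4", "C3.2"),
    ("GII", "GIII"),
    ("C1.3", "GIII"),
    ("GIII", "C3.3"),
    ("C2.4", "C3.3"),
    ("C3.2", "C3.3"),
)


@dataclass(frozen=True)
class RoadmapNode:
    """One roadmap box: a subgroup or merged group with its median profile."""

    name: str
    median_vector: tuple[float, float, float]  # (ADL, BPSD, CF)
    median_tdd: float
    terminal: bool = False

    def __post_init__(self):
        if self.median_tdd <= 0:
            raise ValueError("median TDD must be positive")


@dataclass(frozen=True)
class RoadmapEdge:
    """A classified progression step between two roadmap nodes."""

    src: str
    dst: str
    deltas: tuple[float, float, float]  # dst medians - src medians
    color: str


@dataclass(frozen=True)
class RoadmapGraph:
    """Directed acyclic progression graph with severity-ordered nodes."""

    nodes: tuple[RoadmapNode, ...]
    edges: tuple[RoadmapEdge, ...]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(
                node.name,
                median_vector=node.median_vector,
                median_tdd=node.median_tdd,
                terminal=node.terminal,
            )
        for edge in self.edges:
            g.add_edge(edge.src, edge.dst, deltas=edge.deltas, color=edge.color)
        return g


def classify_edge(
    src_vec: Sequence[float],
    dst_vec: Sequence[float],
    delta_tol: float = 1.0,
) -> str:
    """Color a progression step by which domains deteriorate.

    ``src_vec`` and ``dst_vec`` are (ADL, BPSD, CF) medians; a domain
    deteriorates iff its delta (dst - src) is below ``-delta_tol``.  The
    five colors are exhaustive and mutually exclusive over deterioration
    patterns; a pair with no qualifying pattern (e.g. nothing deteriorates)
    returns ``"none"``.
    """
    d_adl, d_bpsd, d_cf = (d - s for s, d in zip(src_vec, dst_vec))
    adl = d_adl < -delta_tol
    bpsd = d_bpsd < -delta_tol
    cf = d_cf < -delta_tol
    if adl and bpsd and cf:
        return "red"
    if (adl or cf) and not bpsd:
        return "blue"
    if bpsd and not adl and not cf:
        return "yellow"
    if bpsd and cf and not adl:
        return "green"
    if adl and bpsd and not cf:
        return "orange"
    return "none"


def build_roadmap(
    nodes: Sequence[RoadmapNode],
    edge_list: Sequence[tuple[str, str]] | None = None,
    delta_tol: float = 1.0,
) -> RoadmapGraph:
    """Assemble and validate the progression graph.

    Every edge must strictly decrease median TDD and receive a color other
    than ``"none"``; offending edges raise with a per-edge report rather
    than being silently dropped.  Exactly one node must be flagged
    terminal (the end-stage analog).
    """
    if edge_list is None:
        edge_list = DEFAULT_EDGE_LIST
    by_name = {n.name: n for n in nodes}
    if len(by_name) != len(nodes):
        raise ValueError("duplicate node names")
    n_terminal = sum(n.terminal for n in nodes)
    if n_terminal != 1:
        raise ValueError(f"roadmap needs exactly one terminal node, found {n_terminal}")

    problems = []
    edges = []
    for src, dst in edge_list:
        if src not in by_name or dst not in by_name:
            problems.append(f"{src}->{dst}: unknown node")
            continue
        s, d = by_name[src], by_name[dst]
        if not d.median_tdd < s.median_tdd:
            problems.append(
                f"{src}->{dst}: median TDD does not decrease "
                f"({s.median_tdd:.1f} -> {d.median_tdd:.1f})"
            )
            continue
        color = classify_edge(s.median_vector, d.median_vector, delta_tol)
        if color == "none":
            problems.append(f"{src}->{dst}: no qualifying deterioration pattern")
            continue
        deltas = tuple(
            round(dv - sv, 10) for sv, dv in zip(s.median_vector, d.median_vector)
        )
        edges.append(RoadmapEdge(src=src, dst=dst, deltas=deltas, color=color))
    if problems:
        raise ValueError("rejected edges:\n  " + "\n  ".join(problems))

    ordered = tuple(sorted(nodes, key=lambda n: -n.median_tdd))
    graph = RoadmapGraph(nodes=ordered, edges=tuple(edges))
    if not nx.is_directed_acyclic_graph(graph.to_networkx()):
        raise AssertionError("roadmap contains a cycle despite TDD monotonicity")
    return graph


def discover_edges(
    nodes: Sequence[RoadmapNode], delta_tol: float = 1.0
) -> list[tuple[str, str]]:
    """Experimental: propose all monotone-TDD edges between successive layers.

    Nodes are sorted by descending median TDD and each node is linked to
    every node in the next severity layer whose deterioration pattern gets
    a color.  This is a discovery aid, not the published edge set.
    """
    ordered = sorted(nodes, key=lambda n: -n.median_tdd)
    out = []
    for i, src in enumerate(ordered[:-1]):
        dst = ordered[i + 1]
        if classify_edge(src.median_vector, dst.median_vector, delta_tol) != "none":
            out.append((src.name, dst.name))
    return out


def export_graph(graph: RoadmapGraph, fmt: str = "dot") -> str:
    """Serialize the roadmap as Graphviz DOT or JSON."""
    if fmt == "dot":
        lines = ["digraph roadmap {", "  rankdir=TB;"]
        for node in graph.nodes:
            adl, bpsd, cf = node.median_vector
            label = (
                f"{node.name}\\n({adl:g}, {bpsd:g}, {cf:g})\\nTDD {node.median_tdd:.1f}"
            )
            shape = ", shape=doublecircle" if node.terminal else ""
            lines.append(f'  "{node.name}" [label="{label}"{shape}];')
        for edge in graph.edges:
            lines.append(f'  "{edge.src}" -> "{edge.dst}" [color={edge.color}];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "json":
        payload = {
            "nodes": [
                {
                    "name": n.name,
                    "median_vector": list(n.median_vector),
                    "median_tdd": n.median_tdd,
                    "terminal": n.terminal,
                }
                for n in graph.nodes
            ],
            "edges": [
                {"src": e.src, "dst": e.dst, "deltas": list(e.deltas), "color": e.color}
                for e in graph.edges
            ],
        }
        return json.dumps(payload, indent=2) + "\n"
    raise ValueError(f"unknown format {fmt!r}; choose 'dot' or 'json'")


def import_graph_json(text: str) -> RoadmapGraph:
    """Inverse of :func:`export_graph` for the JSON format."""
    payload = json.loads(text)
    nodes = tuple(
        RoadmapNode(
            name=n["name"],
            median_vector=tuple(n["median_vector"]),
            median_tdd=n["median_tdd"],
            terminal=n["terminal"],
        )
        for n in payload["nodes"]
    )
    edges = tuple(
        RoadmapEdge(
            src=e["src"], dst=e["dst"], deltas=tuple(e["deltas"]), color=e["color"]
        )
        for e in payload["edges"]
    )
    return RoadmapGraph(nodes=nodes, edges=edges)


def nodes_from_groups(
    groups: Sequence[MergedGroup],
    profiles: Sequence[SubgroupProfile],
    terminal: str | None = None,
) -> list[RoadmapNode]:
    """Turn merged groups (plus pass-through singletons) into roadmap nodes.

    Merged-group medians are the size-weighted member medians computed by
    :func:`abcds.profiles.merge_similar`; singleton nodes carry their
    subgroup's own medians.  ``terminal`` names the end-stage node and
    defaults to the lowest-TDD node.
    """
    if terminal is None:
        terminal = min(groups, key=lambda g: g.profile["tdd"]).name
    nodes = []
    for g in groups:
        nodes.append(
            RoadmapNode(
                name=g.name,
                median_vector=(g.profile["adl"], g.profile["bpsd"], g.profile["cf"]),
                median_tdd=g.profile["tdd"],
                terminal=g.name == terminal,
            )
        )
    return nodes


def default_nodes(
    reference: str = "C1.1", tau: float = 8.0, terminal: str = "C3.3"
) -> list[RoadmapNode]:
    """Roadmap nodes built from the packaged subgroup summaries.

    Loads the published per-subgroup medians, merges similar subgroups into
    GI/GII/GIII, and returns the eight severity-ordered nodes.
    """
    from abcds.synthetic import load_fixture_profiles

    profiles = load_fixture_profiles()
    groups = merge_similar(profiles, reference=reference, tau=tau)
    return nodes_from_groups(groups, profiles, terminal=terminal)


def default_edge_list() -> list[tuple[str, str]]:
    """The packaged progression-step fixture (narrative edge set)."""
    return list(DEFAULT_EDGE_LIST)
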