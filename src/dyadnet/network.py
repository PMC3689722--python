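"""Group interaction networks over combined mother-infant states.

Nodes are combined states; a directed edge records every observed
transition between two states, pooled over all dyads of a group.  Each
edge carries its raw count and its *transition rate*: 100 x count /
(total transitions in the group).  Dividing by the group total normalizes
simultaneously for the number of dyads and for unequal recording lengths.
Nodes additionally carry dwell time (total seconds the group spent in the
state) and a per-dyad mean dwell used for display scaling.  States that
were occupied but never entered or left (dwell without edges) are retained
as isolated nodes — their presence is itself a group feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .codebook import CodeBook, CombinedState
from .stats import ChiSquareResult, chisq_2x2
from .streams import BehavioralStream, Transition, extract_transitions, splice_other

__all__ = [
    "InteractionNetwork",
    "ConnectivityProfile",
    "build_network",
    "connectivity_profile",
    "compare_connectivity",
    "export_network",
]


@dataclass
class InteractionNetwork:
    """A weighted directed network of behavioral state transitions.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes are
    :class:`CombinedState` with attributes ``dwell`` (total seconds),
    ``n_dyads`` (dyads observed in the state) and ``mean_dwell``
    (dwell / n_dyads), and whose edges carry ``count`` and ``rate_percent``.
    """

    group: str
    graph: nx.DiGraph
    total_transitions: int
    n_dyads: int
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_counts(self) -> dict[Transition, int]:
        return {
            Transition(u, v): data["count"] for u, v, data in self.graph.edges(data=True)
        }

    def edge_rates(self) -> dict[Transition, float]:
        return {
            Transition(u, v): data["rate_percent"]
            for u, v, data in self.graph.edges(data=True)
        }

    def rate(self, transition: Transition) -> float:
        """Rate of one transition; 0.0 when the edge is absent."""
        if self.graph.has_edge(transition.source, transition.target):
            return self.graph.edges[transition.source, transition.target]["rate_percent"]
        return 0.0

    def dwell(self, state: CombinedState) -> int:
        return self.graph.nodes[state]["dwell"] if state in self.graph else 0

    def recompute_rates(self) -> None:
        """Refresh ``rate_percent`` and ``total_transitions`` from edge counts."""
        total = sum(d["count"] for _, _, d in self.graph.edges(data=True))
        self.total_transitions = total
        for _, _, data in self.graph.edges(data=True):
            data["rate_percent"] = 100.0 * data["count"] / total if total else float("nan")

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(
            self.group, self.graph.copy(), self.total_transitions, self.n_dyads, dict(self.meta)
        )


def build_network(
    streams: Sequence[BehavioralStream],
    codebook: CodeBook,
    group: str,
) -> InteractionNetwork:
    """Pool one group's dyad streams into an interaction network.

    Each stream is spliced at 'other'-coded seconds and transitions are
    extracted per segment, so no edge ever spans a dyad boundary or a
    splice cut.  Rates are percentages of the group's total transition
    count.  A group with zero transitions yields an empty edge set with
    ``total_transitions == 0`` and a ``meta["no_transitions"]`` flag.
    """
    if not streams:
        raise ValueError("at least one stream required")
    for s in streams:
        if s.group != group:
            raise ValueError(f"stream {s.dyad_id} has group {s.group!r}, expected {group!r}")

    g = nx.DiGraph()
    total = 0
    for stream in streams:
        dyad_states: set[CombinedState] = set()
        for segment in splice_other(stream, codebook):
            transitions, dwell = extract_transitions(segment)
            for state, seconds in dwell.items():
                if state not in g:
                    g.add_node(state, dwell=0, n_dyads=0)
                g.nodes[state]["dwell"] += seconds
                dyad_states.add(state)
            for tr in transitions:
                if g.has_edge(tr.source, tr.target):
                    g.edges[tr.source, tr.target]["count"] += 1
                else:
                    g.add_edge(tr.source, tr.target, count=1)
                total += 1
        for state in dyad_states:
            g.nodes[state]["n_dyads"] += 1

    for state, data in g.nodes(data=True):
        data["mean_dwell"] = data["dwell"] / data["n_dyads"] if data["n_dyads"] else 0.0
    net = InteractionNetwork(group=group, graph=g, total_transitions=total, n_dyads=len(streams))
    net.recompute_rates()
    if total == 0:
        net.meta["no_transitions"] = True
    return net


@dataclass(frozen=True)
class ConnectivityProfile:
    """Coarse-grained degree distribution over five connectivity categories.

    Categories (from unweighted in-/out-degree): (1) one in and one out,
    (2) multiple in, one out, (3) one in, multiple out, (4) multiple in and
    out, (5) no in or no out.  Fully isolated nodes (zero in AND zero out)
    are a sub-count of category 5.
    """

    c1: int
    c2: int
    c3: int
    c4: int
    c5: int
    isolated_count: int

    @property
    def n_nodes(self) -> int:
        return self.c1 + self.c2 + self.c3 + self.c4 + self.c5

    def count(self, category: int | str) -> int:
        if category == "isolated":
            return self.isolated_count
        return {1: self.c1, 2: self.c2, 3: self.c3, 4: self.c4, 5: self.c5}[int(category)]


def _category(in_deg: int, out_deg: int) -> int:
    if in_deg == 0 or out_deg == 0:
        return 5
    if in_deg == 1 and out_deg == 1:
        return 1
    if in_deg > 1 and out_deg == 1:
        return 2
    if in_deg == 1 and out_deg > 1:
        return 3
    return 4


def connectivity_profile(network: InteractionNetwork) -> ConnectivityProfile:
    """Classify every node by its unweighted in- and out-degree."""
    counts = {1: 0, 2: 0, 3: 0, 4: 0, 5: 0}
    isolated = 0
    g = network.graph
    for node in g.nodes:
        in_deg, out_deg = g.in_degree(node), g.out_degree(node)
        counts[_category(in_deg, out_deg)] += 1
        if in_deg == 0 and out_deg == 0:
            isolated += 1
    return ConnectivityProfile(
        counts[1], counts[2], counts[3], counts[4], counts[5], isolated
    )


def node_category(network: InteractionNetwork, state: CombinedState) -> int:
    """Connectivity category (1-5) of a single node."""
    g = network.graph
    return _category(g.in_degree(state), g.out_degree(state))


def compare_connectivity(
    profile_a: ConnectivityProfile,
    profile_b: ConnectivityProfile,
    focal: int | str,
) -> ChiSquareResult:
    """Chi-square test of a focal connectivity category between two networks.

    The 2x2 table is group x (focal category vs rest) over node counts;
    ``focal`` may be a category 1-5 or ``"isolated"``.
    """
    if profile_a.n_nodes == 0 or profile_b.n_nodes == 0:
        raise ValueError("both profiles must be non-empty")
    return chisq_2x2(
        profile_a.count(focal), profile_a.n_nodes, profile_b.count(focal), profile_b.n_nodes
    )


# -- exports ---------------------------------------------------------------


def node_table(network: InteractionNetwork) -> pd.DataFrame:
    """Node attributes (dwell, mean_dwell, connectivity category) as a table."""
    rows = [
        {
            "state": str(state),
            "infant_code": state.infant,
            "mother_code": state.mother,
            "dwell": data["dwell"],
            "mean_dwell": data["mean_dwell"],
            "n_dyads": data["n_dyads"],
            "category": node_category(network, state),
        }
        for state, data in sorted(network.graph.nodes(data=True))
    ]
    return pd.DataFrame(rows)


def edge_table(network: InteractionNetwork) -> pd.DataFrame:
    """Edge attributes (count, rate_percent) as a table, direction explicit."""
    rows = [
        {
            "source": str(u),
            "target": str(v),
            "count": data["count"],
            "rate_percent": data["rate_percent"],
        }
        for u, v, data in sorted(network.graph.edges(data=True))
    ]
    return pd.DataFrame(rows)


def export_network(network: InteractionNetwork, basepath: str | Path) -> list[Path]:
    """Write GraphML, SIF and node/edge attribute tables for graph viewers.

    Produces ``<basepath>.graphml``, ``<basepath>.sif``,
    ``<basepath>.nodes.tsv`` and ``<basepath>.edges.tsv``; returns the paths.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    paths = []

    gml = nx.DiGraph()
    for state, data in network.graph.nodes(data=True):
        gml.add_node(
            str(state),
            dwell=int(data["dwell"]),
            mean_dwell=float(data["mean_dwell"]),
            category=node_category(network, state),
        )
    for u, v, data in network.graph.edges(data=True):
        gml.add_edge(str(u), str(v), count=int(data["count"]), rate_percent=float(data["rate_percent"]))
    p = Path(str(basepath) + ".graphml")
    nx.write_graphml(gml, p)
    paths.append(p)

    p = Path(str(basepath) + ".sif")
    with open(p, "w", encoding="utf-8") as fh:
        for u, v in sorted(network.graph.edges):
            fh.write(f"{u}\ttransition\t{v}\n")
    paths.append(p)

    p = Path(str(basepath) + ".nodes.tsv")
    node_table(network).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = Path(str(basepath) + ".edges.tsv")
    edge_table(network).to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths
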