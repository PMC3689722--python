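"""Group comparison: network subtraction, distinct-transition flagging, chi-square.

Two groups' interaction networks are compared by subtracting per-edge
transition rates over the union of their edge sets (an edge absent from
one network contributes rate 0).  Edges whose rate difference reaches the
distinctness threshold (default 0.5 percentage points, inclusive) are
flagged as group-distinctive and their raw counts tested with a 2x2
Pearson chi-square against the group totals.  Node dwell times are
subtracted unnormalized (plain seconds), for display scaling only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebook import CombinedState
from .network import InteractionNetwork
from .stats import ChiSquareResult, chisq_2x2
from .streams import Transition

__all__ = [
    "DifferenceNetwork",
    "subtract_networks",
    "flag_distinct_transitions",
    "difference_table",
    "export_difference",
]

DEFAULT_THRESHOLD = 0.5  # percentage points


@dataclass
class DifferenceNetwork:
    """Per-edge rate differences and per-node dwell differences (A minus B)."""

    group_a: str
    group_b: str
    rate_difference: dict[Transition, float]
    dwell_difference: dict[CombinedState, float]
    threshold: float
    flags_a: list[Transition]  # rate_difference >= +threshold (A-distinct)
    flags_b: list[Transition]  # rate_difference <= -threshold (B-distinct)
    chi_square: dict[Transition, ChiSquareResult]
    counts_a: dict[Transition, int] = field(default_factory=dict)
    counts_b: dict[Transition, int] = field(default_factory=dict)
    total_a: int = 0
    total_b: int = 0


def _sorted_flags(
    edges: list[Transition], diffs: dict[Transition, float]
) -> list[Transition]:
    # |difference| descending; ties broken by (source, target) state order
    return sorted(edges, key=lambda t: (-abs(diffs[t]), t.source, t.target))


def flag_distinct_transitions(
    rate_difference: dict[Transition, float], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[Transition], list[Transition]]:
    """Split edges into A-distinct (diff >= +threshold) and B-distinct lists.

    The threshold is inclusive; both lists are sorted by |difference|
    descending with a deterministic lexicographic tie-break.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a = [t for t, d in rate_difference.items() if d >= threshold]
    b = [t for t, d in rate_difference.items() if d <= -threshold]
    return _sorted_flags(a, rate_difference), _sorted_flags(b, rate_difference)


def subtract_networks(
    net_a: InteractionNetwork,
    net_b: InteractionNetwork,
    threshold: float = DEFAULT_THRESHOLD,
    test_all: bool = False,
) -> DifferenceNetwork:
    """Subtract group B's network from group A's (rates in A minus rates in B).

    Chi-square tests are computed for the flagged (distinct) edges, or for
    every union edge when ``test_all`` is set; edges whose 2x2 table has a
    zero marginal are skipped (the test is undefined there).
    """
    if net_a.total_transitions == 0 or net_b.total_transitions == 0:
        raise ValueError("both networks need at least one transition")

    counts_a = net_a.edge_counts()
    counts_b = net_b.edge_counts()
    edges = set(counts_a) | set(counts_b)
    diffs = {t: net_a.rate(t) - net_b.rate(t) for t in edges}

    nodes = set(net_a.graph.nodes) | set(net_b.graph.nodes)
    dwell_diff = {s: float(net_a.dwell(s) - net_b.dwell(s)) for s in nodes}

    flags_a, flags_b = flag_distinct_transitions(diffs, threshold)
    to_test = sorted(edges) if test_all else flags_a + flags_b
    chi: dict[Transition, ChiSquareResult] = {}
    for t in to_test:
        try:
            chi[t] = chisq_2x2(
                counts_a.get(t, 0),
                net_a.total_transitions,
                counts_b.get(t, 0),
                net_b.total_transitions,
            )
        except ValueError:
            pass  # zero marginal: untestable edge
    return DifferenceNetwork(
        group_a=net_a.group,
        group_b=net_b.group,
        rate_difference=diffs,
        dwell_difference=dwell_diff,
        threshold=threshold,
        flags_a=flags_a,
        flags_b=flags_b,
        chi_square=chi,
        counts_a={t: counts_a.get(t, 0) for t in edges},
        counts_b={t: counts_b.get(t, 0) for t in edges},
        total_a=net_a.total_transitions,
        total_b=net_b.total_transitions,
    )


def difference_table(diff: DifferenceNetwork) -> pd.DataFrame:
    """Edge-level comparison as a table: rates, difference, flag, chi-square."""
    rows = []
    for t in sorted(diff.rate_difference):
        d = diff.rate_difference[t]
        flag = ""
        if t in diff.flags_a:
            flag = f"{diff.group_a}_distinct"
        elif t in diff.flags_b:
            flag = f"{diff.group_b}_distinct"
        chi = diff.chi_square.get(t)
        rows.append(
            {
                "source": str(t.source),
                "target": str(t.target),
                "count_a": diff.counts_a[t],
                "count_b": diff.counts_b[t],
                "rate_a": 100.0 * diff.counts_a[t] / diff.total_a,
                "rate_b": 100.0 * diff.counts_b[t] / diff.total_b,
                "difference": d,
                "flag": flag,
                "chi2": chi.statistic if chi else float("nan"),
                "p": chi.p_value if chi else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def export_difference(diff: DifferenceNetwork, basepath: str | Path) -> list[Path]:
    """Write the difference as a TSV edge table and an attributed GraphML."""
    import networkx as nx

    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    paths = [Path(str(basepath) + ".edges.tsv")]
    difference_table(diff).to_csv(paths[0], sep="\t", index=False)

    g = nx.DiGraph()
    for state, d in diff.dwell_difference.items():
        g.add_node(str(state), dwell_difference=float(d))
    for t, d in diff.rate_difference.items():
        chi = diff.chi_square.get(t)
        flag = (
            f"{diff.group_a}_distinct"
            if t in diff.flags_a
            else f"{diff.group_b}_distinct" if t in diff.flags_b else ""
        )
        g.add_edge(
            str(t.source),
            str(t.target),
            rate_difference=float(d),
            flag=flag,
            chi2=float(chi.statistic) if chi else float("nan"),
            p=float(chi.p_value) if chi else float("nan"),
        )
    p = Path(str(basepath) + ".graphml")
    nx.write_graphml(g, p)
    paths.append(p)
    return paths
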