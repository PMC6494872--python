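"""Median-joining haplotype networks.

The network starts from the epsilon-relaxed minimum-spanning network
(MSN) over the observed haplotypes; quasi-median vectors of connectable
triplets are inserted iteratively, and superfluous latent nodes are
pruned at the end.  Edge weights are the number of differing sites.  All
tie-breaking is lexicographic so the output is independent of the input
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx


def collapse_identical(seqs: Mapping[str, str]) -> list[tuple[str, list[str]]]:
    """Merge identical sequences; returns (haplotype, carrier ids) sorted."""
    groups: dict[str, list[str]] = {}
    for sid in sorted(seqs):
        groups.setdefault(seqs[sid], []).append(sid)
    return sorted(groups.items(), key=lambda kv: kv[1][0])


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class MjnGraph:
    graph: nx.Graph
    epsilon: int
    dropped_sites: int = 0
    #: retained variable-site rCRS positions (1-based), parallel to node states
    site_positions: list[int] = field(default_factory=list)

    @property
    def observed_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if not d["is_median"]
        )

    @property
    def median_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["is_median"])

    def node_table(self):
        import pandas as pd

        rows = [
            {
                "node": n,
                "is_median": d["is_median"],
                "multiplicity": d["multiplicity"],
                "carriers": ",".join(d["carriers"]),
                "states": d["states"],
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows)

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d["carriers"] = ",".join(d["carriers"])
        nx.write_graphml(g, path)

    def to_dot(self) -> str:
        lines = ["graph mjn {"]
        for n, d in sorted(self.graph.nodes(data=True)):
            shape = "point" if d["is_median"] else "circle"
            label = f"{n} (x{d['multiplicity']})" if not d["is_median"] else ""
            lines.append(f'  "{n}" [shape={shape}, label="{label}"];')
        for u, v, d in sorted(self.graph.edges(data=True)):
            lines.append(f'  "{u}" -- "{v}" [label="{d["weight"]}"];')
        lines.append("}")
        return "\n".join(lines)


def _msn_edges(
    nodes: Sequence[str], states: Mapping[str, str], epsilon: int
) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum-spanning-network edges.

    An edge of weight w is feasible when its endpoints are not connected
    using only edges of weight < w - epsilon; at epsilon = 0 this is the
    classical MSN, whose edge set contains every minimum spanning tree.
    """
    pairs = sorted(
        ((_hamming(states[u], states[v]), u, v) for u, v in combinations(nodes, 2))
    )
    edges = []
    for w, u, v in pairs:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(
            (x, y) for ww, x, y in pairs if ww < w - epsilon
        )
        if not nx.has_path(g, u, v):
            edges.append((u, v, w))
    return edges


def _quasi_median(a: str, b: str, c: str) -> str:
    """Per-site majority state of a triplet; three-way ties keep the first
    sequence's state (a deterministic simplification of the quasi-median)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def build_mjn(
    seqs: Mapping[str, str], epsilon: int = 0, max_rounds: int = 20
) -> MjnGraph:
    """Median-joining network of equal-length sequences with ids.

    Sites carrying a missing symbol (``N`` or ``-``) in any sequence are
    excluded with a warning; identical sequences are collapsed into one
    node with recorded multiplicity.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")

    ids = sorted(seqs)
    keep = [
        i
        for i in range(lengths.pop())
        if all(seqs[s][i] not in "N-" for s in ids)
    ]
    dropped = len(seqs[ids[0]]) - len(keep)
    if dropped:
        warnings.warn(f"dropped {dropped} sites with missing symbols")
    # restrict to variable sites (weights are unaffected)
    variable = [
        i for i in keep if len({seqs[s][i] for s in ids}) > 1
    ]
    reduced = {s: "".join(seqs[s][i] for i in variable) for s in ids}

    collapsed = collapse_identical(reduced)
    states: dict[str, str] = {}
    meta: dict[str, dict] = {}
    for hap, carriers in collapsed:
        name = carriers[0]
        states[name] = hap
        meta[name] = {
            "is_median": False,
            "multiplicity": len(carriers),
            "carriers": carriers,
        }

    median_count = 0
    for _ in range(max_rounds):
        nodes = sorted(states)
        edges = _msn_edges(nodes, states, epsilon)
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v, _w in edges:
            adj[u].add(v)
            adj[v].add(u)
        max_w = max((w for _, _, w in edges), default=0)

        existing = set(states.values())
        new_medians = set()
        for u in nodes:
            for v, w in combinations(sorted(adj[u]), 2):
                m = _quasi_median(states[u], states[v], states[w])
                if m in existing or m in new_medians:
                    continue
                links = (
                    _hamming(m, states[u]),
                    _hamming(m, states[v]),
                    _hamming(m, states[w]),
                )
                if max(links) <= max_w + epsilon:
                    new_medians.add(m)
        if not new_medians:
            break
        for m in sorted(new_medians):
            median_count += 1
            name = f"mv{median_count}"
            states[name] = m
            meta[name] = {"is_median": True, "multiplicity": 0, "carriers": []}

    # prune superfluous latent nodes, then rebuild the final MSN
    while True:
        nodes = sorted(states)
        edges = _msn_edges(nodes, states, epsilon)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(edges)
        removable = []
        for n in nodes:
            if not meta[n]["is_median"]:
                continue
            deg = g.degree(n)
            if deg <= 1:
                removable.append(n)
            elif deg == 2:
                u, v = list(g.neighbors(n))
                through = g[n][u]["weight"] + g[n][v]["weight"]
                if through >= _hamming(states[u], states[v]):
                    removable.append(n)
        if not removable:
            break
        for n in removable:
            del states[n]
            del meta[n]

    graph = nx.Graph()
    for n in sorted(states):
        graph.add_node(n, states=states[n], **meta[n])
    for u, v, w in _msn_edges(sorted(states), states, epsilon):
        graph.add_edge(u, v, weight=w)
    return MjnGraph(
        graph=graph,
        epsilon=epsilon,
        dropped_sites=dropped,
        site_positions=[i + 1 for i in variable],
    )
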