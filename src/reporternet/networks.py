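"""Interaction-network loading, DEG-centred sub-network reconstruction,
centralities, and hub selection.

Hubs are the union of the top-k nodes by degree and the top-k by betweenness
centrality (unnormalized shortest-path counts, endpoints excluded), so the
hub set always has between k and 2k members.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def load_edge_list(path: str | Path, directed: bool = False) -> nx.Graph:
    """Load a two-column (or wider; extras ignored) TSV edge list.

    Lines starting with '#' and blank lines are skipped. Identifiers are
    whitespace-trimmed, case-preserving. In undirected mode reversed
    duplicates collapse to one edge; self-loops are dropped with a logged
    count in either mode.
    """
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            n_lines += 1
            if u == v:
                n_self += 1
                continue
            graph.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: no edges found")
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Simple-interaction-format export for visualization tools."""
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")


def reconstruct_subnetwork(seeds: Iterable[str], ppi: nx.Graph) -> nx.Graph:
    """Induced subgraph on the seed genes and their first neighbors.

    Node set = (seeds present in the network) plus their direct neighbors;
    every network edge internal to that node set is kept. Seeds left with no
    edges are excluded. Seeds absent from the network are reported, not fatal.
    """
    seeds = set(seeds)
    mapped = seeds & set(ppi.nodes)
    missing = seeds - mapped
    if missing:
        logger.info("%d seed(s) not present in the interaction network", len(missing))
    if not mapped:
        raise ValueError("empty subnetwork: no seed maps into the interaction network")
    nodes = set(mapped)
    for s in mapped:
        nodes.update(ppi.neighbors(s))
    sub = ppi.subgraph(nodes).copy()
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    sub.remove_nodes_from(isolated)
    if sub.number_of_nodes() == 0:
        raise ValueError("empty subnetwork: all mapped seeds are isolated")
    return sub


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree and exact unnormalized betweenness for every node.

    Betweenness sums, over ordered node pairs collapsed to unordered pairs,
    the fraction of shortest paths passing through the node (endpoints
    excluded); disconnected graphs are handled naturally, pairs in different
    components contributing nothing.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    btw = nx.betweenness_centrality(net, normalized=False)
    table = pd.DataFrame(
        {
            "degree": [net.degree(n) for n in net.nodes],
            "betweenness": [btw[n] for n in net.nodes],
        },
        index=pd.Index(net.nodes, name="node"),
    )
    table["hub_flag"] = False
    table["selection_reason"] = ""
    return table.sort_index()


def _top_k(table: pd.DataFrame, metric: str, other: str, k: int) -> list[str]:
    # ties at the k-th rank broken by the other metric, then lexicographic id
    ranked = table.assign(_node=table.index.astype(str)).sort_values(
        [metric, other, "_node"], ascending=[False, False, True], kind="stable"
    )
    return list(ranked.index[:k])


def select_hubs(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Flag hub nodes: union of top-k by degree and top-k by betweenness.

    ``selection_reason`` records which list(s) admitted each hub. The hub
    count is always between k and 2k.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if table.empty:
        raise ValueError("empty centrality table")
    by_degree = set(_top_k(table, "degree", "betweenness", k))
    by_btw = set(_top_k(table, "betweenness", "degree", k))
    out = table.copy()
    out["hub_flag"] = False
    out["selection_reason"] = ""
    for node in by_degree | by_btw:
        reason = (
            "both"
            if node in by_degree and node in by_btw
            else ("degree" if node in by_degree else "betweenness")
        )
        out.loc[node, ["hub_flag", "selection_reason"]] = True, reason
    return out.sort_values(
        ["hub_flag", "degree", "betweenness"], ascending=[False, False, False], kind="stable"
    )


def hub_nodes(table: pd.DataFrame) -> list[str]:
    return sorted(table.index[table["hub_flag"]])
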