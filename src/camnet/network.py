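"""Differential-feature interaction subnetworks and central-node support.

Networks are undirected :class:`networkx.Graph` objects with an optional
``score`` edge attribute (confidence in [0, 1], STRING-style). The
subnetwork of differential features is the induced subgraph on the union of
differential genes (DEG) and differential proteins (DEP), restricted to
edges at or above a confidence cutoff; features significant at both the
transcript and the protein level ("concordant") are the candidate central
nodes of the map.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def read_edge_list(path) -> nx.Graph:
    """Read a 2-3 column TSV edge list (node_a, node_b[, score])."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    g = nx.Graph()
    has_score = df.shape[1] >= 3
    for row in df.itertuples(index=False):
        u, v = str(row[0]), str(row[1])
        if u == v:
            raise ValueError(f"self-edge on {u!r}")
        attrs = {"score": float(row[2])} if has_score else {}
        g.add_edge(u, v, **attrs)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a, b, float(data.get("score", 1.0))))
    rows.sort()
    pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def differential_subnetwork(
    net: nx.Graph,
    deg: set[str],
    dep: set[str],
    min_score: float = 0.4,
) -> nx.Graph:
    """Induced subgraph on deg ∪ dep keeping edges with score >= min_score.

    Nodes of the selection present in the network but left without a
    qualifying edge are retained and flagged with the node attribute
    ``isolated=True``. Edges without a score attribute count as score 1.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    selected = deg | dep
    if not selected:
        logger.warning("differential_subnetwork: empty DEG ∪ DEP selection")
    nodes = selected & set(net.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    for u, v, data in net.edges(nodes, data=True):
        if u in nodes and v in nodes and float(data.get("score", 1.0)) >= min_score:
            sub.add_edge(u, v, **data)
    for n in sub.nodes:
        sub.nodes[n]["isolated"] = sub.degree(n) == 0
    return sub


def concordant_nodes(
    deg: set[str],
    dep: set[str],
    mapping: dict[str, str] | None = None,
) -> tuple[set[str], set[str]]:
    """Features differential at both the transcript and the protein level.

    ``mapping`` translates protein ids to transcript/gene ids (identity by
    default). Returns (concordant gene ids, unmapped protein ids).
    """
    if mapping is None:
        mapped = {p: p for p in dep}
        unmapped: set[str] = set()
    else:
        mapped = {p: mapping[p] for p in dep if p in mapping}
        unmapped = dep - set(mapped)
        if unmapped:
            logger.warning("concordant_nodes: %d unmapped protein id(s)", len(unmapped))
    return deg & set(mapped.values()), unmapped


def node_degree(net: nx.Graph) -> dict[str, int]:
    """Distinct-neighbor degree per node (handshake: sum = 2|E|)."""
    return {n: int(d) for n, d in net.degree()}
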