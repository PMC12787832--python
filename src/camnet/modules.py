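"""Contraction of a feature-level interaction network into a functional-module
network, and degree-based module ranking.

Every node of the interaction network is first assigned to one (or, in
multi mode, several) KEGG pathway modules from its annotation. The quotient
graph then has the modules as nodes; two modules are connected iff at least
one node-level edge joins a member of one to a member of the other.
Parallel module edges collapse into a single edge whose weight counts the
supporting node edges ("redundant edges removed"); within-module edges are
reported separately as self-support, never as self-loops. A module's
connectivity degree — the number of distinct neighboring modules — ranks
its relative importance; a weighted variant (sum of incident edge weights)
is also available.

A brute-force pairwise-enumeration oracle (:func:`contraction_oracle`)
verifies the contraction on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .gmt import GeneSetCollection

POLICIES = ("unique_lexicographic", "unique_smallest_set", "multi")


@dataclass
class ModuleAssignment:
    """node -> pathway(s) mapping under a stated policy.

    In unique modes every assigned node maps to exactly one pathway id
    (stored as a 1-element frozenset for uniformity); unannotated nodes are
    listed in ``unassigned``.
    """

    mapping: dict[str, frozenset[str]]
    policy: str
    unassigned: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy.startswith("unique"):
            bad = {n for n, p in self.mapping.items() if len(p) != 1}
            if bad:
                raise ValueError(f"non-unique assignment under {self.policy}: {sorted(bad)[:5]}")
        if set(self.mapping) & set(self.unassigned):
            raise ValueError("a node cannot be both assigned and unassigned")

    def modules_of(self, node: str) -> frozenset[str]:
        return self.mapping.get(node, frozenset())


def assign_modules(
    nodes: set[str],
    annotation: GeneSetCollection,
    policy: str = "unique_lexicographic",
) -> ModuleAssignment:
    """Assign each node to its functional module(s) from the annotation.

    unique_lexicographic: multi-pathway nodes take the lexicographically
    smallest pathway id; unique_smallest_set: the smallest annotated pathway
    (ties broken lexicographically); multi: all pathways kept.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    node_sets: dict[str, set[str]] = {n: set() for n in nodes}
    for pid, members in annotation.sets.items():
        for n in members & frozenset(nodes):
            node_sets[n].add(pid)

    mapping: dict[str, frozenset[str]] = {}
    unassigned: set[str] = set()
    for n in sorted(nodes):
        ps = node_sets[n]
        if not ps:
            unassigned.add(n)
        elif policy == "multi":
            mapping[n] = frozenset(ps)
        elif policy == "unique_lexicographic":
            mapping[n] = frozenset({min(ps)})
        else:  # unique_smallest_set
            mapping[n] = frozenset({min(ps, key=lambda p: (len(annotation.members(p)), p))})
    return ModuleAssignment(mapping, policy, frozenset(unassigned))


@dataclass
class ModuleNetwork:
    """Quotient graph over pathway modules.

    ``edges`` maps an unordered module pair (sorted tuple) to the number of
    supporting cross-module node edges; ``self_support`` counts
    within-module node edges; ``dropped_edges`` counts node edges with an
    unassigned endpoint.
    """

    modules: frozenset[str]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    self_support: dict[str, int] = field(default_factory=dict)
    dropped_edges: int = 0

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"module self-edge {a!r}")
            if a > b:
                raise ValueError(f"module pair {a, b} not in sorted order")
            if w < 1:
                raise ValueError("module edge weight must be >= 1")
            if a not in self.modules or b not in self.modules:
                raise ValueError(f"edge endpoint outside module set: {(a, b)}")

    @property
    def degree(self) -> dict[str, int]:
        """Distinct-neighbor count per module."""
        d = {m: 0 for m in self.modules}
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    @property
    def weighted_degree(self) -> dict[str, int]:
        """Sum of incident cross-module edge weights per module."""
        d = {m: 0 for m in self.modules}
        for (a, b), w in self.edges.items():
            d[a] += w
            d[b] += w
        return d

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.modules))
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def degree_table(self) -> pd.DataFrame:
        deg, wdeg = self.degree, self.weighted_degree
        rows = [
            (m, deg[m], wdeg[m], self.self_support.get(m, 0))
            for m in sorted(self.modules)
        ]
        return pd.DataFrame(
            rows, columns=["module", "degree", "weighted_degree", "self_support"]
        )


def contract(net: nx.Graph, assignment: ModuleAssignment) -> ModuleNetwork:
    """Contract a node-level network into its functional-module network.

    Unique mode: each node edge supports exactly one module edge (or one
    module's self-support when both endpoints share the module). Multi
    mode: each distinct unordered pathway pair spanned by the edge's
    endpoint annotations contributes once per node edge; pathways shared by
    both endpoints accrue self-support once per node edge.
    """
    modules: set[str] = set()
    for mods in assignment.mapping.values():
        modules |= mods
    edges: dict[tuple[str, str], int] = {}
    self_support: dict[str, int] = {}
    dropped = 0
    for u, v in net.edges():
        mu, mv = assignment.modules_of(u), assignment.modules_of(v)
        if not mu or not mv:
            dropped += 1
            continue
        pairs = {(min(a, b), max(a, b)) for a in mu for b in mv if a != b}
        for pair in pairs:
            edges[pair] = edges.get(pair, 0) + 1
        for shared in mu & mv:
            self_support[shared] = self_support.get(shared, 0) + 1
    return ModuleNetwork(frozenset(modules), edges, self_support, dropped)


def contraction_oracle(net: nx.Graph, assignment: ModuleAssignment) -> ModuleNetwork:
    """Independent brute-force contraction for verification at test scale.

    For every unordered module pair, scans all node pairs for connecting
    edges; must agree exactly with :func:`contract`.
    """
    if net.number_of_nodes() > 200:
        raise ValueError("oracle is for instances with <= 200 nodes")
    modules: set[str] = set()
    for mods in assignment.mapping.values():
        modules |= mods
    members: dict[str, set[str]] = {m: set() for m in modules}
    for n, mods in assignment.mapping.items():
        for m in mods:
            members[m].add(n)

    edges: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(sorted(modules), 2):
        # a node edge whose endpoints both belong to members[a] ∩ members[b]
        # would be met twice by the scan; dedupe on the unordered node pair
        seen: set[tuple[str, str]] = set()
        w = 0
        for u in members[a]:
            for v in members[b]:
                if u == v or not net.has_edge(u, v):
                    continue
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen.add(key)
                    w += 1
        if w:
            edges[(a, b)] = w

    self_support: dict[str, int] = {}
    for m in sorted(modules):
        w = 0
        for u, v in itertools.combinations(sorted(members[m]), 2):
            if net.has_edge(u, v):
                w += 1
        if w:
            self_support[m] = w

    dropped = sum(
        1
        for u, v in net.edges()
        if not assignment.modules_of(u) or not assignment.modules_of(v)
    )
    return ModuleNetwork(frozenset(modules), edges, self_support, dropped)


def rank_modules(mn: ModuleNetwork, by: str = "degree") -> list[tuple[str, int]]:
    """Modules ordered by descending connectivity, ties broken by module id."""
    if by == "degree":
        values = mn.degree
    elif by == "weighted_degree":
        values = mn.weighted_degree
    else:
        raise ValueError(f"unknown ranking criterion {by!r}")
    return sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
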