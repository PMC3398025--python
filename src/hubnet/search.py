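"""Maximal-scoring connected subnetwork search.

Two solvers share one contract: ``exact_mss`` enumerates every connected
induced subgraph of a small graph and is the oracle; ``heuristic_mss``
scales to real interactomes by contracting positive components into
meta-nodes, transferring negative node penalties onto edges, and extracting
the best path through two rounds of minimum spanning trees.

All tie-breaking is lexicographic on sorted node lists so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from hubnet._errors import DataError, NumericalError
from hubnet.bum import (
    BUMFit,
    DEFAULT_FDR_GRID,
    ScoreTable,
    choose_fdr_for_fraction,
    fit_bum,
    score_pvalues,
)
from hubnet.diffexpr import moderated_t
from hubnet.graph_io import ExpressionMatrix, clean_network

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ScoredGraph:
    """A network with one finite real score per node."""

    graph: nx.Graph
    score: dict

    def __post_init__(self) -> None:
        missing = [n for n in self.graph.nodes if n not in self.score]
        if missing:
            raise DataError(f"{len(missing)} nodes without a score")
        bad = [n for n in self.graph.nodes if not np.isfinite(self.score[n])]
        if bad:
            raise DataError(f"{len(bad)} nodes with non-finite scores")


@dataclass(frozen=True)
class Subnetwork:
    """A connected induced subgraph and its aggregate node score."""

    nodes: frozenset
    edges: frozenset
    total_score: float

    @property
    def size(self) -> int:
        return len(self.nodes)

    def __bool__(self) -> bool:
        return bool(self.nodes)


EMPTY_SUBNETWORK = Subnetwork(nodes=frozenset(), edges=frozenset(), total_score=0.0)


def _make_subnetwork(g: nx.Graph, score: dict, nodes) -> Subnetwork:
    nodes = frozenset(nodes)
    if not nodes:
        return EMPTY_SUBNETWORK
    sub = g.subgraph(nodes)
    if not nx.is_connected(sub):
        raise NumericalError("internal error: candidate subnetwork not connected")
    edges = frozenset(frozenset(e) for e in sub.edges)
    total = float(sum(score[n] for n in nodes))
    return Subnetwork(nodes=nodes, edges=edges, total_score=total)


def _lex_key(nodes) -> tuple:
    return tuple(sorted(nodes))


# ---------------------------------------------------------------------------
# exact solver
# ---------------------------------------------------------------------------

def exact_mss(sg: ScoredGraph, max_nodes: int = 15) -> Subnetwork:
    """Optimal connected induced subgraph by exhaustive enumeration.

    Only for graphs of at most ``max_nodes`` nodes.  Returns the empty
    subnetwork (score 0) when no subset scores positively.  Ties between
    equal-score optima break by lexicographically smallest sorted node list.
    """
    g, score = sg.graph, sg.score
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n > max_nodes:
        raise DataError(
            f"graph has {n} > {max_nodes} nodes; use heuristic_mss for large graphs"
        )
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in g.edges:
        if u == v:
            continue
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    scores = [float(score[v]) for v in nodes]

    best_score = 0.0
    best_nodes: tuple = ()
    for mask in range(1, 1 << n):
        total = 0.0
        m = mask
        while m:
            b = m & -m
            total += scores[b.bit_length() - 1]
            m ^= b
        if total < best_score - _TIE_TOL:
            continue
        # connectivity check via bitmask flood fill
        start = mask & -mask
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            f = frontier
            while f:
                b = f & -f
                nxt |= adj[b.bit_length() - 1]
                f ^= b
            nxt &= mask & ~seen
            seen |= nxt
            frontier = nxt
        if seen != mask:
            continue
        cand = tuple(nodes[i] for i in range(n) if mask >> i & 1)
        if total > best_score + _TIE_TOL:
            best_score, best_nodes = total, cand
        elif abs(total - best_score) <= _TIE_TOL and best_nodes and cand < best_nodes:
            best_nodes = cand
        elif abs(total - best_score) <= _TIE_TOL and not best_nodes and total > 0:
            best_score, best_nodes = total, cand
    if not best_nodes:
        return EMPTY_SUBNETWORK
    return _make_subnetwork(g, score, best_nodes)


# ---------------------------------------------------------------------------
# MST heuristic
# ---------------------------------------------------------------------------

def _contract_positive(g: nx.Graph, score: dict):
    """Stage 1: contract each connected component of positive nodes.

    Returns (meta graph, meta score, meta -> member set).  Meta-node ids are
    the lexicographically smallest member, so the contraction is
    deterministic.
    """
    pos_nodes = [n for n in g.nodes if score[n] > 0]
    comps = [sorted(c) for c in nx.connected_components(g.subgraph(pos_nodes))]
    rep = {}
    members = {}
    for comp in sorted(comps):
        r = comp[0]
        members[r] = set(comp)
        for n in comp:
            rep[n] = r
    h = nx.Graph()
    h_score = {}
    for n in sorted(g.nodes):
        m = rep.get(n, n)
        if m not in h:
            h.add_node(m)
            h_score[m] = (
                float(sum(score[x] for x in sorted(members[m])))
                if m in members
                else float(score[n])
            )
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        mu, mv = rep.get(u, u), rep.get(v, v)
        if mu != mv:
            h.add_edge(mu, mv)
    return h, h_score, members


def _edge_weight(score: dict, u, v) -> float:
    """Stage 2: an edge pays for the negative endpoints it touches."""
    return -min(score[u], 0.0) - min(score[v], 0.0)


def _weighted(h: nx.Graph, h_score: dict) -> nx.Graph:
    w = nx.Graph()
    w.add_nodes_from(sorted(h.nodes))
    for u, v in sorted(tuple(sorted(e)) for e in h.edges):
        w.add_edge(u, v, weight=_edge_weight(h_score, u, v))
    return w


def _tree_paths_nodes(tree: nx.Graph, sources) -> dict:
    """Unique tree paths from each source to every reachable node."""
    paths = {}
    for s in sources:
        paths[s] = nx.single_source_shortest_path(tree, s)
    return paths


def heuristic_mss(sg: ScoredGraph) -> Subnetwork:
    """MST-based approximation of the maximal-scoring subnetwork.

    Stages: contract positive components into meta-nodes; weight edges by
    the negative-node penalty of their endpoints; take an MST; collect the
    negative connectors lying on MST paths between positive meta-nodes;
    re-span meta-nodes plus connectors with a second MST and return its
    highest-scoring path, meta-nodes expanded back.  The result is
    post-pruned by iteratively removing negative-score leaves.
    """
    g, score = sg.graph, sg.score
    if g.number_of_nodes() == 0:
        return EMPTY_SUBNETWORK
    if not nx.is_connected(g):
        raise DataError("heuristic_mss requires a connected graph")

    h, h_score, members = _contract_positive(g, score)
    metas = sorted(members)
    if not metas:
        return EMPTY_SUBNETWORK
    if len(metas) == 1:
        return _prune(g, score, members[metas[0]])

    w = _weighted(h, h_score)
    t1 = nx.minimum_spanning_tree(w, weight="weight", algorithm="kruskal")

    # stage 4: negative connectors on MST paths between positive meta-nodes
    paths1 = _tree_paths_nodes(t1, metas)
    connectors: set = set()
    for i, a in enumerate(metas):
        for b in metas[i + 1:]:
            path = paths1[a].get(b)
            if path is None:
                continue
            connectors.update(n for n in path if n not in members)

    # stage 5: second MST on meta-nodes + connectors, best path by node score
    keep = set(metas) | connectors
    h2 = _weighted(h.subgraph(keep), h_score)
    best_nodes: tuple = ()
    best_score = -np.inf
    for comp in nx.connected_components(h2):
        t2 = nx.minimum_spanning_tree(h2.subgraph(comp), weight="weight",
                                      algorithm="kruskal")
        comp_metas = sorted(set(comp) & set(metas))
        if not comp_metas:
            continue
        paths2 = _tree_paths_nodes(t2, comp_metas)
        # candidate paths: every meta-meta pair plus each meta alone
        for a in comp_metas:
            for b in comp_metas:
                if b < a:
                    continue
                path = paths2[a].get(b)
                if path is None:
                    continue
                nodeset = set()
                for n in path:
                    nodeset.update(members.get(n, {n}))
                total = sum(score[x] for x in nodeset)
                key = _lex_key(nodeset)
                if total > best_score + _TIE_TOL or (
                    abs(total - best_score) <= _TIE_TOL and key < _lex_key(best_nodes)
                ):
                    best_score, best_nodes = total, tuple(sorted(nodeset))
    if not best_nodes or best_score <= 0:
        # no positive path; fall back to best single meta-node
        best_meta = min(metas, key=lambda m: (-h_score[m], _lex_key(members[m])))
        if h_score[best_meta] <= 0:
            return EMPTY_SUBNETWORK
        return _prune(g, score, members[best_meta])
    return _prune(g, score, set(best_nodes))


def _prune(g: nx.Graph, score: dict, nodes: set) -> Subnetwork:
    """Iteratively strip negative-score leaves; keeps connectivity."""
    nodes = set(nodes)
    sub = g.subgraph(nodes).copy()
    while True:
        leaves = sorted(
            n for n in sub.nodes if sub.degree(n) <= 1 and score[n] < 0
        )
        if not leaves or sub.number_of_nodes() <= 1:
            break
        sub.remove_nodes_from(leaves)
    if sub.number_of_nodes() == 0:
        return EMPTY_SUBNETWORK
    return _make_subnetwork(g, score, set(sub.nodes))


# ---------------------------------------------------------------------------
# pipeline stage
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    subnetwork: Subnetwork
    fit: BUMFit
    table: ScoreTable
    de: pd.DataFrame
    fdr: float


def perturbed_subnetwork(
    m: ExpressionMatrix,
    g: nx.Graph,
    target_fraction: float = 0.10,
    fdr_grid=DEFAULT_FDR_GRID,
    exact_max_nodes: int = 15,
) -> SearchResult:
    """Full scoring-and-search chain for one condition.

    Moderated t -> BUM fit -> FDR scan to the target positive fraction ->
    node scores -> subnetwork search (exact when the cleaned graph is small
    enough, MST heuristic otherwise).
    """
    shared = sorted(set(m.gene_ids) & set(g.nodes))
    if len(shared) < 100:
        raise DataError(
            f"expression matrix and network share only {len(shared)} genes (< 100)"
        )
    net = clean_network(g, shared)
    mm = m.subset_genes(net.nodes)
    de = moderated_t(mm)
    fit = fit_bum(de["p"].to_numpy())
    if fit.lam >= 1.0 - 1e-9:
        # pure-noise fit: no attainable threshold, report an empty subnetwork
        table = ScoreTable(
            scores=pd.Series(-np.inf, index=de.index, dtype=float), tau=0.0, fdr=np.nan
        )
        return SearchResult(EMPTY_SUBNETWORK, fit, table, de, float("nan"))
    fdr = choose_fdr_for_fraction(fit, de["p"], target_fraction, fdr_grid)
    table = score_pvalues(fit, fdr, de["p"])
    sg = ScoredGraph(graph=net, score=table.scores.to_dict())
    if net.number_of_nodes() <= exact_max_nodes:
        sub = exact_mss(sg, max_nodes=exact_max_nodes)
    else:
        sub = heuristic_mss(sg)
    return SearchResult(sub, fit, table, de, fdr)


def write_subnetwork(sub: Subnetwork, table: ScoreTable, path_nodes, path_edges) -> None:
    """Node TSV (gene, score, in/out of subnetwork) and edge TSV."""
    with open(path_nodes, "w") as fh:
        fh.write("gene\tscore\tin_subnetwork\n")
        for gene in sorted(table.scores.index):
            flag = "in" if gene in sub.nodes else "out"
            fh.write(f"{gene}\t{table.scores[gene]:.10g}\t{flag}\n")
    with open(path_edges, "w") as fh:
        fh.write("u\tv\n")
        for u, v in sorted(tuple(sorted(e)) for e in sub.edges):
            fh.write(f"{u}\t{v}\n")
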