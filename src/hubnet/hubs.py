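"""Hub extraction, cross-condition hub-network assembly and perturbation tests.

Hubs are nodes whose within-subnetwork degree reaches the chosen empirical
degree quantile (linear interpolation, default 0.9).  The hub network is the
union of all conditions' hubs, connected by edges present in at least one
condition's perturbed subnetwork; each edge carries its condition
provenance.  Perturbation of the hub network in a dataset is the mean
absolute moderated t over measured hub genes, with a same-size random-set
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from hubnet._errors import DataError
from hubnet.search import Subnetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubSet:
    condition: str
    hubs: frozenset
    quantile_value: float
    degree: dict


@dataclass(frozen=True)
class HubNetwork:
    graph: nx.Graph  # edges carry a "provenance" frozenset of conditions
    components: tuple  # tuple of frozensets, sorted by (-size, lex)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)


@dataclass(frozen=True)
class PerturbationResult:
    statistic: float
    n_used: int
    p: float
    null_mean: float
    null_sd: float


def find_hubs(sub: Subnetwork, q: float = 0.9, condition: str = "") -> HubSet:
    """Nodes at or above the ``q`` degree quantile of a subnetwork.

    The quantile is the linear-interpolation empirical quantile of the
    within-subnetwork degree multiset.
    """
    if not sub:
        raise DataError("cannot extract hubs from an empty subnetwork")
    if not 0.0 < q < 1.0:
        raise DataError("quantile must be in (0, 1)")
    g = nx.Graph()
    g.add_nodes_from(sub.nodes)
    g.add_edges_from(tuple(e) for e in sub.edges)
    degree = {n: int(g.degree(n)) for n in sorted(g.nodes)}
    qv = float(np.quantile(np.array(sorted(degree.values()), dtype=float), q,
                           method="linear"))
    hubs = frozenset(n for n, d in degree.items() if d >= qv)
    return HubSet(condition=condition, hubs=hubs, quantile_value=qv, degree=degree)


def build_hub_network(hubsets: list[HubSet], subs: list[Subnetwork]) -> HubNetwork:
    """Union hub network with per-condition edge provenance.

    An edge joins two hubs (of any condition) iff it occurs in at least one
    condition's subnetwork.  Connected components are reported sorted by
    size (ties by lexicographically smallest member).
    """
    if len(hubsets) != len(subs):
        raise DataError("hub sets and subnetworks must align by condition")
    all_hubs = sorted(set().union(*[hs.hubs for hs in hubsets])) if hubsets else []
    g = nx.Graph()
    g.add_nodes_from(all_hubs)
    hub_set = set(all_hubs)
    for hs, sub in zip(hubsets, subs):
        for e in sub.edges:
            u, v = sorted(e)
            if u in hub_set and v in hub_set:
                if g.has_edge(u, v):
                    g[u][v]["provenance"] = g[u][v]["provenance"] | {hs.condition}
                else:
                    g.add_edge(u, v, provenance=frozenset({hs.condition}))
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), sorted(c)),
    )
    return HubNetwork(graph=g, components=tuple(comps))


def perturbation_test(
    hub_genes,
    de: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> PerturbationResult:
    """Mean |moderated t| over hub genes vs a random-gene-set null.

    The null draws ``n_perm`` same-size gene sets uniformly without
    replacement from all genes measured in ``de``; the p-value is
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    measured = de.index
    hub_genes = set(hub_genes)
    used = sorted(hub_genes & set(measured))
    dropped = len(hub_genes) - len(used)
    if dropped:
        logger.info("perturbation_test: %d hub genes not measured, dropped", dropped)
    if len(used) < 10:
        raise DataError(
            f"only {len(used)} hub genes measured in the dataset (< 10)"
        )
    abs_t = de["t_mod"].abs()
    observed = float(abs_t.loc[used].mean())
    rng = np.random.default_rng(seed)
    pool = abs_t.to_numpy(dtype=float)
    n_used = len(used)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(pool.size, size=n_used, replace=False)
        null[i] = pool[idx].mean()
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PerturbationResult(
        statistic=observed,
        n_used=n_used,
        p=p,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
    )


def subnetwork_overlap_test(a, b, universe: int) -> tuple[int, float]:
    """One-sided Fisher exact test for the overlap of two gene sets.

    Returns (overlap count, p-value of over-representation) from the 2x2
    membership table over a universe of ``universe`` genes.
    """
    a, b = set(a), set(b)
    if universe < len(a | b):
        raise DataError(
            f"universe {universe} smaller than |a union b| = {len(a | b)}"
        )
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, universe - len(a | b)],
    ]
    p = float(stats.fisher_exact(table, alternative="greater").pvalue)
    return k, p


def write_hub_network(hn: HubNetwork, hubsets: list[HubSet], path_nodes, path_edges) -> None:
    """Node TSV (gene, #conditions as hub) and edge TSV with provenance."""
    count = {}
    for hs in hubsets:
        for g in hs.hubs:
            count[g] = count.get(g, 0) + 1
    with open(path_nodes, "w") as fh:
        fh.write("gene\tn_conditions_hub\n")
        for gene in sorted(hn.graph.nodes):
            fh.write(f"{gene}\t{count.get(gene, 0)}\n")
    with open(path_edges, "w") as fh:
        fh.write("u\tv\tprovenance\n")
        for u, v in sorted(tuple(sorted(e)) for e in hn.graph.edges):
            prov = ",".join(sorted(hn.graph[u][v]["provenance"]))
            fh.write(f"{u}\t{v}\t{prov}\n")
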