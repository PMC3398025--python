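"""Synthetic networks, expression matrices, p-values and severity scores.

Every generator is deterministic given its parameters and seed, and the
ground truth (planted module, mixture parameters, coupled genes) is
returned alongside the data so each pipeline stage can be validated without
external downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hubnet._errors import DataError
from hubnet.graph_io import GROUP_CASE, GROUP_CONTROL, ExpressionMatrix


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    planted_module: frozenset = frozenset()
    effect_size: float = 0.0
    bum_params: tuple | None = None
    coupled_genes: frozenset = frozenset()
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_module": sorted(self.planted_module),
                    "effect_size": self.effect_size,
                    "bum_params": self.bum_params,
                    "coupled_genes": sorted(self.coupled_genes),
                    "seed": self.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_network(n: int, m_per_node: int = 2, seed: int = 0) -> nx.Graph:
    """Connected scale-free-like network by preferential attachment.

    ``n`` nodes, each newcomer attaching ``m_per_node`` edges; the result
    has ``m_per_node * (n - m_per_node)`` edges and a heavy-tailed degree
    distribution.
    """
    if n < 10:
        raise DataError("need n >= 10 nodes")
    if not 1 <= m_per_node < n:
        raise DataError("need 1 <= m_per_node < n")
    g = nx.barabasi_albert_graph(n, m_per_node, seed=int(seed))
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})


def plant_module(g: nx.Graph, size: int, seed: int = 0) -> frozenset:
    """Grow a connected node set by seeded breadth-first expansion."""
    nodes = sorted(g.nodes)
    if size < 1 or size > len(nodes):
        raise DataError(f"module size {size} not in [1, {len(nodes)}]")
    rng = np.random.default_rng(seed)
    start = nodes[int(rng.integers(len(nodes)))]
    module = [start]
    chosen = {start}
    frontier = sorted(set(g.neighbors(start)) - chosen)
    while len(module) < size:
        if not frontier:
            raise DataError(
                f"component around {start!r} exhausted at {len(module)} nodes"
            )
        nxt = frontier[int(rng.integers(len(frontier)))]
        module.append(nxt)
        chosen.add(nxt)
        frontier = sorted(
            {v for u in module for v in g.neighbors(u)} - chosen
        )
    return frozenset(module)


def simulate_expression(
    g: nx.Graph,
    module,
    n_case: int = 10,
    n_control: int = 10,
    effect: float = 2.0,
    sigma: float = 1.0,
    seed: int = 0,
    random_sign: bool = False,
    probe_duplication: bool = False,
    missing_rate: float = 0.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group expression matrix with a shifted planted module.

    Every gene is Normal(0, sigma^2) per sample; module genes gain
    ``effect * sigma`` in cases (sign randomized per gene when
    ``random_sign``).  With ``probe_duplication`` each gene gets 1-3 probe
    rows (ids ``<gene>_p<i>``) with extra noise; ``missing_rate`` knocks
    out entries at random to exercise imputation.
    """
    if effect < 0:
        raise DataError("effect must be >= 0")
    if sigma <= 0:
        raise DataError("sigma must be > 0")
    module = frozenset(module)
    unknown = module - set(g.nodes)
    if unknown:
        raise DataError(f"module genes not in network: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    genes = sorted(g.nodes)
    samples = [f"case{i:03d}" for i in range(n_case)] + [
        f"ctrl{i:03d}" for i in range(n_control)
    ]
    x = rng.normal(0.0, sigma, size=(len(genes), n_case + n_control))
    in_module = np.array([gene in module for gene in genes])
    signs = (
        rng.choice([-1.0, 1.0], size=len(genes)) if random_sign
        else np.ones(len(genes))
    )
    x[in_module, :n_case] += (effect * sigma * signs[in_module])[:, None]
    df = pd.DataFrame(x, index=genes, columns=samples)

    if probe_duplication:
        rows, index = [], []
        for gi, gene in enumerate(genes):
            n_probes = int(rng.integers(1, 4))
            for pi in range(n_probes):
                noise = rng.normal(0.0, 0.25 * sigma, size=df.shape[1])
                rows.append(df.iloc[gi].to_numpy() + noise)
                index.append(f"{gene}_p{pi}")
        df = pd.DataFrame(np.vstack(rows), index=index, columns=samples)

    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))

    group = pd.Series(
        [GROUP_CASE] * n_case + [GROUP_CONTROL] * n_control, index=samples
    )
    truth = SyntheticTruth(
        planted_module=module, effect_size=float(effect), seed=int(seed)
    )
    return ExpressionMatrix(df, group), truth


def probe_map_for(m: ExpressionMatrix) -> dict[str, str]:
    """Probe -> gene map for matrices produced with probe duplication."""
    return {p: p.rsplit("_p", 1)[0] for p in m.values.index}


def simulate_pvalues(lam: float, a: float, n: int, seed: int = 0) -> np.ndarray:
    """Draws from ``lam * Uniform(0,1) + (1 - lam) * Beta(a, 1)``."""
    if not 0.0 <= lam <= 1.0:
        raise DataError("lam must be in [0, 1]")
    if not 0.0 < a < 1.0:
        raise DataError("a must be in (0, 1)")
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    from_noise = rng.random(n) < lam
    u = rng.random(n)
    # Beta(a, 1) via inverse CDF: F^-1(u) = u**(1/a)
    return np.where(from_noise, u, u ** (1.0 / a))


def simulate_severity(
    m: ExpressionMatrix,
    coupled,
    slope: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    names: tuple[str, str] = ("mmse", "nft"),
) -> dict[str, pd.Series]:
    """Two anti-correlated severity scores coupled to chosen genes.

    The first score is ``-slope * mean(coupled expression) + noise`` (falls
    with severity, MMSE-like); the second uses ``+slope`` (rises, NFT-like).
    """
    coupled = sorted(set(coupled))
    unknown = set(coupled) - set(m.values.index)
    if unknown:
        raise DataError(f"coupled genes not in matrix: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    base = (
        m.values.loc[coupled].mean(axis=0).to_numpy(dtype=float)
        if coupled
        else np.zeros(m.n_samples)
    )
    first = -slope * base + rng.normal(0.0, noise_sd, size=m.n_samples)
    second = slope * base + rng.normal(0.0, noise_sd, size=m.n_samples)
    return {
        names[0]: pd.Series(first, index=m.values.columns),
        names[1]: pd.Series(second, index=m.values.columns),
    }
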