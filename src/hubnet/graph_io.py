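"""I/O and preprocessing for networks, expression matrices, probe maps and gene sets.

Networks are plain :class:`networkx.Graph` objects whose nodes are opaque
gene-identifier strings.  Expression data travel as :class:`ExpressionMatrix`,
a thin wrapper around a genes x samples :class:`pandas.DataFrame` with an
optional two-group design and named per-sample severity scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hubnet._errors import DataError

logger = logging.getLogger(__name__)

GROUP_CASE = "case"
GROUP_CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with an optional two-group design.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe id with sample ids as columns.
        Missing entries are NaN.
    group
        Optional Series mapping sample id -> ``"case"`` / ``"control"``.
    severity
        Optional named per-sample score vectors (e.g. ``{"mmse": ...}``).
    """

    values: pd.DataFrame
    group: pd.Series | None = None
    severity: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            # duplicates are legal for probe-level data; gene-level callers
            # collapse first
            pass
        if self.group is not None:
            self.group = self.group.reindex(self.values.columns)
            if self.group.isna().any():
                missing = list(self.values.columns[self.group.isna()])
                raise DataError(f"samples without group label: {missing}")
            bad = set(self.group.unique()) - {GROUP_CASE, GROUP_CONTROL}
            if bad:
                raise DataError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_control_split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (case columns, control columns); requires a design."""
        if self.group is None:
            raise DataError("expression matrix has no group design attached")
        case = self.values.loc[:, self.group == GROUP_CASE]
        ctrl = self.values.loc[:, self.group == GROUP_CONTROL]
        return case, ctrl

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.group, dict(self.severity))


# ---------------------------------------------------------------------------
# network reading / cleaning
# ---------------------------------------------------------------------------

def read_edge_list(path, dialect: str = "tsv") -> nx.Graph:
    """Read an undirected network from a SIF or two-column TSV edge list.

    Duplicate lines collapse to a single edge.  SIF lines fan out:
    ``A pp B C`` yields edges A-B and A-C.

    Raises
    ------
    DataError
        On an empty file or a malformed line (reported with its line number).
    """
    if dialect not in ("sif", "tsv"):
        raise DataError(f"unknown edge-list dialect: {dialect!r}")
    g = nx.Graph()
    n_edges = 0
    n_skipped = 0
    any_line = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                n_skipped += 1
                continue
            any_line = True
            tokens = line.split("\t") if dialect == "tsv" else line.split()
            tokens = [t.strip() for t in tokens if t.strip()]
            if dialect == "tsv":
                if len(tokens) != 2:
                    raise DataError(
                        f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}"
                    )
                g.add_edge(tokens[0], tokens[1])
                n_edges += 1
            else:  # sif: source relation target [target ...]
                if len(tokens) == 1:
                    # an isolated node is legal SIF
                    g.add_node(tokens[0])
                    continue
                if len(tokens) < 3:
                    raise DataError(
                        f"{path}: line {lineno}: SIF line needs source, relation "
                        f"and at least one target"
                    )
                src = tokens[0]
                for tgt in tokens[2:]:
                    g.add_edge(src, tgt)
                    n_edges += 1
    if not any_line:
        raise DataError(f"{path}: empty edge-list file")
    logger.info(
        "read %d edge lines (%d blank skipped) -> %d nodes, %d edges",
        n_edges, n_skipped, g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def clean_network(g: nx.Graph, measured) -> nx.Graph:
    """Restrict a network to measured genes and keep its largest component.

    Self-loops are dropped, nodes outside ``measured`` removed, and the
    largest connected component of the remainder returned.  Equal-size
    components tie-break by lexicographically smallest sorted node list.
    A surviving component must have at least two nodes: a single node is
    not a searchable network.
    """
    measured = set(measured)
    if not measured:
        raise DataError("measured gene set is empty")
    h = nx.Graph()
    h.add_nodes_from(n for n in g.nodes if n in measured)
    h.add_edges_from(
        (u, v) for u, v in g.edges if u != v and u in measured and v in measured
    )
    comps = [sorted(c) for c in nx.connected_components(h)]
    comps = [c for c in comps if len(c) >= 2]
    if not comps:
        raise DataError("no measured genes in network")
    comps.sort(key=lambda c: (-len(c), c))
    keep = comps[0]
    return h.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------

def filter_detection(
    m: ExpressionMatrix, calls: pd.DataFrame, min_fraction: float = 0.10
) -> ExpressionMatrix:
    """Drop rows detected in fewer than ``min_fraction`` of samples.

    ``calls`` is a boolean (or truthy) present/absent matrix with the same
    shape as the expression values.  A row detected in exactly
    ``min_fraction`` of samples is kept ("fewer than" is strict).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise DataError("min_fraction must be in [0, 1]")
    if calls.shape != m.values.shape:
        raise DataError(
            f"detection-call matrix shape {calls.shape} != expression shape "
            f"{m.values.shape}"
        )
    frac = calls.astype(bool).to_numpy().mean(axis=1)
    keep = frac >= min_fraction
    out = m.values.loc[keep]
    logger.info("detection filter: kept %d of %d rows", out.shape[0], m.n_genes)
    return ExpressionMatrix(out, m.group, dict(m.severity))


def collapse_probes(
    m: ExpressionMatrix,
    probe_map: dict,
    strategy: str = "max_variance",
    scores: pd.Series | None = None,
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    ``max_variance`` keeps the probe with the largest sample variance;
    ``best_correlation`` keeps the probe whose Pearson correlation with
    ``scores`` has the smallest p-value.  Ties break by probe id order.
    Probes absent from the map are dropped (count logged).
    """
    from scipy import stats

    if strategy not in ("max_variance", "best_correlation"):
        raise DataError(f"unknown collapse strategy: {strategy!r}")
    if strategy == "best_correlation" and scores is None:
        raise DataError("best_correlation collapse requires a score vector")

    unmapped = 0
    by_gene: dict[str, list[str]] = {}
    for probe in m.values.index:
        gene = probe_map.get(probe)
        if gene is None:
            unmapped += 1
            continue
        by_gene.setdefault(gene, []).append(probe)
    if unmapped:
        logger.info("collapse_probes: dropped %d unmapped probe rows", unmapped)

    if strategy == "best_correlation":
        scores = scores.reindex(m.values.columns).astype(float)

    def _pick(probes: list[str]) -> str:
        probes = sorted(probes)
        if len(probes) == 1:
            return probes[0]
        if strategy == "max_variance":
            best, best_var = probes[0], -np.inf
            for p in probes:
                v = float(np.nanvar(m.values.loc[p].to_numpy(), ddof=1))
                if np.isfinite(v) and v > best_var:
                    best, best_var = p, v
            return best
        # best_correlation: smallest correlation p-value; undefined -> worst
        best, best_p = probes[0], np.inf
        for p in probes:
            row = m.values.loc[p].to_numpy(dtype=float)
            mask = np.isfinite(row) & np.isfinite(scores.to_numpy())
            if mask.sum() < 3 or np.std(row[mask]) == 0 or np.std(scores.to_numpy()[mask]) == 0:
                continue
            pv = stats.pearsonr(row[mask], scores.to_numpy()[mask]).pvalue
            if pv < best_p:
                best, best_p = p, pv
        return best

    genes = sorted(by_gene)
    rows = [_pick(by_gene[g]) for g in genes]
    out = m.values.loc[rows].copy()
    out.index = genes
    return ExpressionMatrix(out, m.group, dict(m.severity))


def knn_impute(
    m: ExpressionMatrix, k: int = 10, max_missing_fraction: float = 0.10
) -> ExpressionMatrix:
    """Remove heavily missing rows and impute the rest by k-nearest rows.

    Rows missing in more than ``max_missing_fraction`` of samples are dropped
    first.  Each remaining missing entry becomes the mean over the ``k``
    nearest rows (Euclidean distance over co-observed columns, rescaled by
    the fraction observed) that have a value in that column.  Observed
    entries are untouched.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    vals = m.values.to_numpy(dtype=float)
    miss_frac = np.isnan(vals).mean(axis=1)
    keep_mask = miss_frac <= max_missing_fraction
    kept = m.values.loc[keep_mask]
    dropped = int((~keep_mask).sum())
    if dropped:
        logger.info("knn_impute: removed %d rows missing > %.0f%% of samples",
                    dropped, 100 * max_missing_fraction)
    x = kept.to_numpy(dtype=float)
    nan_mask = np.isnan(x)
    if not nan_mask.any():
        return ExpressionMatrix(kept.copy(), m.group, dict(m.severity))

    complete = ~nan_mask.any(axis=1)
    if complete.sum() < k:
        raise DataError(
            f"k={k} exceeds the {int(complete.sum())} complete rows available"
        )

    n_cols = x.shape[1]
    out = x.copy()
    target_rows = np.where(nan_mask.any(axis=1))[0]
    for i in target_rows:
        obs_i = ~nan_mask[i]
        # rescaled Euclidean distance to every other row over co-observed cols
        diff = x - x[i]
        co = obs_i & ~nan_mask  # co-observed columns per candidate row
        sq = np.where(co, diff**2, 0.0)
        n_co = co.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.sqrt(sq.sum(axis=1) * (n_cols / n_co))
        dist[i] = np.inf
        dist[n_co == 0] = np.inf
        for j in np.where(nan_mask[i])[0]:
            cand = np.where(~nan_mask[:, j] & np.isfinite(dist))[0]
            if cand.size == 0:
                raise DataError(
                    f"no donor rows for column {kept.columns[j]!r} of row "
                    f"{kept.index[i]!r}"
                )
            order = cand[np.argsort(dist[cand], kind="stable")]
            donors = order[: min(k, order.size)]
            out[i, j] = x[donors, j].mean()
    res = pd.DataFrame(out, index=kept.index, columns=kept.columns)
    return ExpressionMatrix(res, m.group, dict(m.severity))


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, members per line).

    Duplicate members within a set collapse silently; a duplicate set name
    or an empty member list is an error.
    """
    coll: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT needs name, description and "
                    f"at least one member"
                )
            name = parts[0]
            members = {p for p in parts[2:] if p}
            if not members:
                raise DataError(f"{path}: line {lineno}: set {name!r} is empty")
            if name in coll:
                raise DataError(f"{path}: line {lineno}: duplicate set name {name!r}")
            coll[name] = members
    if not coll:
        raise DataError(f"{path}: empty GMT file")
    return coll


# ---------------------------------------------------------------------------
# tabular readers / writers used by the CLI
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path,
    design_path=None,
    severity_paths: dict | None = None,
    negative_as_missing: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV (first column id, header row of sample ids).

    Empty fields and ``NA`` are missing; negative values are treated as
    missing only when ``negative_as_missing`` is set.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if negative_as_missing:
        df = df.mask(df < 0)
    group = None
    if design_path is not None:
        design = pd.read_csv(
            design_path, sep="\t", header=None, names=["sample", "group"], dtype=str,
        )
        group = design.set_index("sample")["group"]
    severity = {}
    for name, p in (severity_paths or {}).items():
        sv = pd.read_csv(p, sep="\t", header=None, names=["sample", "value"])
        severity[name] = sv.set_index("sample")["value"].astype(float)
    return ExpressionMatrix(df, group, severity)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def write_edge_list(g: nx.Graph, path) -> None:
    """Write edges as a sorted 2-column TSV (deterministic byte output)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")


def write_design_tsv(group: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for sample, label in group.items():
            fh.write(f"{sample}\t{label}\n")
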