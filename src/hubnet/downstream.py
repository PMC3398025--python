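"""Gene-set over-representation, enrichment maps and severity correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from hubnet._errors import DataError
from hubnet.graph_io import ExpressionMatrix


@dataclass(frozen=True)
class EnrichmentRow:
    name: str
    k: int  # overlap
    K: int  # set size (within universe, by assumption)
    n: int  # query size
    N: int  # universe size
    p: float
    significant: bool


def enrich(
    query,
    collection: dict,
    universe: int,
    min_overlap: int = 5,
    alpha: float = 0.01,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of a query set in each collection set.

    For each set, ``p = P(X >= k)`` with population ``universe``, successes
    ``|set|`` and draws ``|query|``.  A row is significant when the overlap
    strictly exceeds ``min_overlap`` and ``p < alpha`` (defaults 5 and 0.01).
    Rows come back sorted by p (ties by set name).
    """
    if not collection:
        raise DataError("empty gene-set collection")
    query = set(query)
    n = len(query)
    if universe < n:
        raise DataError(f"universe {universe} smaller than query size {n}")
    rows = []
    for name in sorted(collection):
        members = set(collection[name])
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, universe, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        rows.append(
            EnrichmentRow(
                name=name, k=k, K=K, n=n, N=universe, p=p,
                significant=(k > min_overlap and p < alpha),
            )
        )
    rows.sort(key=lambda r: (r.p, r.name))
    return rows


def enrichment_map(
    rows: list[EnrichmentRow],
    collection: dict,
    query,
    cutoff: float = 0.5,
    restrict_to_query: bool = True,
) -> nx.Graph:
    """Term graph of significant sets, joined by overlap coefficient >= cutoff.

    The coefficient ``|A & B| / min(|A|, |B|)`` is computed on the
    query-restricted sets by default (``restrict_to_query=False`` uses the
    full sets).  Edge weights hold the coefficient.
    """
    if not 0.0 < cutoff <= 1.0:
        raise DataError("cutoff must be in (0, 1]")
    query = set(query)
    sig = [r for r in rows if r.significant]
    g = nx.Graph()
    g.add_nodes_from(r.name for r in sig)
    restricted = {}
    for r in sig:
        s = set(collection[r.name])
        restricted[r.name] = (s & query) if restrict_to_query else s
    names = sorted(restricted)
    for i, s_name in enumerate(names):
        for t_name in names[i + 1:]:
            s, t = restricted[s_name], restricted[t_name]
            denom = min(len(s), len(t))
            if denom == 0:
                continue
            coeff = len(s & t) / denom
            if coeff >= cutoff:
                g.add_edge(s_name, t_name, weight=coeff)
    return g


@dataclass(frozen=True)
class SeverityCorrelation:
    gene: str
    r: dict  # score name -> Pearson r (NaN when undefined)
    p: dict  # score name -> two-sided p (NaN when undefined)
    klass: str  # "<name>_only", "both", or "neither"


def _classify(sig: dict[str, bool], names: list[str]) -> str:
    hits = [n for n in names if sig[n]]
    if len(hits) == len(names) and len(names) > 1:
        return "both"
    if len(hits) == 1:
        return f"{hits[0]}_only"
    if hits:  # >1 but not all (3+ score vectors)
        return "multiple"
    return "neither"


def severity_correlation(
    m: ExpressionMatrix,
    scores: dict[str, pd.Series] | None = None,
    alpha: float = 0.05,
) -> list[SeverityCorrelation]:
    """Per-gene Pearson correlation against each named severity score.

    A gene is significant for a score when the two-sided t-based p-value is
    at most ``alpha``.  Genes or scores with zero variance give undefined r
    and never count as significant.
    """
    scores = scores if scores is not None else m.severity
    if not scores:
        raise DataError("no severity score vectors supplied")
    names = sorted(scores)
    aligned = {}
    for name in names:
        v = pd.Series(scores[name]).reindex(m.values.columns).astype(float)
        if v.isna().any():
            raise DataError(f"severity score {name!r} missing for some samples")
        if len(v) < 3:
            raise DataError("need >= 3 scored samples for correlation")
        aligned[name] = v.to_numpy()
    x = m.values.to_numpy(dtype=float)
    nsamp = x.shape[1]
    dfree = nsamp - 2
    out = []
    warned = False
    r_all, p_all = {}, {}
    for name in names:
        y = aligned[name]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sx = np.sqrt((xc**2).sum(axis=1))
        sy = float(np.sqrt((yc**2).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / (sx * sy)
        r = np.where((sx == 0) | (sy == 0), np.nan, np.clip(r, -1.0, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(dfree / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), dfree)
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
        r_all[name], p_all[name] = r, p
        if np.isnan(r).any():
            warned = True
    if warned:
        warnings.warn(
            "some genes or scores are constant; their correlations are "
            "undefined and classified 'neither'",
            stacklevel=2,
        )
    for i, gene in enumerate(m.values.index):
        rr = {name: float(r_all[name][i]) for name in names}
        pp = {name: float(p_all[name][i]) for name in names}
        sig = {
            name: bool(np.isfinite(pp[name]) and pp[name] <= alpha)
            for name in names
        }
        out.append(SeverityCorrelation(gene=str(gene), r=rr, p=pp,
                                       klass=_classify(sig, names)))
    return out


# fixed cognitive-score bins; boundary values belong to the printed closed ranges
_SEVERITY_BINS = (
    (25, "Control"),     # score > 25
    (20, "Incipient"),   # 20..25
    (14, "Moderate"),    # 14..19
)


def severity_groups(mmse: dict | pd.Series) -> dict[str, str]:
    """Bin MMSE-like scores into Control / Incipient / Moderate / Severe."""
    out = {}
    for sample, value in pd.Series(mmse).items():
        v = float(value)
        if v > 25:
            out[str(sample)] = "Control"
        elif v >= 20:
            out[str(sample)] = "Incipient"
        elif v >= 14:
            out[str(sample)] = "Moderate"
        else:
            out[str(sample)] = "Severe"
    return out


def write_enrichment_tsv(rows: list[EnrichmentRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tk\tK\tn\tN\tp\tsignificant\n")
        for r in rows:
            fh.write(
                f"{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.10g}\t"
                f"{'yes' if r.significant else 'no'}\n"
            )


def write_correlation_tsv(rows: list[SeverityCorrelation], path) -> None:
    if not rows:
        raise DataError("no correlation rows to write")
    names = sorted(rows[0].r)
    with open(path, "w") as fh:
        cols = [f"{x}_{n}" for n in names for x in ("r", "p")]
        fh.write("gene\t" + "\t".join(cols) + "\tclass\n")
        for row in rows:
            vals = []
            for n in names:
                vals.append(f"{row.r[n]:.10g}")
                vals.append(f"{row.p[n]:.10g}")
            fh.write(f"{row.gene}\t" + "\t".join(vals) + f"\t{row.klass}\n")
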