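"""Two-group differential expression with empirical-Bayes variance moderation.

Per-gene pooled two-sample statistics are shrunk toward a common prior
variance estimated by method of moments on log sample variances (matching
the first two moments of a scaled-F / log-chi-square model).  The moderated
t-statistic gains the prior degrees of freedom; with an unbounded prior the
Gaussian tail is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from hubnet._errors import DataError, NumericalError
from hubnet.graph_io import ExpressionMatrix


@dataclass(frozen=True)
class VariancePrior:
    """Prior degrees of freedom and prior variance for moderation.

    ``d0 = math.inf`` marks an unbounded prior (complete shrinkage to
    ``s0sq``).
    """

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise NumericalError("prior df must be >= 0")
        if not (self.s0sq > 0):
            raise NumericalError("prior variance must be > 0")

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.d0)


def group_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean difference (case - control), pooled variance and df.

    Both groups need at least two samples and the matrix must be complete.
    """
    case, ctrl = m.case_control_split()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError(f"need >= 2 samples per group, got case={n1} control={n2}")
    x1 = case.to_numpy(dtype=float)
    x2 = ctrl.to_numpy(dtype=float)
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise DataError("expression matrix contains missing values; impute first")
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return pd.DataFrame(
        {"mean_diff": mean_diff, "s2": s2, "df_residual": df},
        index=m.values.index,
    )


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    out = np.full_like(y, np.inf)
    pos = y > 1e-8
    x = 0.5 + 1.0 / np.where(pos, y, 1.0)
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / np.where(pos, y, 1.0)) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-12 * np.maximum(x, 1.0)):
            break
    out[pos] = x[pos]
    return out if out.ndim else float(out)


def fit_variance_prior(s2, df_residual: int) -> VariancePrior:
    """Estimate (d0, s0sq) from the spread of log sample variances.

    Matches mean and variance of ``log s2`` (corrected for the sampling
    log-chi-square moments at ``df_residual``) to the prior's log moments.
    When the empirical spread does not exceed the sampling minimum the prior
    df is unbounded.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    pos = s2[s2 > 0]
    if pos.size < 10:
        raise DataError(f"need >= 10 genes with positive variance, got {pos.size}")
    df = float(df_residual)
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if pos.size == s2.size and np.allclose(z, z[0]):
        # degenerate zero-spread input: the common value is the prior
        return VariancePrior(math.inf, float(pos[0]))
    evar = float(e.var(ddof=1))
    evar_resid = evar - float(special.polygamma(1, df / 2.0))
    if evar_resid <= 0:
        return VariancePrior(math.inf, float(np.exp(emean)))
    d0 = 2.0 * float(_trigamma_inverse(evar_resid))
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0, s0sq)


def moderated_t(
    m: ExpressionMatrix, prior: VariancePrior | None = None
) -> pd.DataFrame:
    """Moderated two-sample t-statistics and two-sided p-values per gene.

    The posterior variance is the prior-weighted combination
    ``(d0*s0sq + df*s2) / (d0 + df)``; the reference distribution is
    Student t with ``df + d0`` degrees of freedom (Gaussian when the prior
    is unbounded).

    Returns a DataFrame with columns mean_diff, s2, df_residual, t_mod,
    df_total, p.
    """
    gs = group_stats(m)
    case, ctrl = m.case_control_split()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if prior is None:
        prior = fit_variance_prior(gs["s2"].to_numpy(), int(gs["df_residual"].iloc[0]))
    df = gs["df_residual"].to_numpy(dtype=float)
    s2 = gs["s2"].to_numpy(dtype=float)
    if prior.unbounded:
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = gs["mean_diff"].to_numpy() / se
    undefined = ~np.isfinite(t)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} genes have undefined t (zero variance and "
            f"zero prior df); p set to 1",
            stacklevel=2,
        )
        t = np.where(undefined, 0.0, t)
    if prior.unbounded:
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = gs.copy()
    out["t_mod"] = t
    out["df_total"] = df_total
    out["p"] = p
    return out


def write_de_tsv(de: pd.DataFrame, path) -> None:
    cols = ["mean_diff", "t_mod", "df_total", "p"]
    de[cols].to_csv(path, sep="\t", float_format="%.10g", index_label="gene")
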