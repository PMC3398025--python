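"""Beta-uniform mixture model of p-values and FDR-controlled node scoring.

The p-value density is modelled as ``f(x) = lam + (1 - lam) * a * x**(a-1)``
on (0, 1]: uniform noise with weight ``lam`` plus Beta(a, 1) signal.  The
fitted model gives the noise upper bound ``pi = f(1)``, a significance
threshold ``tau`` controlling the FDR among positively scored p-values, and
the per-gene score ``(a - 1) * (log x - log tau)`` — the signal/noise
log-likelihood ratio shifted to zero at ``tau``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from hubnet._errors import DataError, NumericalError

_P_FLOOR = 1e-300
_A_LO, _A_HI = 1e-6, 1.0 - 1e-6


@dataclass(frozen=True)
class BUMFit:
    """Fitted mixture: uniform weight ``lam``, beta shape ``a``."""

    lam: float
    a: float
    loglik: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise NumericalError("lam outside [0, 1]")
        if not (0.0 < self.a < 1.0):
            raise NumericalError("a outside (0, 1)")

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lam + (1.0 - self.lam) * self.a * x ** (self.a - 1.0)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lam * x + (1.0 - self.lam) * x**self.a


@dataclass(frozen=True)
class ScoreTable:
    """Per-gene scores with the threshold and FDR they derive from."""

    scores: pd.Series
    tau: float
    fdr: float

    def positive_genes(self) -> list[str]:
        return sorted(self.scores.index[self.scores > 0])


def _clamp_pvalues(pvalues: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(pvalues)):
        raise DataError("p-values contain non-finite entries")
    if (pvalues < 0).any() or (pvalues > 1).any():
        raise DataError("p-values outside [0, 1]")
    if (pvalues == 0).any():
        warnings.warn("p-values of exactly 0 clamped to 1e-300", stacklevel=3)
        pvalues = np.maximum(pvalues, _P_FLOOR)
    return pvalues


def fit_bum(pvalues) -> BUMFit:
    """Maximum-likelihood fit of the beta-uniform mixture.

    Deterministic: bounded quasi-Newton from a fixed 5 x 5 multi-start grid
    over (lam, a) in [0.05, 0.95]^2.  Needs at least 100 p-values.
    """
    p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                   dtype=float).ravel()
    if p.size < 100:
        raise DataError(f"need >= 100 p-values to fit the mixture, got {p.size}")
    p = _clamp_pvalues(p)
    p = np.sort(p)  # fixed summation order: estimates invariant to input order
    logp = np.log(p)

    def nll(theta: np.ndarray) -> float:
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        dens = np.maximum(dens, 1e-320)
        return -float(np.sum(np.log(dens)))

    starts = [(lam0, a0)
              for lam0 in np.linspace(0.05, 0.95, 5)
              for a0 in np.linspace(0.05, 0.95, 5)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0=np.array(x0), method="L-BFGS-B",
            bounds=[(0.0, 1.0), (_A_LO, _A_HI)],
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    lam, a = float(best.x[0]), float(best.x[1])
    loglik = -float(best.fun)
    # the (lam, a) surface is a ridge near the uniform density: any pair with
    # a ~ 1 or lam ~ 1 describes pure noise.  When the fit is not
    # significantly better than uniform (whose log-likelihood is exactly 0),
    # canonicalize to the lam = 1 representation.
    from scipy import stats as _stats

    if 2.0 * loglik < _stats.chi2.ppf(0.999, df=2):
        lam = 1.0
    if lam > 1.0 - 1e-9 or not (1e-4 < a < 1.0 - 1e-4):
        warnings.warn(
            f"BUM fit at parameter boundary (lam={lam:.4g}, a={a:.4g}); "
            f"the p-value collection may be pure noise or degenerate",
            stacklevel=2,
        )
    a = min(max(a, _A_LO), _A_HI)
    return BUMFit(lam=lam, a=a, loglik=loglik, n=int(p.size))


def pi_upper(fit: BUMFit) -> float:
    """Upper bound on the noise proportion: ``f(1) = lam + (1 - lam) * a``."""
    return fit.lam + (1.0 - fit.lam) * fit.a


def tau_from_fdr(fit: BUMFit, fdr: float) -> float:
    """Significance threshold controlling the FDR among positive scores.

    ``tau = ((pi - fdr*lam) / (fdr*(1 - lam))) ** (1 / (a - 1))``, strictly
    increasing in ``fdr``.
    """
    if not 0.0 < fdr < 1.0:
        raise NumericalError(f"fdr must be in (0, 1), got {fdr}")
    pi = pi_upper(fit)
    num = pi - fdr * fit.lam
    den = fdr * (1.0 - fit.lam)
    if num <= 0 or den <= 0:
        raise NumericalError("FDR not attainable under fitted model")
    ratio = num / den
    tau = ratio ** (1.0 / (fit.a - 1.0))
    if not 0.0 < tau < 1.0:
        raise NumericalError("FDR not attainable under fitted model")
    return float(tau)


def score_pvalues(fit: BUMFit, fdr: float, pvalues: pd.Series | dict) -> ScoreTable:
    """Per-gene differential-significance scores at threshold tau(fdr).

    ``score(x) = (a - 1) * (log x - log tau)``: positive iff ``x < tau``,
    zero at ``tau``.
    """
    tau = tau_from_fdr(fit, fdr)
    s = pd.Series(pvalues, dtype=float)
    vals = _clamp_pvalues(s.to_numpy())
    scores = (fit.a - 1.0) * (np.log(vals) - np.log(tau))
    return ScoreTable(scores=pd.Series(scores, index=s.index), tau=tau, fdr=float(fdr))


# log-spaced scan grid; spans the small FDRs seen in practice and extends
# moderately beyond 0.05 so weak-signal collections can approach the target
# positive fraction without flooding the scores with uniform noise
DEFAULT_FDR_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.round(10 ** np.linspace(-6, np.log10(0.3), 60), 12)
)


def choose_fdr_for_fraction(
    fit: BUMFit,
    pvalues,
    target_fraction: float = 0.10,
    grid=DEFAULT_FDR_GRID,
) -> float:
    """Scan an FDR grid; pick the one whose positive fraction is closest to target.

    Ties prefer the smaller FDR.  Grid values for which tau is not
    attainable are skipped; all skipped is an error.
    """
    if not 0.0 < target_fraction < 1.0:
        raise NumericalError("target_fraction must be in (0, 1)")
    grid = sorted(set(float(f) for f in grid))
    if not grid:
        raise NumericalError("FDR grid is empty")
    p = np.asarray(pd.Series(pvalues, dtype=float).to_numpy())
    p = _clamp_pvalues(p)
    best_fdr, best_gap = None, np.inf
    for fdr in grid:
        try:
            tau = tau_from_fdr(fit, fdr)
        except NumericalError:
            continue
        frac = float(np.mean(p < tau))
        gap = abs(frac - target_fraction)
        if gap < best_gap - 1e-15:
            best_fdr, best_gap = fdr, gap
    if best_fdr is None:
        raise NumericalError("no FDR in grid attainable under fitted model")
    return best_fdr


def qq_table(fit: BUMFit, pvalues) -> pd.DataFrame:
    """Theoretical vs observed quantiles of the fitted mixture CDF.

    Row i pairs the observed order statistic with the model quantile at
    probability (i - 0.5) / n.
    """
    p = np.sort(np.asarray(pd.Series(pvalues, dtype=float).to_numpy()))
    p = _clamp_pvalues(p)
    n = p.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = np.empty(n)
    for i, q in enumerate(probs):
        theo[i] = optimize.brentq(
            lambda x: fit.lam * x + (1.0 - fit.lam) * x**fit.a - q,
            1e-320, 1.0, xtol=1e-12,
        )
    return pd.DataFrame({"theoretical": theo, "observed": p})


def write_score_table(table: ScoreTable, fit: BUMFit, path) -> None:
    """TSV gene/score table preceded by a one-line JSON comment header."""
    import json

    header = json.dumps(
        {"lam": fit.lam, "a": fit.a, "fdr": table.fdr, "tau": table.tau},
        sort_keys=True,
    )
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("gene\tscore\n")
        for gene, score in table.scores.items():
            fh.write(f"{gene}\t{score:.10g}\n")
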