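"""Lognormal mixture decomposition of length-frequency distributions.

Annual length distributions of forage fish are multimodal because age
classes overlap in length.  A K-component lognormal mixture — a
Gaussian mixture on log-lengths — is fit by EM with quantile-seeded
multi-start initialization; size-class proportions are integrals of the
fitted mixture over length intervals (class 1 is fish < 100 mm, roughly
age-0 in summer) and are scaled by catch-per-unit-effort to give an
abundance-weighted size-structure index per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-3  # on the log scale; guards against degenerate spikes

__all__ = [
    "LognormalMixtureFit",
    "fit_lognormal_mixture",
    "component_proportions",
    "size_class_cpue",
    "bic",
    "fit_with_bic_fallback",
]


@dataclass
class LognormalMixtureFit:
    """Fitted K-component lognormal mixture, components ordered by meanlog."""

    k: int
    weights: np.ndarray
    meanlog: np.ndarray
    sdlog: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    seed: int
    n: int

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, mu, sd in zip(self.weights, self.meanlog, self.sdlog):
            out += w * stats.lognorm.pdf(x, s=sd, scale=np.exp(mu))
        return out


def _log_mixture_density(logx: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """log sum_k w_k N(logx; mu_k, sd_k) — density on the log scale."""
    comp = (
        np.log(w)[None, :]
        - 0.5 * np.log(2 * np.pi)
        - np.log(sd)[None, :]
        - 0.5 * ((logx[:, None] - mu[None, :]) / sd[None, :]) ** 2
    )
    m = comp.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(comp - m).sum(axis=1, keepdims=True))).ravel()


def _em_once(
    logx: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Run EM from one start; returns params, per-iteration loglik path,
    convergence flag.  Raises FloatingPointError on component collapse."""
    n = len(logx)
    path = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step: responsibilities
        logcomp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sd)[None, :]
            - 0.5 * ((logx[:, None] - mu[None, :]) / sd[None, :]) ** 2
        )
        m = logcomp.max(axis=1, keepdims=True)
        lse = m + np.log(np.exp(logcomp - m).sum(axis=1, keepdims=True))
        resp = np.exp(logcomp - lse)
        ll = float(lse.sum())
        path.append(ll)
        if np.isfinite(prev) and abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        # M-step: weighted moment updates
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            raise FloatingPointError("empty component")
        w = nk / n
        mu = (resp * logx[:, None]).sum(axis=0) / nk
        var = (resp * (logx[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if np.any(sd < SIGMA_FLOOR):
            raise FloatingPointError("component collapse (sdlog below floor)")
    return w, mu, sd, np.asarray(path), converged


def _quantile_init(logx: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed component means at interior quantiles of log-lengths, with
    jitter, equal weights, and a common within-slice spread."""
    qs = (np.arange(k) + 0.5) / k
    mu = np.quantile(logx, qs)
    spread = max(float(np.std(logx)) / max(k, 1), 10 * SIGMA_FLOOR)
    mu = mu + rng.normal(0.0, 0.25 * spread, size=k)
    sd = np.full(k, max(spread, 10 * SIGMA_FLOOR))
    w = np.full(k, 1.0 / k)
    return w, np.sort(mu), sd


def fit_lognormal_mixture(
    lengths: np.ndarray,
    k: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> LognormalMixtureFit:
    """Fit a K-component lognormal mixture to lengths (mm) by EM.

    The best of ``n_starts`` quantile-seeded random initializations (by
    final log-likelihood, ties to the lowest start index) is returned
    with components reordered by ascending meanlog.  Identical seed and
    data give a bit-identical fit.

    Raises ``ValueError`` on non-positive lengths and ``RuntimeError``
    when every start collapses a component below the sigma floor.
    """
    x = np.asarray(lengths, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all lengths must be positive and finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    logx = np.log(x)

    if k == 1:
        mu = np.array([logx.mean()])
        sd = np.array([max(logx.std(), SIGMA_FLOOR)])  # population convention
        ll = float(_log_mixture_density(logx, np.array([1.0]), mu, sd).sum())
        return LognormalMixtureFit(
            k=1, weights=np.array([1.0]), meanlog=mu, sdlog=sd,
            loglik=ll, loglik_path=np.array([ll]), n_iter=1,
            converged=True, seed=seed, n=len(x),
        )

    best = None
    failures = []
    for s in range(n_starts):
        rng = np.random.default_rng((seed, s))
        w0, mu0, sd0 = _quantile_init(logx, k, rng)
        try:
            w, mu, sd, path, conv = _em_once(logx, w0, mu0, sd0, tol, max_iter)
        except FloatingPointError as err:
            failures.append((s, str(err)))
            continue
        ll = float(path[-1])
        if best is None or ll > best[0] + 1e-12:
            best = (ll, w, mu, sd, path, conv, s)
    if best is None:
        raise RuntimeError(
            f"all {n_starts} EM starts collapsed (seed={seed}): {failures}"
        )
    ll, w, mu, sd, path, conv, s = best
    order = np.argsort(mu)
    return LognormalMixtureFit(
        k=k, weights=w[order], meanlog=mu[order], sdlog=sd[order],
        loglik=ll, loglik_path=path, n_iter=len(path), converged=conv,
        seed=seed, n=len(x),
    )


def bic(fit: LognormalMixtureFit) -> float:
    """Bayesian information criterion; 3K − 1 free parameters."""
    p = 3 * fit.k - 1
    return p * np.log(fit.n) - 2.0 * fit.loglik


def fit_with_bic_fallback(
    lengths: np.ndarray, k: int = 3, **kwargs
) -> LognormalMixtureFit:
    """Fit K components, falling back to K−1 when a component collapses
    or when BIC prefers the smaller model; used for years with few large
    fish."""
    try:
        fit_k = fit_lognormal_mixture(lengths, k, **kwargs)
    except RuntimeError:
        logger.info("K=%d collapsed; falling back to K=%d", k, k - 1)
        return fit_with_bic_fallback(lengths, k - 1, **kwargs) if k > 1 else None
    if k == 1:
        return fit_k
    fit_km1 = fit_lognormal_mixture(lengths, k - 1, **kwargs)
    if bic(fit_km1) < bic(fit_k):
        logger.info("BIC prefers K=%d over K=%d", k - 1, k)
        return fit_km1
    return fit_k


def component_proportions(
    fit: LognormalMixtureFit, boundaries: list[float]
) -> np.ndarray:
    """Mixture mass per size class defined by length cut points (mm).

    ``boundaries`` are interior cut points; classes partition (0, inf),
    so ``[100]`` gives two classes (< 100 mm and >= 100 mm).  The
    class proportion is

        sum_k w_k [Phi((log b_hi − mu_k)/sd_k) − Phi((log b_lo − mu_k)/sd_k)].
    """
    b = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    edges = np.concatenate([[0.0], b, [np.inf]])
    log_edges = np.log(edges, where=edges > 0, out=np.full(len(edges), -np.inf))
    props = np.zeros(len(edges) - 1)
    for w, mu, sd in zip(fit.weights, fit.meanlog, fit.sdlog):
        cdf = stats.norm.cdf((log_edges - mu) / sd)
        props += w * np.diff(cdf)
    return props


def size_class_cpue(
    props_by_year: pd.DataFrame, cpue_by_year: pd.Series
) -> pd.DataFrame:
    """Scale per-year size-class proportions by total CPUE.

    ``props_by_year`` has columns ``year, size_class, proportion``;
    returns the same with ``cpue_scaled = proportion * CPUE[year]``.
    Years missing from the CPUE table are omitted with a warning.
    """
    rows = []
    for year, grp in props_by_year.groupby("year"):
        if year not in cpue_by_year.index:
            logger.warning("year %s missing from CPUE table; omitted", year)
            continue
        cpue = float(cpue_by_year.loc[year])
        for _, r in grp.iterrows():
            rows.append(
                {
                    "year": year,
                    "size_class": r["size_class"],
                    "proportion": r["proportion"],
                    "cpue_scaled": r["proportion"] * cpue,
                }
            )
    return pd.DataFrame(rows)
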