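"""Z-REG-FDR: summary-statistic empirical-Bayes gene-level lfdr.

Model.  Each gene carries m z-statistics.  Under the gene-level null all m
are marginally N(0,1).  Under the alternative exactly one SNP (uniformly
chosen) is causal with z ~ N(mu, 1) and mu ~ N(0, sigma^2), so the causal
z's marginal is N(0, 1 + sigma^2).  The dependence among the non-causal z
given the causal one is assumed identical under null and alternative, so it
cancels from both the gene-level posterior null probability (lfdr)

    lfdr_i = 1 / (1 + (1-pi0)/pi0 * (1/m_i) * sum_k p1(z_k)/p0(z_k))

and from the pseudo-likelihood

    sum_i log( pi0 + (1-pi0) * (1/m_i) * sum_k p1(z_k)/p0(z_k) ),

which is maximized over (pi0, sigma).  Only z-statistics are needed; the
sample size and SNP dependence never enter.

All accumulation is in log space; the objective and its analytic gradient
are evaluated vectorized over the flattened ragged z array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from ._types import (
    PI0_MAX,
    PI0_MIN,
    SIGMA_MAX,
    SIGMA_MIN,
    LfdrTable,
    ModelParams,
    SummaryDataset,
)

__all__ = [
    "alt_null_ratio",
    "gene_lfdr",
    "pseudo_loglik",
    "fit_zreg",
    "lfdr_table",
    "ZregFit",
]


def alt_null_ratio(z: float | np.ndarray, sigma: float) -> float | np.ndarray:
    """Density ratio p1(z)/p0(z) of the causal-SNP marginal to the null.

    p1 is N(0, 1 + sigma^2) after integrating mu ~ N(0, sigma^2) out of
    N(mu, 1); p0 is N(0, 1).  Closed form:
    (1+sigma^2)^(-1/2) * exp(z^2 sigma^2 / (2 (1+sigma^2))).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    z = np.asarray(z, dtype=float)
    out = np.exp(_log_ratio(z, sigma))
    return float(out) if out.ndim == 0 else out


def _log_ratio(z: np.ndarray, sigma: float) -> np.ndarray:
    s2 = sigma * sigma
    return -0.5 * np.log1p(s2) + z * z * (s2 / (2.0 * (1.0 + s2)))


def _log_mean_ratio(d: SummaryDataset, sigma: float) -> np.ndarray:
    """log of the per-gene mean density ratio, stably via per-gene LSE."""
    lr = _log_ratio(d.flat_z, sigma)
    # segment logsumexp over the CSR layout
    seg_max = np.maximum.reduceat(lr, d.ptr[:-1])
    shifted = np.exp(lr - np.repeat(seg_max, d.m))
    seg_sum = np.add.reduceat(shifted, d.ptr[:-1])
    return seg_max + np.log(seg_sum) - np.log(d.m)


def gene_lfdr(zvec: np.ndarray, params: ModelParams) -> float:
    """Posterior null probability of one gene given its z vector."""
    zvec = np.asarray(zvec, dtype=float)
    if zvec.size == 0:
        raise ValueError("empty z vector")
    if params.pi0 == 0.0:
        warnings.warn("pi0 = 0: lfdr is 0 by convention")
        return 0.0
    if params.pi0 == 1.0:
        return 1.0
    lr = _log_ratio(zvec, params.sigma)
    m = zvec.size
    log_rbar = _logsumexp(lr) - np.log(m)
    log_den = np.logaddexp(np.log(params.pi0), np.log1p(-params.pi0) + log_rbar)
    return float(np.exp(np.log(params.pi0) - log_den))


def _logsumexp(a: np.ndarray) -> float:
    amax = np.max(a)
    return float(amax + np.log(np.sum(np.exp(a - amax))))


def pseudo_loglik(d: SummaryDataset, params: ModelParams) -> float:
    """Pseudo-log-likelihood sum_i log(pi0 + (1-pi0) * mean ratio)."""
    p = params
    log_rbar = _log_mean_ratio(d, p.sigma)
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(np.log(p.pi0), np.log1p(-p.pi0) + log_rbar)
    total = float(np.sum(terms))
    if not np.isfinite(total):
        bad = int(np.argmax(~np.isfinite(terms)))
        raise FloatingPointError(
            f"non-finite pseudo-log-likelihood at gene {d.gene_ids[bad]}"
        )
    return total


def _negloglik_and_grad(
    theta: np.ndarray, d: SummaryDataset
) -> tuple[float, np.ndarray]:
    """Objective and gradient on transformed coordinates (logit pi0, log sigma)."""
    pi0 = float(expit(theta[0]))
    sigma = float(np.exp(theta[1]))
    s2 = sigma * sigma
    lr = _log_ratio(d.flat_z, sigma)
    seg_max = np.maximum.reduceat(lr, d.ptr[:-1])
    shifted = np.exp(lr - np.repeat(seg_max, d.m))
    seg_sum = np.add.reduceat(shifted, d.ptr[:-1])
    log_rbar = seg_max + np.log(seg_sum) - np.log(d.m)

    log_pi0 = np.log(pi0)
    log_1mpi0 = np.log1p(-pi0)
    log_den = np.logaddexp(log_pi0, log_1mpi0 + log_rbar)
    ll = float(np.sum(log_den))

    # A_i = (1-pi0) Rbar_i / D_i in (0,1)
    A = np.exp(log_1mpi0 + log_rbar - log_den)
    # d ll / d pi0 = sum (1 - Rbar_i)/D_i
    dpi0 = float(np.sum(np.exp(-log_den)) - np.sum(A) / (1.0 - pi0))
    # weighted mean of z^2 under the ratio weights, per gene
    z2w = np.add.reduceat(shifted * d.flat_z**2, d.ptr[:-1]) / seg_sum
    dsigma = float(
        np.sum(A * (-sigma / (1.0 + s2) + z2w * sigma / (1.0 + s2) ** 2))
    )
    # chain rule to transformed coordinates
    g = np.array(
        [dpi0 * pi0 * (1.0 - pi0), dsigma * sigma],
        dtype=float,
    )
    return -ll, -g


def _moment_start(d: SummaryDataset) -> ModelParams:
    """Method-of-moments start from the |z| > 2 exceedance fraction.

    Under the mixture, the fraction of all z with |z| > 2 is
    p0 + (1-pi0)/mbar * (pa(sigma) - p0) with p0 = 2 Phi(-2) and
    pa = 2 Phi(-2/sqrt(1+sigma^2)); the mean z^2 is
    1 + (1-pi0) sigma^2 / mbar.  One alternating pass gives a crude but
    well-scaled start.
    """
    z = d.flat_z
    mbar = float(np.mean(d.m))
    p_hat = float(np.mean(np.abs(z) > 2.0))
    z2bar = float(np.mean(z * z))
    p0 = 2.0 * norm.cdf(-2.0)
    sigma = 3.0
    pi0 = 0.5
    for _ in range(2):
        pa = 2.0 * norm.cdf(-2.0 / np.sqrt(1.0 + sigma * sigma))
        denom = max(pa - p0, 1e-8)
        pi0 = float(np.clip(1.0 - mbar * (p_hat - p0) / denom, 0.05, 0.95))
        s2 = mbar * max(z2bar - 1.0, 0.0) / max(1.0 - pi0, 1e-3)
        sigma = float(np.clip(np.sqrt(s2), 0.5, SIGMA_MAX))
    return ModelParams(pi0=pi0, sigma=sigma).clipped()


@dataclass
class ZregFit:
    """Result of a Z-REG-FDR fit."""

    params: ModelParams
    loglik: float
    converged: bool
    grad_norm: float
    n_starts: int
    message: str = ""

    @property
    def pi0(self) -> float:
        return self.params.pi0

    @property
    def sigma(self) -> float:
        return self.params.sigma


_DEFAULT_STARTS = (ModelParams(0.5, 1.0), ModelParams(0.5, 3.0))


def fit_zreg(
    d: SummaryDataset,
    starts: tuple[ModelParams, ...] | None = None,
    tol: float = 1e-9,
) -> ZregFit:
    """Maximize the pseudo-log-likelihood over (pi0, sigma).

    Box-constrained quasi-Newton (L-BFGS-B) on transformed coordinates
    (logit pi0, log sigma) with the analytic gradient, from multiple starts:
    the supplied/default grid plus a method-of-moments start.  The best
    converged optimum wins.
    """
    if starts is None:
        starts = _DEFAULT_STARTS + (_moment_start(d),)
    if len(starts) == 0:
        raise ValueError("at least one start is required")
    bounds = [
        (float(logit(PI0_MIN)), float(logit(PI0_MAX))),
        (float(np.log(SIGMA_MIN)), float(np.log(SIGMA_MAX))),
    ]
    best = None
    any_converged = False
    messages = []
    for s0 in starts:
        p = s0.clipped()
        x0 = np.array([logit(p.pi0), np.log(p.sigma)])
        res = minimize(
            _negloglik_and_grad,
            x0,
            args=(d,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        messages.append(str(res.message))
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise RuntimeError(
            "no start converged; optimizer diagnostics: " + "; ".join(messages)
        )
    pi0 = float(expit(best.x[0]))
    sigma = float(np.exp(best.x[1]))
    if sigma <= SIGMA_MIN * (1.0 + 1e-6):
        warnings.warn(
            "sigma estimate on the lower boundary: effect-size signal "
            "indistinguishable from null"
        )
    grad_norm = float(np.linalg.norm(best.jac))
    return ZregFit(
        params=ModelParams(pi0=pi0, sigma=sigma),
        loglik=-float(best.fun),
        converged=bool(best.success),
        grad_norm=grad_norm,
        n_starts=len(starts),
        message=str(best.message),
    )


def lfdr_table(d: SummaryDataset, params: ModelParams) -> LfdrTable:
    """Gene-level lfdr for every gene in the dataset (vectorized)."""
    p = params
    if p.pi0 == 0.0:
        warnings.warn("pi0 = 0: all lfdr are 0 by convention")
        lf = np.zeros(d.n_genes)
    elif p.pi0 == 1.0:
        lf = np.ones(d.n_genes)
    else:
        log_rbar = _log_mean_ratio(d, p.sigma)
        log_den = np.logaddexp(np.log(p.pi0), np.log1p(-p.pi0) + log_rbar)
        lf = np.exp(np.log(p.pi0) - log_den)
    return LfdrTable(gene_ids=list(d.gene_ids), lfdr=lf, params=p, method="zreg")
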