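"""Gene-level decision procedures.

The primary rule is adaptive lfdr thresholding: reject the L genes with the
smallest posterior null probabilities, where L is the largest prefix whose
mean lfdr stays at or below the target FDR level.  The mean lfdr among the
rejected genes is itself the estimated FDR of the rejection set, so the
rule spends exactly the available FDR budget.

Competitor gene-level pipelines are included for benchmarking: Bonferroni
and Simes combination of within-gene p-values, the permutation min-p
("eGene") statistic, and Storey's q-value for the final FDR step.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy.stats import norm

from ._types import DiscoverySet

__all__ = [
    "adaptive_threshold",
    "bonferroni_gene_p",
    "simes_gene_p",
    "permutation_minp",
    "storey_qvalue",
    "calibrated_alpha",
]


def adaptive_threshold(lfdrs: np.ndarray, alpha: float) -> DiscoverySet:
    """Largest prefix of ascending lfdrs whose running mean is <= alpha."""
    lfdrs = np.asarray(lfdrs, dtype=float)
    if np.any(~np.isfinite(lfdrs)) or np.any((lfdrs < 0) | (lfdrs > 1)):
        raise ValueError("lfdr values must be finite and in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    order = np.argsort(lfdrs, kind="stable")
    running_mean = np.cumsum(lfdrs[order]) / np.arange(1, lfdrs.size + 1)
    ok = np.flatnonzero(running_mean <= alpha)
    if ok.size == 0:
        return DiscoverySet(alpha=alpha, rejected=np.empty(0, dtype=np.int64), est_fdr=0.0)
    L = int(ok[-1]) + 1
    return DiscoverySet(
        alpha=alpha,
        rejected=np.sort(order[:L]),
        est_fdr=float(running_mean[L - 1]),
    )


def bonferroni_gene_p(pvec: np.ndarray) -> float:
    """Bonferroni gene-level p: min(1, m * min p)."""
    pvec = np.asarray(pvec, dtype=float)
    return float(min(1.0, pvec.size * pvec.min()))


def simes_gene_p(pvec: np.ndarray) -> float:
    """Simes gene-level p: min_j m * p_(j) / j over ascending p_(j)."""
    p = np.sort(np.asarray(pvec, dtype=float))
    m = p.size
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * norm.sf(np.abs(z))


def permutation_minp(
    d, B: int = 1000, seed: int = 0, n_min_resolution: int = 100
) -> np.ndarray:
    """Permutation min-p gene-level p-values from a full dataset.

    The test statistic per gene is the smallest two-sided normal p-value of
    its Fisher-scaled z-statistics; the null distribution comes from B
    permutations of the expression sample labels.  One shared permutation
    stream is applied across genes (standard eGene practice; genes remain
    exchangeable because the statistic is computed per gene).  p-values use
    the add-one convention (1 + #{perm <= obs}) / (B + 1) and so are never 0.
    """
    from ._types import FullDataset  # local import to avoid cycle at module load

    if not isinstance(d, FullDataset):
        raise TypeError("permutation_minp needs a FullDataset")
    if B < n_min_resolution:
        warnings.warn(
            f"B={B} permutations give at best p-resolution 1/{B + 1}; "
            "thousands of simultaneous tests generally need far more "
            "(even 10,000 permutations may not suffice)"
        )
    n = d.n_samples
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(B)])
    scale = np.sqrt(n - 3.0)

    def _std_rows(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = np.sqrt(np.mean(Mc**2, axis=1, keepdims=True))
        sd[sd == 0] = 1.0
        return Mc / sd

    out = np.empty(d.n_genes)
    clip = 1.0 - 1e-12
    for i in range(d.n_genes):
        y = _std_rows(d.expression[i : i + 1])[0]
        X = _std_rows(d.genotype_groups[i])
        r_obs = np.clip(X @ y / n, -clip, clip)
        obs = _two_sided_p(scale * np.arctanh(r_obs)).min()
        r_perm = np.clip(X @ y[perms].T / n, -clip, clip)  # (m, B)
        perm_stat = _two_sided_p(scale * np.arctanh(r_perm)).min(axis=0)
        out[i] = (1.0 + np.sum(perm_stat <= obs)) / (B + 1.0)
    return out


def storey_qvalue(
    pvec: np.ndarray, lam: float = 0.5
) -> tuple[float, np.ndarray]:
    """Storey's q-values with a fixed-lambda pi0 estimate.

    pi0_hat = min(1, #{p > lambda} / (N (1 - lambda))); q-values are the
    pi0-scaled step-up adjusted p-values, enforced monotone in rank.
    """
    p = np.asarray(pvec, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must be in (0, 1)")
    N = p.size
    pi0_hat = min(1.0, np.sum(p > lam) / (N * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * N / np.arange(1, N + 1)
    q_sorted = pi0_hat * np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(N)
    q[order] = np.minimum(q_sorted, 1.0)
    return float(pi0_hat), q


def calibrated_alpha(
    fdp_at: Callable[[float], float],
    target: float = 0.05,
    tol: float = 0.002,
    max_iter: int = 40,
) -> float:
    """Nominal level whose mean realized FDP equals the target.

    ``fdp_at(alpha)`` must return the mean realized false discovery
    proportion across replicates when the procedure is run at nominal level
    alpha (precompute per-replicate lfdr vectors and truths; rejection at a
    new alpha is then cheap).  Bisection exploits monotonicity of the mean
    FDP in the nominal level.
    """
    lo, hi = 1e-6, target
    if fdp_at(target) <= target + tol:
        return target
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = fdp_at(mid)
        if abs(f - target) <= tol:
            return mid
        if f > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
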