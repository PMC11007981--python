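"""Simulation engines with the statistical structure the model assumes.

Two schemes are provided:

* ``simulate_z_ar1`` draws per-gene z-statistic vectors directly.  Null
  genes follow a stationary AR(1) Gaussian chain with N(0,1) margins and
  lag-1 correlation rho.  Alternative genes place a causal SNP uniformly,
  draw its z from N(mu, 1) with mu ~ N(0, sigma^2), and extend left and
  right using the *null* Markov kernel z_{j+-1} | z_j ~ N(rho z_j, 1-rho^2),
  so the conditional law of the non-causal statistics given the causal one
  is exactly the null law (the model's key conditional-independence
  assumption holds by construction).

* ``simulate_genotypes`` + ``simulate_expression`` build a full dataset:
  LD-correlated dosages from a latent-Gaussian AR(1) haplotype model with
  Hardy-Weinberg margins, then gene expression from the causal-SNP
  regression N(beta X_k, 1 - beta^2) with the Fisher-scale random effect
  sqrt(n-3) atanh(beta) ~ N(0, sigma^2); null genes are i.i.d. N(0,1).

``pi0`` is the probability that a gene has NO eQTL throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._types import FullDataset, SimTruth, SummaryDataset

__all__ = [
    "SimConfig",
    "simulate_z_ar1",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_full",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for both simulation schemes.

    N : number of genes.
    m : SNPs per gene (constant), or the string "uniform" for
        m_i ~ UniformInt(m_low, m_high).
    n : sample size (used by the expression scheme; carried through by the
        z scheme for interface consistency only).
    pi0 : probability that a gene has no eQTL.
    sigma : SD of the Fisher-scale random effect.
    rho : AR(1) lag-1 correlation of z-statistics (z scheme) or of the
        latent haplotype field across SNPs (genotype scheme).
    maf_range : interval of minor allele frequencies for simulated SNPs.
    seed : RNG seed.
    """

    N: int = 10_000
    m: int | str = 30
    n: int = 200
    pi0: float = 0.2
    sigma: float = 5.0
    rho: float = 0.1
    maf_range: tuple[float, float] = (0.1, 0.5)
    m_low: int = 10
    m_high: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not (abs(self.rho) < 1):
            raise ValueError("|rho| must be < 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.N < 1 or self.n < 4:
            raise ValueError("need N >= 1 genes and n >= 4 samples")
        if isinstance(self.m, int) and self.m < 1:
            raise ValueError("m must be >= 1")


def _draw_m(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.m, int):
        return np.full(cfg.N, cfg.m, dtype=np.int64)
    if cfg.m == "uniform":
        return rng.integers(cfg.m_low, cfg.m_high + 1, size=cfg.N)
    raise ValueError(f"unrecognized m spec: {cfg.m!r}")


def _draw_truth(cfg: SimConfig, m: np.ndarray, rng: np.random.Generator) -> SimTruth:
    is_null = rng.random(cfg.N) < cfg.pi0
    causal = np.full(cfg.N, -1, dtype=np.int64)
    alt = ~is_null
    causal[alt] = (rng.random(alt.sum()) * m[alt]).astype(np.int64)
    effect = np.full(cfg.N, np.nan)
    effect[alt] = rng.normal(0.0, cfg.sigma, size=alt.sum())
    return SimTruth(is_null=is_null, causal_index=causal, effect=effect)


def _ar1_block(
    z0: np.ndarray, k: np.ndarray, m: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Extend anchor values z0 at positions k to full AR(1) rows of width m.

    The same symmetric stationary kernel generates both directions; for a
    reversible AR(1) chain conditioning on any interior anchor and growing
    outward reproduces the stationary joint law.
    """
    G = z0.shape[0]
    z = np.empty((G, m))
    z[np.arange(G), k] = z0
    sd = np.sqrt(1.0 - rho * rho)
    # forward pass: fill j from the left neighbor where j > k
    for j in range(1, m):
        mask = k < j
        if np.any(mask):
            z[mask, j] = rho * z[mask, j - 1] + sd * rng.normal(size=mask.sum())
    # backward pass: fill j from the right neighbor where j < k
    for j in range(m - 2, -1, -1):
        mask = k > j
        if np.any(mask):
            z[mask, j] = rho * z[mask, j + 1] + sd * rng.normal(size=mask.sum())
    return z


def simulate_z_ar1(cfg: SimConfig) -> tuple[SummaryDataset, SimTruth]:
    """Directly simulated per-gene z vectors with AR(1) serial correlation."""
    rng = np.random.default_rng(cfg.seed)
    m = _draw_m(cfg, rng)
    truth = _draw_truth(cfg, m, rng)
    # anchor: null genes start the chain at position 0 with N(0,1);
    # alt genes anchor the causal position at N(mu, 1).
    anchor_pos = np.where(truth.is_null, 0, truth.causal_index)
    anchor_mean = np.where(truth.is_null, 0.0, np.nan_to_num(truth.effect))
    anchor = anchor_mean + rng.normal(size=cfg.N)

    z_list: list[np.ndarray] = [np.empty(0)] * cfg.N
    for mv in np.unique(m):
        idx = np.flatnonzero(m == mv)
        block = _ar1_block(anchor[idx], anchor_pos[idx], int(mv), cfg.rho, rng)
        for row, i in enumerate(idx):
            z_list[i] = block[row]
    d = SummaryDataset(z_list, n=cfg.n)
    return d, truth


def simulate_genotypes(cfg: SimConfig) -> list[np.ndarray]:
    """LD-correlated dosage matrices, one (m_i, n) block per gene.

    Two latent Gaussian haplotype fields per sample follow an AR(1) chain
    with correlation rho across the m SNP positions; each SNP's allele
    indicator thresholds its latent value at the quantile of a MAF drawn
    uniformly from ``maf_range``.  Dosage = sum of the two haplotypes, so
    margins are Binomial(2, maf) (Hardy-Weinberg) with LD decaying in
    |position difference|.  SNPs that come out monomorphic are redrawn
    marginally (LD with neighbors is sacrificed for those rare columns).
    """
    rng = np.random.default_rng(cfg.seed)
    m = _draw_m(cfg, rng)
    out: list[np.ndarray] = []
    sd = np.sqrt(1.0 - cfg.rho * cfg.rho)
    lo, hi = cfg.maf_range
    for mi in m:
        mi = int(mi)
        lat = np.empty((2, cfg.n, mi))
        lat[:, :, 0] = rng.normal(size=(2, cfg.n))
        for j in range(1, mi):
            lat[:, :, j] = cfg.rho * lat[:, :, j - 1] + sd * rng.normal(
                size=(2, cfg.n)
            )
        maf = rng.uniform(lo, hi, size=mi)
        thresh = norm.ppf(maf)
        dos = (lat < thresh).sum(axis=0).T.astype(float)  # (mi, n)
        mono = dos.std(axis=1) == 0
        while np.any(mono):
            k = int(mono.sum())
            dos[mono] = rng.binomial(2, maf[mono][:, None], size=(k, cfg.n)).astype(
                float
            )
            mono = dos.std(axis=1) == 0
        out.append(dos)
    return out


def simulate_expression(
    genotypes: list[np.ndarray], cfg: SimConfig
) -> tuple[FullDataset, SimTruth]:
    """Expression matrix conditioned on genotypes, per the causal-SNP model.

    Per gene: Bernoulli draw of the null state (P(null) = pi0); if
    alternative, a causal SNP k is uniform over the gene's SNPs, the effect
    beta satisfies sqrt(n-3) atanh(beta) ~ N(0, sigma^2), and each sample's
    expression is N(beta x_k, 1 - beta^2) with x_k the standardized dosage.
    Null genes are i.i.d. N(0, 1).  The unconditional variance is 1 either
    way.
    """
    # use an independent stream from the genotype draw
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    N = len(genotypes)
    if N != cfg.N:
        raise ValueError("genotype list length disagrees with cfg.N")
    n = cfg.n
    m = np.array([g.shape[0] for g in genotypes], dtype=np.int64)
    truth = _draw_truth(cfg, m, rng)
    scale = np.sqrt(n - 3.0)
    Y = rng.normal(size=(N, n))
    beta_all = np.full(N, np.nan)
    for i in range(N):
        if truth.is_null[i]:
            continue
        k = truth.causal_index[i]
        beta = np.tanh(truth.effect[i] / scale)
        beta_all[i] = beta
        x = genotypes[i][k]
        xs = (x - x.mean()) / x.std()
        Y[i] = beta * xs + np.sqrt(1.0 - beta * beta) * Y[i]
    truth = SimTruth(
        is_null=truth.is_null, causal_index=truth.causal_index, effect=beta_all
    )
    d = FullDataset(expression=Y, genotype_groups=genotypes)
    return d, truth


def simulate_full(cfg: SimConfig) -> tuple[FullDataset, SimTruth]:
    """Convenience: genotypes then genotype-conditioned expression."""
    return simulate_expression(simulate_genotypes(cfg), cfg)
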