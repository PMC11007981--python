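"""Core data containers shared across the package.

The central objects are grouped collections of gene-level data: each gene
carries a ragged vector of per-SNP quantities (z-statistics or sufficient
statistics), and model fits are summarized by the two parameters of the
empirical-Bayes mixture: ``pi0``, the prior probability that a gene has no
eQTL, and ``sigma``, the standard deviation of the Fisher-scale random
effect governing causal effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Box constraints for the mixture parameters.  pi0 is kept strictly inside
# (0, 1) so that logits and log-odds are finite; sigma's upper bound is far
# above any effect-size SD seen in eQTL practice.
PI0_MIN = 1e-6
PI0_MAX = 1.0 - 1e-6
SIGMA_MIN = 1e-4
SIGMA_MAX = 50.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-group mixture: (pi0, sigma).

    pi0 : prior null probability P(no eQTL for a gene), in [0, 1].
    sigma : SD of the random effect mu on the Fisher-z scale
        (equivalently of sqrt(n-3) * atanh(beta)); non-negative.
    """

    pi0: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def clipped(self) -> "ModelParams":
        """Return a copy with both parameters inside the fitting box."""
        return ModelParams(
            pi0=float(np.clip(self.pi0, PI0_MIN, PI0_MAX)),
            sigma=float(np.clip(self.sigma, SIGMA_MIN, SIGMA_MAX)),
        )


class SummaryDataset:
    """Per-gene ragged vectors of Fisher-scaled z-statistics.

    Parameters
    ----------
    z : sequence of 1-D arrays
        ``z[i]`` holds the ``m_i`` z-statistics of gene ``i``.
    n : int or None
        Sample size used in the sqrt(n-3) scaling (None when z were supplied
        directly rather than computed from correlations).
    gene_ids, snp_ids : labels; generated if omitted.
    """

    def __init__(
        self,
        z: Sequence[np.ndarray],
        n: int | None = None,
        gene_ids: Sequence[str] | None = None,
        snp_ids: Sequence[Sequence[str]] | None = None,
    ) -> None:
        if len(z) == 0:
            raise ValueError("SummaryDataset requires at least one gene")
        self.z = [np.asarray(v, dtype=float) for v in z]
        for i, v in enumerate(self.z):
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"gene {i}: z vector must be 1-D and non-empty")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"gene {i}: non-finite z value")
        if n is not None and n < 4:
            raise ValueError("n must be >= 4 when z derive from correlations")
        self.n = n
        self.gene_ids = (
            list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(len(z))]
        )
        if len(self.gene_ids) != len(self.z):
            raise ValueError("gene_ids length mismatch")
        if snp_ids is not None:
            self.snp_ids = [list(s) for s in snp_ids]
            for v, s in zip(self.z, self.snp_ids):
                if len(s) != v.size:
                    raise ValueError("snp_ids shape mismatch")
        else:
            self.snp_ids = [
                [f"{g}_s{j}" for j in range(v.size)]
                for g, v in zip(self.gene_ids, self.z)
            ]
        # Flattened CSR-like view used by the vectorized likelihood code.
        self.m = np.array([v.size for v in self.z], dtype=np.int64)
        self.flat_z = np.concatenate(self.z) if len(self.z) > 1 else self.z[0].copy()
        self.ptr = np.zeros(len(self.z) + 1, dtype=np.int64)
        np.cumsum(self.m, out=self.ptr[1:])

    @property
    def n_genes(self) -> int:
        return len(self.z)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SummaryDataset(n_genes={self.n_genes}, "
            f"total_snps={self.flat_z.size}, n={self.n})"
        )


class FullDataset:
    """Expression matrix with per-gene genotype groups and covariates.

    expression : (N, n) array, one row per gene.
    genotype_groups : list of N arrays, the i-th of shape (m_i, n).
    covariates : (c, n) array, possibly with zero rows.
    """

    def __init__(
        self,
        expression: np.ndarray,
        genotype_groups: Sequence[np.ndarray],
        covariates: np.ndarray | None = None,
        gene_ids: Sequence[str] | None = None,
        snp_ids: Sequence[Sequence[str]] | None = None,
    ) -> None:
        self.expression = np.asarray(expression, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D (genes x samples) array")
        n_genes, n = self.expression.shape
        if len(genotype_groups) != n_genes:
            raise ValueError("one genotype group is required per gene")
        self.genotype_groups = [np.asarray(g, dtype=float) for g in genotype_groups]
        for i, g in enumerate(self.genotype_groups):
            if g.ndim != 2 or g.shape[1] != n:
                raise ValueError(f"gene {i}: genotype matrix must be (m_i, {n})")
            if g.shape[0] < 1:
                raise ValueError(f"gene {i}: needs at least one SNP")
        if covariates is None:
            covariates = np.empty((0, n))
        self.covariates = np.asarray(covariates, dtype=float)
        if self.covariates.ndim != 2 or self.covariates.shape[1] != n:
            raise ValueError(f"covariates must be (c, {n})")
        self.gene_ids = (
            list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_genes)]
        )
        if snp_ids is not None:
            self.snp_ids = [list(s) for s in snp_ids]
        else:
            self.snp_ids = [
                [f"{g}_s{j}" for j in range(grp.shape[0])]
                for g, grp in zip(self.gene_ids, self.genotype_groups)
            ]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class LfdrTable:
    """Per-gene local false discovery rates with fit provenance."""

    gene_ids: list[str]
    lfdr: np.ndarray
    params: ModelParams
    method: str  # "zreg" | "reg"

    def __post_init__(self) -> None:
        self.lfdr = np.asarray(self.lfdr, dtype=float)
        if len(self.gene_ids) != self.lfdr.size:
            raise ValueError("gene_ids / lfdr length mismatch")
        if not np.all(np.isfinite(self.lfdr)):
            raise ValueError("non-finite lfdr")
        if np.any((self.lfdr < 0) | (self.lfdr > 1)):
            raise ValueError("lfdr outside [0, 1]")


@dataclass
class DiscoverySet:
    """Result of a gene-level rejection procedure at target FDR alpha."""

    alpha: float
    rejected: np.ndarray  # sorted gene indices
    est_fdr: float
    method: str = "lfdr-adaptive"

    @property
    def L(self) -> int:
        return int(self.rejected.size)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for FDP/power scoring.

    causal_index and effect are -1 / nan for null genes.
    """

    is_null: np.ndarray
    causal_index: np.ndarray
    effect: np.ndarray  # mu (z scheme) or beta (expression scheme)

    def __post_init__(self) -> None:
        self.is_null = np.asarray(self.is_null, dtype=bool)
        self.causal_index = np.asarray(self.causal_index, dtype=np.int64)
        self.effect = np.asarray(self.effect, dtype=float)

    @property
    def n_null(self) -> int:
        return int(self.is_null.sum())

    @property
    def n_alt(self) -> int:
        return int((~self.is_null).sum())
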