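"""From expression/genotype/covariate matrices to per-gene z-statistics.

The association statistic for a gene-SNP pair is the Fisher-transformed and
scaled sample correlation z = sqrt(n-3) * atanh(r), computed after both
expression and genotypes have been residualized on the same covariates
(equivalent to a partial correlation).  Under the per-pair null, z is
approximately N(0, 1); under the alternative its mean is the Fisher-scale
effect size.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._types import FullDataset, SummaryDataset

__all__ = ["residualize", "fisher_z", "compute_summary"]


def residualize(M: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of each row of ``M`` on [intercept; C].

    Parameters
    ----------
    M : (k, n) array of responses, one per row.
    C : (c, n) covariate matrix or None/empty for intercept-only centering.

    Returns
    -------
    (k, n) array of residuals; every row has mean zero.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    n = M.shape[1]
    if C is None or np.size(C) == 0:
        return M - M.mean(axis=1, keepdims=True)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != n:
        raise ValueError("covariates and data disagree on sample count")
    c = C.shape[0]
    if n <= c + 1:
        raise ValueError(f"need n > c+1 samples to residualize (n={n}, c={c})")
    design = np.vstack([np.ones(n), C]).T  # (n, c+1)
    rank = np.linalg.matrix_rank(design)
    if rank < c + 1:
        # identify offending rows by incremental rank
        bad = []
        acc = design[:, :1]
        for j in range(1, c + 1):
            cand = np.hstack([acc, design[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(j - 1)
            else:
                acc = cand
        raise ValueError(
            f"rank-deficient covariate design; collinear covariate rows: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, M.T, rcond=None)
    return M - (design @ coef).T


def fisher_z(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Fisher-transformed, scaled correlation: sqrt(n-3) * atanh(r).

    Variance-stabilizing: the result is approximately N(0,1) under the null
    for any population correlation of zero, and its mean under the
    alternative does not depend (to first order) on the true correlation's
    sampling variance.
    """
    if n < 4:
        raise ValueError("fisher_z requires n >= 4")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1: perfect correlation cannot be transformed")
    out = np.sqrt(n - 3.0) * np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _standardize_rows(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows to unit population variance; flag constant rows."""
    Mc = M - M.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.mean(Mc**2, axis=1))
    ok = sd > 0
    Mc[ok] /= sd[ok, None]
    return Mc, ok


def compute_summary(d: FullDataset) -> SummaryDataset:
    """Compute the per-gene z-statistic vectors of a full dataset.

    Expression and genotype rows are residualized on the dataset's
    covariates, then Pearson-correlated, then Fisher-transformed with the
    sqrt(n-3) scaling.  Constant expression rows cause the gene to be
    dropped (with a warning); SNPs with |r| = 1 are dropped likewise.
    """
    n = d.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    Y = residualize(d.expression, d.covariates)
    Ys, y_ok = _standardize_rows(Y)

    z_list: list[np.ndarray] = []
    gene_ids: list[str] = []
    snp_ids: list[list[str]] = []
    for i in range(d.n_genes):
        if not y_ok[i]:
            warnings.warn(
                f"gene {d.gene_ids[i]}: constant expression after "
                "residualization; dropped"
            )
            continue
        X = residualize(d.genotype_groups[i], d.covariates)
        Xs, x_ok = _standardize_rows(X)
        if not np.all(x_ok):
            warnings.warn(
                f"gene {d.gene_ids[i]}: {int((~x_ok).sum())} monomorphic "
                "SNP(s) dropped"
            )
        r = Xs[x_ok] @ Ys[i] / n
        # guard against roundoff pushing |r| to 1
        sat = np.abs(r) >= 1.0 - 1e-12
        if np.any(sat):
            warnings.warn(
                f"gene {d.gene_ids[i]}: {int(sat.sum())} SNP(s) with |r|=1 dropped"
            )
        keep = ~sat
        if not np.any(keep):
            warnings.warn(f"gene {d.gene_ids[i]}: no usable SNPs; gene dropped")
            continue
        z_list.append(fisher_z(r[keep], n))
        gene_ids.append(d.gene_ids[i])
        kept_ids = [s for s, k in zip(np.array(d.snp_ids[i])[x_ok], keep) if k]
        snp_ids.append(list(kept_ids))
    if not z_list:
        raise ValueError("no genes survived filtering")
    return SummaryDataset(z_list, n=n, gene_ids=gene_ids, snp_ids=snp_ids)
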