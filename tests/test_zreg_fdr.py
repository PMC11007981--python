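import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from groupfdr._types import ModelParams, SummaryDataset
from groupfdr.synthetic_data import SimConfig, simulate_z_ar1
from groupfdr.zreg_fdr import (
    alt_null_ratio,
    fit_zreg,
    gene_lfdr,
    lfdr_table,
    pseudo_loglik,
)


def quadrature_ratio(z: float, sigma: float) -> float:
    """Independent oracle: numeric mu-integral of phi(z-mu) phi(mu/sigma)/sigma."""
    if sigma == 0:
        return 1.0
    # the integrand in mu is Gaussian with mean z*sigma^2/(1+sigma^2) and
    # sd sigma/sqrt(1+sigma^2); integrate a generous window around it
    peak = z * sigma**2 / (1 + sigma**2)
    s = sigma / np.sqrt(1 + sigma**2)
    num, _ = quad(
        lambda mu: norm.pdf(z - mu) * norm.pdf(mu / sigma) / sigma,
        peak - 14 * s,
        peak + 14 * s,
        limit=400,
    )
    return num / norm.pdf(z)


class TestAltNullRatio:
    def test_sigma_zero_is_identity(self):
        for z in (-3.0, 0.0, 1.7):
            assert alt_null_ratio(z, 0.0) == 1.0

    def test_known_values(self):
        assert alt_null_ratio(0.0, 1.0) == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert alt_null_ratio(3.0, 2.0) == pytest.approx(
            np.exp(3.6) / np.sqrt(5), rel=1e-12
        )

    def test_matches_quadrature_oracle_on_grid(self):
        zs = np.linspace(-10, 10, 21)
        for sigma in (0.1, 1.0, 2.0, 5.0, 10.0):
            for z in zs:
                expect = quadrature_ratio(float(z), sigma)
                assert alt_null_ratio(float(z), sigma) == pytest.approx(
                    expect, rel=1e-8
                )

    def test_symmetric_in_z(self):
        z = np.linspace(0, 8, 17)
        assert np.allclose(alt_null_ratio(z, 2.5), alt_null_ratio(-z, 2.5))


class TestGeneLfdr:
    def test_pi0_one_gives_one(self):
        assert gene_lfdr(np.array([5.0, -2.0]), ModelParams(1.0, 3.0)) == 1.0

    def test_known_value(self):
        val = gene_lfdr(np.array([0.0]), ModelParams(0.5, 1.0))
        assert val == pytest.approx(1 / (1 + 1 / np.sqrt(2)), rel=1e-10)

    def test_sigma_zero_returns_pi0(self):
        assert gene_lfdr(np.array([1.0, 2.0]), ModelParams(0.5, 0.0)) == pytest.approx(
            0.5
        )

    def test_matches_direct_bayes_posterior_m1(self, rng):
        """m=1: the group lfdr is the plain two-group posterior (oracle)."""
        for z in rng.normal(scale=3, size=20):
            p = ModelParams(0.3, 2.0)
            f0 = norm.pdf(z)
            f1 = norm.pdf(z, scale=np.sqrt(1 + p.sigma**2))
            oracle = p.pi0 * f0 / (p.pi0 * f0 + (1 - p.pi0) * f1)
            assert gene_lfdr(np.array([z]), p) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_decreasing_in_abs_z(self):
        p = ModelParams(0.5, 2.0)
        vals = [gene_lfdr(np.array([z, 0.5]), p) for z in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) < 0)

    def test_empty_vector_error(self):
        with pytest.raises(ValueError):
            gene_lfdr(np.array([]), ModelParams(0.5, 1.0))


class TestPseudoLoglik:
    def test_single_gene_hand_value(self):
        d = SummaryDataset([np.array([0.0])])
        val = pseudo_loglik(d, ModelParams(0.5, 1.0))
        assert val == pytest.approx(np.log(0.5 + 0.5 / np.sqrt(2)), rel=1e-12)

    def test_sigma_zero_is_zero(self):
        d = SummaryDataset([np.array([1.0, -2.0]), np.array([0.3])])
        # ratio == 1 identically, hence each term log(1) = 0
        assert pseudo_loglik(d, ModelParams(0.3, 0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_loop_oracle(self, rng):
        z = [rng.normal(size=m) for m in (3, 1, 5)]
        d = SummaryDataset(z)
        p = ModelParams(0.4, 2.5)
        expected = 0.0
        for zv in z:
            ratios = [
                norm.pdf(x, scale=np.sqrt(1 + p.sigma**2)) / norm.pdf(x) for x in zv
            ]
            expected += np.log(p.pi0 + (1 - p.pi0) * np.mean(ratios))
        assert pseudo_loglik(d, p) == pytest.approx(expected, abs=1e-12)


class TestFitZreg:
    def test_all_null_hits_boundary(self):
        cfg = SimConfig(N=3000, m=5, pi0=1.0, sigma=3.0, rho=0.0, seed=5)
        d, _ = simulate_z_ar1(cfg)
        with pytest.warns(UserWarning, match="boundary|indistinguishable"):
            fit = fit_zreg(d)
        # degenerate mixture: sigma at lower bound or pi0 at upper bound
        assert fit.sigma < 0.05 or fit.pi0 > 0.99
        assert abs(fit.loglik) < 50.0

    def test_recovers_truth(self, small_z_dataset):
        cfg, d, _ = small_z_dataset
        fit = fit_zreg(d)
        assert fit.converged
        assert fit.pi0 == pytest.approx(cfg.pi0, abs=0.06)
        assert fit.sigma == pytest.approx(cfg.sigma, rel=0.08)

    def test_consistency_independent_snps(self):
        """N=50,000 independent-SNP fit lands within tight bands of truth."""
        hits = 0
        runs = 6
        for seed in range(runs):
            cfg = SimConfig(
                N=50_000, m=20, pi0=0.5, sigma=4.0, rho=0.0, seed=1000 + seed
            )
            d, _ = simulate_z_ar1(cfg)
            fit = fit_zreg(d)
            if abs(fit.pi0 - 0.5) < 0.02 and abs(fit.sigma - 4.0) < 0.15:
                hits += 1
        assert hits == runs


class TestLfdrTable:
    def test_uniform_zero_z(self):
        d = SummaryDataset([np.zeros(1) for _ in range(4)])
        t = lfdr_table(d, ModelParams(0.5, 1.0))
        assert np.allclose(t.lfdr, 1 / (1 + 1 / np.sqrt(2)))

    def test_permutation_invariance_within_gene(self, rng):
        z = rng.normal(size=7)
        p = ModelParams(0.4, 2.0)
        d1 = SummaryDataset([z])
        d2 = SummaryDataset([z[::-1].copy()])
        assert lfdr_table(d1, p).lfdr[0] == pytest.approx(
            lfdr_table(d2, p).lfdr[0], rel=1e-14
        )

    def test_increasing_one_z_decreases_lfdr(self):
        p = ModelParams(0.4, 2.0)
        base = np.array([0.5, 1.0, -0.3])
        bumped = base.copy()
        bumped[1] = 3.0
        l1 = lfdr_table(SummaryDataset([base]), p).lfdr[0]
        l2 = lfdr_table(SummaryDataset([bumped]), p).lfdr[0]
        assert l2 < l1

    def test_agrees_with_scalar_gene_lfdr(self, small_z_dataset):
        _, d, _ = small_z_dataset
        p = ModelParams(0.25, 3.0)
        t = lfdr_table(d, p)
        for i in (0, 17, 999):
            assert t.lfdr[i] == pytest.approx(gene_lfdr(d.z[i], p), abs=1e-12)
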