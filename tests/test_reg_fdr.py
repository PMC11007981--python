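import numpy as np
import pytest
from scipy.integrate import trapezoid
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from groupfdr._types import ModelParams
from groupfdr.reg_fdr import (
    GeneSufficientStats,
    RegData,
    _dataset_log_f1,
    _gene_log_mix,
    fit_reg_em,
    gene_lfdr_full,
    lfdr_table_full,
    log_f1_conditional,
    log_f1_marginal,
)
from groupfdr.summary_stats import compute_summary
from groupfdr.synthetic_data import SimConfig, simulate_full
from groupfdr.zreg_fdr import fit_zreg, lfdr_table


def trapezoid_marginal(stats, j, sigma, n_points=400_001):
    """Independent oracle: fine trapezoid over beta in (-1, 1) of the
    random-effects integrand written directly on the beta scale."""
    n = stats.n
    beta = np.linspace(-1 + 1e-9, 1 - 1e-9, n_points)
    log_cond = (
        -(n / 2) * np.log(2 * np.pi)
        - (n / 2) * np.log1p(-(beta**2))
        - (stats.yy - 2 * beta * stats.yx[j] + beta**2 * stats.xx[j])
        / (2 * (1 - beta**2))
    )
    log_prior = (
        np.log(np.sqrt(n - 3) / (np.sqrt(2 * np.pi) * sigma * (1 - beta**2)))
        - (n - 3) / (2 * sigma**2) * np.arctanh(beta) ** 2
    )
    g = log_cond + log_prior
    M = g.max()
    return M + np.log(trapezoid(np.exp(g - M), beta))


@pytest.fixture(scope="module")
def reg_data(small_full_dataset):
    _, d, _ = small_full_dataset
    return RegData(d)


class TestConditionalDensity:
    def test_beta_zero_equals_null_density(self, reg_data):
        st = reg_data.gene_stats(0)
        expected = -(st.n / 2) * np.log(2 * np.pi) - st.yy / 2
        assert log_f1_conditional(st, 0, 0.0) == pytest.approx(expected, rel=1e-14)

    def test_matches_direct_gaussian_density(self):
        # n=2 toy, evaluated against scipy's multivariate normal
        Y = np.array([1.0, 0.0])
        X = np.array([1.0, 0.0])
        beta = 0.5
        st = GeneSufficientStats(
            yy=float(Y @ Y), yx=np.array([float(Y @ X)]), xx=np.array([float(X @ X)]),
            n=2,
        )
        direct = multivariate_normal.logpdf(
            Y, mean=beta * X, cov=(1 - beta**2) * np.eye(2)
        )
        assert log_f1_conditional(st, 0, beta) == pytest.approx(direct, rel=1e-12)

    def test_sign_flip_symmetry(self, reg_data):
        st = reg_data.gene_stats(2)
        flipped = GeneSufficientStats(yy=st.yy, yx=-st.yx, xx=st.xx, n=st.n)
        assert log_f1_conditional(st, 1, 0.4) == pytest.approx(
            log_f1_conditional(flipped, 1, -0.4), rel=1e-14
        )

    def test_invalid_beta_error(self, reg_data):
        with pytest.raises(ValueError):
            log_f1_conditional(reg_data.gene_stats(0), 0, 1.0)


class TestMarginalDensity:
    @pytest.mark.parametrize("gi,j,sigma", [(3, 0, 2.0), (0, 2, 5.0), (5, 1, 0.5)])
    def test_matches_trapezoid_oracle(self, reg_data, gi, j, sigma):
        st = reg_data.gene_stats(gi)
        oracle = trapezoid_marginal(st, j, sigma)
        assert log_f1_marginal(st, j, sigma, 41) == pytest.approx(oracle, rel=1e-6)

    def test_quadrature_order_robustness(self, reg_data):
        st = reg_data.gene_stats(7)
        a = log_f1_marginal(st, 0, 2.0, 41)
        b = log_f1_marginal(st, 0, 2.0, 81)
        assert abs(a - b) < 1e-8

    def test_small_sigma_approaches_null_conditional(self, reg_data):
        st = reg_data.gene_stats(1)
        null_val = log_f1_conditional(st, 0, 0.0)
        assert log_f1_marginal(st, 0, 1e-3, 41) == pytest.approx(null_val, abs=1e-3)

    def test_invalid_args(self, reg_data):
        st = reg_data.gene_stats(0)
        with pytest.raises(ValueError):
            log_f1_marginal(st, 0, 0.0)
        with pytest.raises(ValueError):
            log_f1_marginal(st, 0, 1.0, quad_order=5)


class TestGeneLfdrFull:
    def test_pi0_one(self, reg_data):
        assert gene_lfdr_full(reg_data.gene_stats(0), ModelParams(1.0, 2.0)) == 1.0

    def test_sigma_zero_limit_returns_pi0(self, reg_data):
        st = reg_data.gene_stats(4)
        assert gene_lfdr_full(st, ModelParams(0.3, 0.0)) == pytest.approx(
            0.3, abs=1e-9
        )

    def test_orthogonal_snp_favors_null(self):
        # y exactly orthogonal to the only SNP: data mildly favor the null
        n = 40
        st = GeneSufficientStats(
            yy=float(n), yx=np.array([0.0]), xx=np.array([float(n)]), n=n
        )
        lfdr = gene_lfdr_full(st, ModelParams(0.5, 3.0))
        assert lfdr > 0.5

    def test_lfdr_in_unit_interval(self, reg_data):
        t = lfdr_table_full(reg_data, ModelParams(0.2, 5.0))
        assert np.all((t.lfdr >= 0) & (t.lfdr <= 1))

    def test_invariant_to_positive_snp_rescaling(self, small_full_dataset):
        from groupfdr._types import FullDataset

        _, d, _ = small_full_dataset
        scaled = FullDataset(
            expression=d.expression,
            genotype_groups=[3.7 * g for g in d.genotype_groups],
            gene_ids=d.gene_ids,
        )
        a = lfdr_table_full(RegData(d), ModelParams(0.2, 4.0)).lfdr
        b = lfdr_table_full(RegData(scaled), ModelParams(0.2, 4.0)).lfdr
        assert np.allclose(a, b, atol=1e-10)


class TestFitRegEM:
    def test_monotone_loglik_and_recovery(self, small_full_dataset):
        cfg, d, _ = small_full_dataset
        fit = fit_reg_em(d)
        lls = [t[2] for t in fit.trace]
        assert all(b >= a - 1e-8 * max(1, abs(a)) for a, b in zip(lls, lls[1:]))
        assert fit.pi0 == pytest.approx(cfg.pi0, abs=0.12)
        assert fit.sigma == pytest.approx(cfg.sigma, rel=0.30)

    def test_all_null_fit_is_effectively_null(self):
        """pi0=1 truth: (pi0, sigma) is only set-identified (the boundary
        ridge {sigma=0} u {pi0=1} shares one distribution), so assert the
        fit is *effectively* null: no likelihood gain over the null model
        and no discoveries at alpha=0.05."""
        from groupfdr.fdr_control import adaptive_threshold

        cfg = SimConfig(N=200, m=3, n=60, pi0=1.0, sigma=3.0, rho=0.0, seed=9)
        d, _ = simulate_full(cfg)
        rd = RegData(d)
        fit = fit_reg_em(rd, max_iter=60)
        null_ll = float(rd.log_f0.sum())
        assert fit.loglik - null_ll < 3.0
        lf = lfdr_table_full(rd, fit.params).lfdr
        assert adaptive_threshold(lf, 0.05).L == 0

    def test_em_fixed_point_maximizes_composite_likelihood(self):
        """EM lands where a direct 2-parameter numeric maximizer lands."""
        cfg = SimConfig(N=150, m=4, n=60, pi0=0.3, sigma=4.0, rho=0.2, seed=21)
        d, _ = simulate_full(cfg)
        rd = RegData(d)
        fit = fit_reg_em(rd, tol=1e-10)

        def negll(x):
            pi0 = 1 / (1 + np.exp(-x[0]))
            sigma = np.exp(x[1])
            logf1 = _dataset_log_f1(rd, sigma, 41)
            lm, _, _ = _gene_log_mix(rd, logf1, pi0)
            return -lm.sum()

        direct = minimize(
            negll,
            x0=[0.0, np.log(2.0)],
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9},
        )
        pi0_direct = 1 / (1 + np.exp(-direct.x[0]))
        sigma_direct = np.exp(direct.x[1])
        assert fit.pi0 == pytest.approx(pi0_direct, abs=2e-3)
        assert fit.sigma == pytest.approx(sigma_direct, rel=5e-3)
        assert -direct.fun <= fit.loglik + 1e-4

    def test_agrees_with_summary_statistic_route(self, small_full_dataset):
        """The two lfdr routes correlate strongly on the same data."""
        _, d, _ = small_full_dataset
        fit_r = fit_reg_em(d)
        s = compute_summary(d)
        fit_z = fit_zreg(s)
        lr = lfdr_table_full(RegData(d), fit_r.params).lfdr
        lz = lfdr_table(s, fit_z.params).lfdr
        assert np.corrcoef(lr, lz)[0, 1] > 0.9
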