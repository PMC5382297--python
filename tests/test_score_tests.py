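"""Score statistics: arithmetic oracles, invariances, distributional checks."""

import numpy as np
import pytest
from scipy import stats

from mixge import (
    DesignBundle,
    IDENTITY,
    LOGIT,
    fit_null_full,
    fit_null_tau,
    mixge_test,
    score_pi,
    score_tau,
    score_tau_skat_variant,
)


def brute_force_quadratic(r, E, G, omega=None):
    """Triple-loop oracle for r' diag(E) G omega G' diag(E) r."""
    n, p = G.shape
    w = np.ones(p) if omega is None else omega
    total = 0.0
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += E[i] * G[i, j] * r[i]
        total += w[j] * s * s
    return total


def test_tau_statistic_matches_triple_loop(toy_bundle):
    fit = fit_null_tau(toy_bundle, IDENTITY)
    res = score_tau(fit, toy_bundle)
    oracle = brute_force_quadratic(fit.residuals, toy_bundle.E, toy_bundle.G)
    assert np.isclose(res.statistic, oracle, rtol=1e-10)
    assert res.statistic >= 0
    assert (np.diff(res.eigenvalues) <= 1e-12).all()  # sorted descending


def test_tau_statistic_with_omega_weights(toy_bundle):
    fit = fit_null_tau(toy_bundle, IDENTITY)
    omega = np.array([2.0, 0.5])
    res = score_tau(fit, toy_bundle, omega=omega)
    oracle = brute_force_quadratic(fit.residuals, toy_bundle.E, toy_bundle.G, omega)
    assert np.isclose(res.statistic, oracle, rtol=1e-10)


def test_tau_pvalue_matches_monte_carlo_null(toy_bundle):
    """p-value within 0.01 of a direct simulation of the quadratic form
    under the estimated null (refit per draw)."""
    fit = fit_null_tau(toy_bundle, IDENTITY, main_effects="collapsed")
    res = score_tau(fit, toy_bundle)
    D = fit.design
    H = D @ np.linalg.inv(D.T @ D) @ D.T
    A = toy_bundle.E[:, None] * toy_bundle.G
    rng = np.random.default_rng(42)
    sd = np.sqrt(fit.sigma2_diag[0])
    draws = rng.standard_normal((10 ** 6, toy_bundle.n_subjects)) * sd
    R = draws - draws @ H.T          # refit = projection for OLS
    S = ((R @ A) ** 2).sum(axis=1)
    mc_p = (S >= res.statistic).mean()
    assert abs(res.p_value - mc_p) < 0.01


def test_pi_score_matches_scalar_oracle(toy_bundle):
    """q=1, W=1/p: U is the residual--(E x burden) inner product."""
    fit = fit_null_full(toy_bundle, IDENTITY)
    res = score_pi(fit, toy_bundle)
    burden = toy_bundle.G.mean(axis=1)  # W = [1/2, 1/2]
    oracle = sum(toy_bundle.E[i] * burden[i] * fit.residuals[i]
                 for i in range(6))
    assert np.isclose(res.score_vector[0], oracle, rtol=1e-10)
    assert res.df == 1
    assert res.quadratic_stat >= 0
    assert np.allclose(res.covariance, res.covariance.T)


def test_skat_variant_uses_full_null_residuals(toy_bundle):
    fit_f = fit_null_full(toy_bundle, IDENTITY)
    res = score_tau_skat_variant(fit_f, toy_bundle)
    oracle = brute_force_quadratic(fit_f.residuals, toy_bundle.E, toy_bundle.G)
    assert np.isclose(res.statistic, oracle, rtol=1e-10)
    # differs from the sequential tau score only through the residuals
    fit_t = fit_null_tau(toy_bundle, IDENTITY)
    res_t = score_tau(fit_t, toy_bundle)
    assert not np.isclose(res.statistic, res_t.statistic)


def test_zero_residuals_give_unit_pvalues(toy_bundle):
    D = toy_bundle.design_full()
    theta = np.ones(D.shape[1])
    bundle = DesignBundle(Y=D @ theta, X=toy_bundle.X, E=toy_bundle.E,
                          G=toy_bundle.G)
    res = mixge_test(bundle, IDENTITY)
    assert res.tau.statistic == 0.0
    assert res.p_tau == 1.0 and res.p_pi == 1.0
    assert res.p_fisher == 1.0 and res.p_tippett == 1.0


def test_zero_environment_degenerates(gaussian_bundle):
    b = gaussian_bundle
    bundle = DesignBundle(Y=b.Y, X=b.X, E=np.zeros(b.n_subjects), G=b.G)
    res = mixge_test(bundle, IDENTITY)
    assert res.tau.degenerate and res.pi.degenerate
    assert res.p_tau == 1.0 and res.p_pi == 1.0
    assert res.p_fisher == 1.0 and res.p_tippett == 1.0


def test_snp_order_invariance(gaussian_bundle):
    b = gaussian_bundle
    perm = np.array([3, 0, 4, 1, 2])
    shuffled = DesignBundle(Y=b.Y, X=b.X, E=b.E, G=b.G[:, perm])
    r1 = mixge_test(b, IDENTITY)
    r2 = mixge_test(shuffled, IDENTITY)
    assert np.isclose(r1.tau.statistic, r2.tau.statistic, rtol=1e-9)
    assert np.isclose(r1.p_pi, r2.p_pi, rtol=1e-9)
    assert np.isclose(r1.p_fisher, r2.p_fisher, rtol=1e-9)


def test_w_recombination_invariance(gaussian_bundle):
    """U's quadratic statistic is invariant to invertible recombination of W."""
    b = gaussian_bundle
    p = b.n_snps
    rng = np.random.default_rng(8)
    W = rng.random((p, 2)) + 0.1
    T = np.array([[2.0, 1.0], [0.5, 1.5]])  # invertible
    b1 = DesignBundle(Y=b.Y, X=b.X, E=b.E, G=b.G, W=W)
    b2 = DesignBundle(Y=b.Y, X=b.X, E=b.E, G=b.G, W=W @ T)
    s1 = score_pi(fit_null_full(b1, IDENTITY), b1)
    s2 = score_pi(fit_null_full(b2, IDENTITY), b2)
    assert np.isclose(s1.quadratic_stat, s2.quadratic_stat, rtol=1e-8)
    assert s1.df == s2.df


def test_environment_rescaling_invariance(gaussian_bundle):
    """E -> cE multiplies S_tau by c^2 and leaves all p-values unchanged."""
    b = gaussian_bundle
    c = 3.7
    scaled = DesignBundle(Y=b.Y, X=b.X, E=c * b.E, G=b.G)
    r1 = mixge_test(b, IDENTITY)
    r2 = mixge_test(scaled, IDENTITY)
    assert np.isclose(r2.tau.statistic, c ** 2 * r1.tau.statistic, rtol=1e-8)
    assert np.allclose(r2.tau.eigenvalues, c ** 2 * r1.tau.eigenvalues, rtol=1e-8)
    for attr in ("p_pi", "p_tau", "p_fisher", "p_tippett"):
        assert np.isclose(getattr(r1, attr), getattr(r2, attr), rtol=1e-8)


def test_quadratic_stat_is_chi2_under_gaussian_null():
    """Empirical distribution of U' Sigma^-1 U matches chi2_q (KS p > 0.01)."""
    rng = np.random.default_rng(77)
    n, p, reps = 150, 4, 2000
    stats_out = np.empty(reps)
    for r in range(reps):
        maf = rng.uniform(0.1, 0.5, p)
        u = rng.random((n, p))
        G = ((u >= (1 - maf) ** 2).astype(float)
             + (u >= (1 - maf) ** 2 + 2 * maf * (1 - maf)).astype(float))
        E = rng.standard_normal(n)
        Y = 0.3 * E + G @ np.full(p, 0.2) + rng.standard_normal(n)
        b = DesignBundle(Y=Y, X=np.ones((n, 1)), E=E, G=G)
        stats_out[r] = score_pi(fit_null_full(b, IDENTITY), b).quadratic_stat
    assert stats.kstest(stats_out, "chi2", args=(1,)).pvalue > 0.01


def test_collapsed_main_effects_option(gaussian_bundle):
    """The burden-collapsed null design remains available and differs."""
    b = gaussian_bundle
    r_snp = mixge_test(b, IDENTITY, main_effects="per-snp")
    r_col = mixge_test(b, IDENTITY, main_effects="collapsed")
    assert r_col.tau is not None
    # collapsed design has fewer mean-model columns -> different residuals
    assert not np.isclose(r_snp.tau.statistic, r_col.tau.statistic)
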