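"""Null-model fitting: exact recovery, oracle agreement, error modes."""

import numpy as np
import pytest

from mixge import (
    ConvergenceError,
    DesignBundle,
    EstimabilityError,
    IDENTITY,
    LOGIT,
    fit_null_full,
    fit_null_tau,
    variance_diag,
)
from mixge.model_core import NullFit, _irls_logit, prune_columns


def normal_equations(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent oracle: solve (D'D) beta = D'y directly."""
    return np.linalg.solve(D.T @ D, D.T @ y)


@pytest.mark.parametrize("fitter,design_of", [
    (fit_null_tau, lambda b: b.design_tau()),
    (fit_null_full, lambda b: b.design_full()),
])
def test_noiseless_identity_recovery(toy_bundle, fitter, design_of):
    """Y constructed exactly as design @ theta is recovered with zero residuals."""
    D = design_of(toy_bundle)
    theta = np.arange(1.0, D.shape[1] + 1)
    bundle = DesignBundle(Y=D @ theta, X=toy_bundle.X, E=toy_bundle.E,
                          G=toy_bundle.G)
    fit = fitter(bundle, IDENTITY)
    assert np.allclose(fit.coefficients, theta[fit.kept_columns], atol=1e-8)
    assert np.allclose(fit.residuals, 0.0, atol=1e-8)
    assert np.allclose(fit.sigma2_diag, 0.0, atol=1e-12)


@pytest.mark.parametrize("fitter,design_of,kind", [
    (fit_null_tau, lambda b: b.design_tau(), "tau_null"),
    (fit_null_full, lambda b: b.design_full(), "full_null"),
])
def test_identity_fit_matches_normal_equations(toy_bundle, fitter, design_of, kind):
    fit = fitter(toy_bundle, IDENTITY)
    D = design_of(toy_bundle)[:, fit.kept_columns]
    assert fit.null_kind == kind
    assert np.allclose(fit.coefficients, normal_equations(D, toy_bundle.Y),
                       rtol=1e-10)
    assert abs(fit.residuals.sum()) < 1e-8  # intercept present


def test_logit_intercept_only_closed_form():
    """Intercept-only logistic MLE: logit of the sample proportion."""
    y = np.array([1.0] * 3 + [0.0] * 7)
    D = np.ones((10, 1))
    beta, _ = _irls_logit(D, y)
    assert np.isclose(beta[0], np.log(3 / 7), atol=1e-8)
    mu = 1 / (1 + np.exp(-beta[0]))
    assert np.isclose(mu, 0.3, atol=1e-8)


def test_logit_fit_matches_statsmodels(gaussian_bundle):
    """IRLS coefficients agree with the statsmodels GLM oracle."""
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    b = gaussian_bundle
    eta = -0.3 + 0.5 * b.E + b.G @ rng.normal(0, 0.3, b.n_snps)
    y = (rng.random(b.n_subjects) < 1 / (1 + np.exp(-eta))).astype(float)
    bundle = DesignBundle(Y=y, X=b.X, E=b.E, G=b.G)
    fit = fit_null_full(bundle, LOGIT)
    sm_fit = sm.GLM(y, fit.design, family=sm.families.Binomial()).fit()
    assert np.allclose(fit.coefficients, sm_fit.params, rtol=1e-6, atol=1e-8)
    assert np.allclose(fit.mu, sm_fit.fittedvalues, rtol=1e-6)
    assert (fit.mu > 0).all() and (fit.mu < 1).all()


def test_score_equations_hold(toy_bundle, gaussian_bundle):
    """design' (Y - mu) ~ 0 for identity; weighted version for logit."""
    fit = fit_null_tau(toy_bundle, IDENTITY)
    g = fit.design.T @ fit.residuals
    assert np.max(np.abs(g)) < 1e-8 * max(1.0, np.abs(toy_bundle.Y).max())

    rng = np.random.default_rng(11)
    b = gaussian_bundle
    y = (rng.random(b.n_subjects) < 0.4).astype(float)
    bundle = DesignBundle(Y=y, X=b.X, E=b.E, G=b.G)
    fit = fit_null_full(bundle, LOGIT)
    g = fit.design.T @ fit.residuals
    assert np.max(np.abs(g)) < 1e-6


def test_full_null_equals_tau_null_with_zero_environment(gaussian_bundle):
    """With E = 0 the interaction column vanishes: shared coefficients match."""
    b = gaussian_bundle
    zero_e = DesignBundle(Y=b.Y, X=b.X, E=np.zeros(b.n_subjects), G=b.G)
    fit_t = fit_null_tau(zero_e, IDENTITY)
    fit_f = fit_null_full(zero_e, IDENTITY)
    assert np.allclose(fit_t.mu, fit_f.mu, rtol=1e-9)
    # E column and interaction column both pruned from M; coefficient sets match
    assert fit_t.coefficients.size == fit_f.coefficients.size
    assert np.allclose(np.sort(fit_t.coefficients), np.sort(fit_f.coefficients),
                       rtol=1e-8)


def test_identity_fit_invariant_to_covariate_rescaling(gaussian_bundle):
    b = gaussian_bundle
    X2 = b.X.copy()
    X2[:, 1] *= 10.0
    fit1 = fit_null_tau(b, IDENTITY)
    fit2 = fit_null_tau(DesignBundle(Y=b.Y, X=X2, E=b.E, G=b.G), IDENTITY)
    assert np.allclose(fit1.mu, fit2.mu, rtol=1e-9)
    assert np.isclose(fit2.coefficients[1] * 10.0, fit1.coefficients[1], rtol=1e-8)


def test_variance_diag_formulas():
    resid = np.array([1.0, -1.0, 1.0, -1.0])
    fit = NullFit("tau_null", np.zeros(1), np.zeros(4), resid,
                  np.ones(4), np.ones((4, 1)), np.array([0]), np.array([], int),
                  IDENTITY)
    assert np.allclose(variance_diag(fit), 1.0)  # RSS/N = 4/4

    mu = np.full(4, 0.5)
    fit_l = NullFit("tau_null", np.zeros(1), mu, 1 - mu, mu * (1 - mu),
                    np.ones((4, 1)), np.array([0]), np.array([], int), LOGIT)
    assert np.allclose(variance_diag(fit_l), 0.25)
    fit_l.mu = np.array([1e-12, 1 - 1e-12, 0.5, 0.5])
    v = variance_diag(fit_l)
    assert v[0] < 1e-11 and v[1] < 1e-11  # boundary limit -> 0


def test_zero_weight_column_rejected(toy_bundle):
    W = np.array([[0.5, 0.0], [0.5, 0.0]])
    with pytest.raises(EstimabilityError, match="all-zero column"):
        DesignBundle(Y=toy_bundle.Y, X=toy_bundle.X, E=toy_bundle.E,
                     G=toy_bundle.G, W=W)


def test_all_monomorphic_rejected():
    with pytest.raises(EstimabilityError, match="monomorphic"):
        DesignBundle(Y=np.arange(8.0), X=np.ones((8, 1)),
                     E=np.arange(8.0), G=np.zeros((8, 2)))


def test_separation_raises_named_error():
    """A covariate perfectly splitting the outcome triggers the separation guard."""
    n = 40
    x = np.r_[np.full(20, 0.5), np.full(20, -0.5)]
    y = (x > 0).astype(float)
    with pytest.raises(ConvergenceError, match="separation"):
        _irls_logit(np.column_stack([np.ones(n), x]), y)


def test_prune_columns_prefers_earlier():
    rng = np.random.default_rng(3)
    A = rng.standard_normal((20, 3))
    B = np.column_stack([A, A[:, 0] + A[:, 1], rng.standard_normal(20)])
    kept = prune_columns(B)
    assert kept.tolist() == [0, 1, 2, 4]  # dependent 4th column dropped


def test_missing_genotypes_mean_imputed():
    G = np.array([[0.0, np.nan], [1.0, 2.0], [np.nan, 0.0], [2.0, 2.0],
                  [1.0, 1.0], [0.0, 1.0]])
    b = DesignBundle(Y=np.arange(6.0) + 0.5, X=np.ones((6, 1)),
                     E=np.array([1.0, -1, 2, 0, 1, -1]), G=G)
    assert np.isclose(b.G[2, 0], 0.8)       # mean of 0,1,2,1,0
    assert np.isclose(b.G[0, 1], 1.2)       # mean of 2,0,2,1,1
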