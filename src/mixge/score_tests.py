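"""Score statistics for the gene-environment interaction test.

Two independent scores are computed sequentially:

* the variance-component score
  ``S_tau2 = (Y - mu_hat)^T diag(E) G omega G^T diag(E) (Y - mu_hat)``,
  with ``mu_hat`` from the tau null (fixed interaction retained), referred
  to a mixture of 1-df chi-squares whose weights are the non-zero
  eigenvalues of the variance-projected kernel;
* the fixed-effect interaction score
  ``U = (diag(E) G W)^T (Y - mu_tilde)`` with ``mu_tilde`` from the
  interaction-free null, whose quadratic form ``U^T Sigma^{-1} U`` is
  chi-square with q degrees of freedom.

Computing the variance score under the null that keeps the fixed
interaction in the mean model is what makes the two p-values independent
and lets Fisher/Tippett combination apply without permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import (
    DesignBundle,
    LinkSpec,
    NullFit,
    fit_null_full,
    fit_null_tau,
)
from .pvalue_dist import ChiSquareMixture, P_FLOOR, combine_fisher, combine_tippett, mixture_sf

__all__ = [
    "TauScoreResult",
    "PiScoreResult",
    "MixGEResult",
    "score_tau",
    "score_pi",
    "score_tau_skat_variant",
    "mixge_test",
    "maf_beta_weights",
]

EIG_REL_TOL = 1e-10   # keep eigenvalues > tol * lambda_max
SIGMA_REL_TOL = 1e-10  # pseudo-inverse cutoff for Sigma


@dataclass
class TauScoreResult:
    """Variance-component interaction score and its mixture null law."""

    statistic: float
    eigenvalues: np.ndarray       # descending, strictly positive
    p_value: float
    degenerate: bool = False
    omega_used: np.ndarray | None = None


@dataclass
class PiScoreResult:
    """Fixed-effect interaction score vector and its chi-square test."""

    score_vector: np.ndarray
    covariance: np.ndarray
    quadratic_stat: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass
class MixGEResult:
    """The combined set-based interaction test for one variant set."""

    p_pi: float
    p_tau: float
    p_fisher: float
    p_tippett: float
    p_random: float | None = None
    tau: TauScoreResult | None = None
    pi: PiScoreResult | None = None
    diagnostics: dict = field(default_factory=dict)


def maf_beta_weights(G: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Per-SNP variance weights decreasing in minor-allele frequency.

    Beta(a, b) density evaluated at the sample MAF, squared — the common
    rare-variant up-weighting convention.  Off by default in the tests.
    """
    maf = np.clip(np.asarray(G, dtype=float).mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    maf = np.minimum(maf, 1.0 - maf)
    return stats.beta.pdf(maf, a, b) ** 2


def _projected_kernel_eigs(A: np.ndarray, fit: NullFit) -> np.ndarray:
    """Non-zero eigenvalues of the variance-projected kernel.

    With kernel ``K = A A^T`` and projection
    ``P = D - D M (M^T D M)^{-1} M^T D`` (D the variance diagonal, M the
    fitted null design), the statistic's null law has weights
    ``eig(P K) = eig(A^T P A)`` — computed in the economical p x p form.
    """
    d = fit.sigma2_diag
    M = fit.design
    DA = A * d[:, None]
    DM = M * d[:, None]
    MtDM = M.T @ DM
    # A^T P A = A^T D A - (A^T D M) (M^T D M)^+ (M^T D A)
    AtDM = A.T @ DM
    core = A.T @ DA - AtDM @ np.linalg.pinv(MtDM, rcond=1e-12) @ AtDM.T
    core = 0.5 * (core + core.T)
    eigs = np.linalg.eigvalsh(core)[::-1]
    if eigs.size == 0 or eigs[0] <= 0:
        return np.empty(0)
    return eigs[eigs > EIG_REL_TOL * eigs[0]]


def _residuals_negligible(fit: NullFit) -> bool:
    """A numerically perfect null fit leaves nothing to test (p = 1)."""
    scale = 1.0 + np.abs(fit.mu).max(initial=0.0)
    return np.abs(fit.residuals).max(initial=0.0) <= 1e-12 * scale


def _tau_from_fit(fit: NullFit, bundle: DesignBundle,
                  omega: np.ndarray | None) -> TauScoreResult:
    E = bundle.E
    G = bundle.G
    r = fit.residuals
    if omega is not None:
        omega = np.asarray(omega, dtype=float).ravel()
        if omega.shape[0] != bundle.n_snps or (omega < 0).any():
            raise ValueError("omega must be a nonnegative length-p vector")
        A = (E[:, None] * G) * np.sqrt(omega)[None, :]
    else:
        A = E[:, None] * G
    u = A.T @ r
    statistic = float(u @ u)
    if _residuals_negligible(fit):
        return TauScoreResult(0.0, np.empty(0), 1.0, degenerate=True,
                              omega_used=omega)
    eigs = _projected_kernel_eigs(A, fit)
    if eigs.size == 0 or not np.any(E):
        return TauScoreResult(statistic, np.empty(0), 1.0, degenerate=True,
                              omega_used=omega)
    p = float(np.clip(mixture_sf(statistic, ChiSquareMixture(eigs)), P_FLOOR, 1.0))
    return TauScoreResult(statistic, eigs, p, degenerate=False, omega_used=omega)


def score_tau(fit: NullFit, bundle: DesignBundle,
              omega: np.ndarray | None = None) -> TauScoreResult:
    """Variance-component interaction score under the tau null.

    ``omega`` supplies optional per-SNP variance weights (identity when
    absent).  A zero environment or an all-zero projected kernel yields a
    degenerate result with p-value 1 rather than an exception.
    """
    if fit.null_kind != "tau_null":
        raise ValueError("score_tau requires a tau_null fit")
    return _tau_from_fit(fit, bundle, omega)


def score_tau_skat_variant(fit: NullFit, bundle: DesignBundle,
                           omega: np.ndarray | None = None) -> TauScoreResult:
    """SKAT-style variance score computed under the interaction-free null.

    Same quadratic form as :func:`score_tau` but residuals and projection
    come from the mean model without the fixed interaction term (both
    ``pi^(2)`` and ``tau^2`` set to zero) — the classical interaction-SKAT
    construction, reported as ``P_random``.
    """
    if fit.null_kind != "full_null":
        raise ValueError("score_tau_skat_variant requires a full_null fit")
    return _tau_from_fit(fit, bundle, omega)


def score_pi(fit: NullFit, bundle: DesignBundle) -> PiScoreResult:
    """Fixed-effect (burden-type) interaction score under the interaction-free null.

    ``U = (diag(E) G W)^T (Y - mu_tilde)`` with covariance
    ``Sigma = B^T {D - D V (V^T D V)^{-1} V^T D} B``; the quadratic form
    ``U^T Sigma^{-1} U`` is chi-square with ``q`` degrees of freedom
    (numerical rank of Sigma after pseudo-inversion).
    """
    if fit.null_kind != "full_null":
        raise ValueError("score_pi requires a full_null fit")
    B = bundle.E[:, None] * bundle.burden()
    r = fit.residuals
    U = B.T @ r
    if _residuals_negligible(fit):
        return PiScoreResult(np.zeros_like(U), np.zeros((U.size, U.size)),
                             0.0, B.shape[1], 1.0, degenerate=True)
    d = fit.sigma2_diag
    V = fit.design
    DB = B * d[:, None]
    DV = V * d[:, None]
    BtDV = B.T @ DV
    Sigma = B.T @ DB - BtDV @ np.linalg.pinv(V.T @ DV, rcond=1e-12) @ BtDV.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    scale = np.abs(Sigma).max() if Sigma.size else 0.0
    if scale == 0.0:
        q = B.shape[1]
        return PiScoreResult(U, Sigma, 0.0, q, 1.0, degenerate=True)
    # symmetric pseudo-inverse; df is the numerical rank
    evals, evecs = np.linalg.eigh(Sigma)
    keep = evals > SIGMA_REL_TOL * evals.max()
    df = int(keep.sum())
    if df == 0:
        return PiScoreResult(U, Sigma, 0.0, B.shape[1], 1.0, degenerate=True)
    inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    stat = float(U @ inv @ U)
    stat = max(stat, 0.0)
    p = float(np.clip(stats.chi2.sf(stat, df=df), P_FLOOR, 1.0))
    return PiScoreResult(U, Sigma, stat, df, p, degenerate=False)


def mixge_test(bundle: DesignBundle, link: LinkSpec,
               omega: np.ndarray | None = None,
               compute_random: bool = True,
               main_effects: str = "per-snp",
               dof_correction: bool = True) -> MixGEResult:
    """Run the full sequential interaction test on one variant set.

    Fits both nulls, computes the variance-component p-value (fixed
    interaction retained in the mean model) and the fixed-effect p-value,
    and combines them with Fisher's and Tippett's rules.  ``p_random``
    reports the interaction-SKAT variant computed under the
    interaction-free null.  ``main_effects`` selects how genetic main
    effects enter the null mean models: per SNP (default; required for
    calibration when variants carry real heterogeneous main effects) or
    collapsed to the weighted burden (useful when p approaches N).
    """
    fit_tau = fit_null_tau(bundle, link, main_effects, dof_correction)
    fit_full = fit_null_full(bundle, link, main_effects, dof_correction)
    tau = score_tau(fit_tau, bundle, omega)
    pi = score_pi(fit_full, bundle)
    p_fisher = combine_fisher(pi.p_value, tau.p_value)
    p_tippett = combine_tippett(pi.p_value, tau.p_value)
    p_random = None
    if compute_random:
        p_random = score_tau_skat_variant(fit_full, bundle, omega).p_value
    diagnostics = {
        "dropped_columns_tau": fit_tau.dropped_columns.tolist(),
        "dropped_columns_full": fit_full.dropped_columns.tolist(),
        "n_eigenvalues": int(tau.eigenvalues.size),
        "tau_degenerate": tau.degenerate,
        "pi_degenerate": pi.degenerate,
        "irls_iterations": (fit_tau.n_iter, fit_full.n_iter),
    }
    return MixGEResult(pi.p_value, tau.p_value, p_fisher, p_tippett, p_random,
                       tau, pi, diagnostics)
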