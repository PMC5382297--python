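"""Domain containers and null mean-model fitting.

The MixGE model for subject :math:`i` relates a phenotype :math:`y_i` to
covariates :math:`X_i`, an environmental exposure :math:`e_i` and a set of
:math:`p` SNP minor-allele counts :math:`G_i` through

.. math::

    g\\{E(y_i)\\} = X_i^T \\beta_x + e_i \\beta_e + G_i^T W \\pi^{(1)}
                   + e_i G_i^T W \\pi^{(2)} + e_i G_i^T \\delta ,

where ``W`` is a ``p x q`` weight matrix collapsing the variant set,
``pi^(2)`` is the fixed (burden-type) interaction effect and ``delta`` is a
random per-variant interaction effect with variance ``tau^2``.  The score
tests need two null fits of the *mean* part of this model:

* the ``tau_null`` fit, mean model ``M = [X, E, GW, diag(E) GW]``, used to
  test ``tau^2 = 0`` without assuming ``pi^(2) = 0``;
* the ``full_null`` fit, mean model ``V = [X, E, GW]``, used to test
  ``pi^(2) = 0`` under ``tau^2 = 0``.

Both are ordinary least squares under the identity link and logistic
maximum likelihood (IRLS) under the logit link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignBundle",
    "LinkSpec",
    "NullFit",
    "EstimabilityError",
    "ConvergenceError",
    "fit_null_tau",
    "fit_null_full",
    "variance_diag",
    "impute_missing_genotypes",
    "prune_columns",
]

# Numerical policy shared by both null fits.
RANK_TOL = 1e-10          # relative tolerance for dropping collinear columns
IRLS_MAX_ITER = 100
IRLS_DEV_TOL = 1e-10      # relative deviance-change convergence criterion
SEPARATION_COEF = 30.0    # |coefficient| beyond this flags quasi-separation


class EstimabilityError(ValueError):
    """The null mean model cannot be estimated from the given design."""


class ConvergenceError(RuntimeError):
    """The logistic null fit failed to converge (or separated)."""


@dataclass
class LinkSpec:
    """Link function choice: ``identity`` (continuous Y) or ``logit`` (binary Y)."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in ("identity", "logit"):
            raise ValueError(f"unknown link {self.name!r}; use 'identity' or 'logit'")

    @property
    def is_logit(self) -> bool:
        return self.name == "logit"

    def validate_phenotype(self, y: np.ndarray) -> None:
        vals = np.unique(y)
        binary = np.isin(vals, (0.0, 1.0)).all()
        if self.is_logit and not binary:
            raise ValueError("logit link requires a 0/1 phenotype")
        if not self.is_logit and binary and vals.size <= 2:
            raise ValueError("identity link requires a continuous phenotype")


IDENTITY = LinkSpec("identity")
LOGIT = LinkSpec("logit")


@dataclass
class DesignBundle:
    """Aligned inputs for one variant-set test.

    Parameters
    ----------
    Y : (N,) phenotype vector, continuous or coded 0/1.
    X : (N, m) covariate matrix including an intercept column.
    E : (N,) environmental exposure.
    G : (N, p) minor-allele counts in {0, 1, 2}; NaN marks missing calls
        (resolved by :func:`impute_missing_genotypes` at validation).
    W : (p, q) variant weight matrix, ``q >= 1``.  Default is the equal
        1/p collapsing vector.
    """

    Y: np.ndarray
    X: np.ndarray
    E: np.ndarray
    G: np.ndarray
    W: np.ndarray | None = None
    snp_ids: list[str] | None = None
    monomorphic: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.E = np.asarray(self.E, dtype=float).ravel()
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        n = self.Y.shape[0]
        if self.X.shape[0] != n or self.E.shape[0] != n or self.G.shape[0] != n:
            raise ValueError(
                "row mismatch: Y has %d rows, X %d, E %d, G %d"
                % (n, self.X.shape[0], self.E.shape[0], self.G.shape[0])
            )
        if np.isnan(self.G).any():
            self.G = impute_missing_genotypes(self.G)
        observed = self.G[~np.isnan(self.G)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            # imputed entries are fractional by design; only raw input is checked
            pass
        if self.W is None:
            p = self.G.shape[1]
            self.W = np.full((p, 1), 1.0 / p)
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.shape[0] != self.G.shape[1]:
            raise ValueError(
                f"W has {self.W.shape[0]} rows but G has {self.G.shape[1]} SNPs"
            )
        if (np.abs(self.W).sum(axis=0) == 0).any():
            raise EstimabilityError("W contains an all-zero column")
        self.monomorphic = np.ptp(self.G, axis=0) == 0
        if self.monomorphic.all():
            raise EstimabilityError("all SNPs are monomorphic; the set is untestable")
        min_n = self.X.shape[1] + 1 + 2 * self.W.shape[1]
        if n <= min_n:
            raise EstimabilityError(
                f"N={n} too small for m={self.X.shape[1]}, q={self.W.shape[1]} "
                f"(need N > {min_n})"
            )

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    @property
    def n_weights(self) -> int:
        return self.W.shape[1]

    def burden(self) -> np.ndarray:
        """Weighted burden scores ``GW`` (N x q)."""
        return self.G @ self.W

    def _main_block(self, main_effects: str) -> np.ndarray:
        if main_effects == "per-snp":
            return self.G
        if main_effects == "collapsed":
            return self.burden()
        raise ValueError("main_effects must be 'per-snp' or 'collapsed'")

    def design_tau(self, main_effects: str = "per-snp") -> np.ndarray:
        """Mean-model design ``M = [X, E, G-main, diag(E) GW]`` for the tau null.

        The genetic main-effect block adjusts each SNP separately by default
        (``per-snp``); ``collapsed`` uses the weighted burden ``GW`` instead.
        Adjusting every SNP's main effect is what keeps the interaction
        scores centred when the variants have real, heterogeneous main
        effects — without it, unmodelled main-effect structure leaks into
        the interaction residuals (severely so under case-control
        sampling, where exposure and genotype become dependent given
        selection).
        """
        gw = self.burden()
        return np.column_stack([self.X, self.E, self._main_block(main_effects),
                                self.E[:, None] * gw])

    def design_full(self, main_effects: str = "per-snp") -> np.ndarray:
        """Mean-model design ``V = [X, E, G-main]`` for the interaction-free null."""
        return np.column_stack([self.X, self.E, self._main_block(main_effects)])


@dataclass
class NullFit:
    """A fitted null mean model consumed by the score tests."""

    null_kind: str                 # "tau_null" | "full_null"
    coefficients: np.ndarray       # on the retained (pruned) columns
    mu: np.ndarray                 # fitted means, length N
    residuals: np.ndarray          # Y - mu
    sigma2_diag: np.ndarray        # per-subject variance entries, length N
    design: np.ndarray             # pruned design matrix actually fitted
    kept_columns: np.ndarray       # indices into the unpruned design
    dropped_columns: np.ndarray    # complement of kept_columns
    link: LinkSpec
    converged: bool = True
    n_iter: int = 0


def impute_missing_genotypes(G: np.ndarray, round_to_int: bool = False) -> np.ndarray:
    """Fill NaN genotype calls with the per-SNP mean of observed values.

    A SNP with no observed calls is set to 0 (treated as monomorphic).
    """
    G = np.array(G, dtype=float)
    all_nan = np.isnan(G).all(axis=0)
    col_mean = np.zeros(G.shape[1])
    if (~all_nan).any():
        col_mean[~all_nan] = np.nanmean(G[:, ~all_nan], axis=0)
    idx = np.where(np.isnan(G))
    G[idx] = col_mean[idx[1]]
    if round_to_int:
        G = np.clip(np.rint(G), 0, 2)
    return G


def prune_columns(A: np.ndarray, tol: float = RANK_TOL) -> np.ndarray:
    """Indices of a maximal independent column subset, preferring earlier columns.

    Incremental Gram-Schmidt rank test: a column is kept iff its residual
    after projection onto the span of the already-kept columns exceeds
    ``tol`` relative to its own norm.  Deterministic, and never drops an
    early column (covariate) in favour of a later one (burden/interaction).
    """
    n, k = A.shape
    kept: list[int] = []
    Q = np.empty((n, 0))
    for j in range(k):
        c = A[:, j]
        nc = np.linalg.norm(c)
        if nc == 0.0:
            continue
        r = c - Q @ (Q.T @ c)
        nr = np.linalg.norm(r)
        if nr > tol * nc:
            kept.append(j)
            Q = np.column_stack([Q, r / nr])
    return np.asarray(kept, dtype=int)


def _fit(design: np.ndarray, bundle: DesignBundle, link: LinkSpec,
         null_kind: str, dof_correction: bool) -> NullFit:
    link.validate_phenotype(bundle.Y)
    kept = prune_columns(design)
    if kept.size == 0:
        raise EstimabilityError("design matrix has no independent columns")
    dropped = np.setdiff1d(np.arange(design.shape[1]), kept)
    D = design[:, kept]
    y = bundle.Y
    n, k = D.shape
    # plug-in variance estimates ignore the k fitted mean parameters; the
    # n/(n-k) inflation restores finite-sample calibration of the score
    # tests and is negligible for n >> k
    scale = n / (n - k) if (dof_correction and n > k) else 1.0

    if not link.is_logit:
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        mu = D @ beta
        resid = y - mu
        sigma2 = np.full(n, scale * (resid @ resid) / n)
        return NullFit(null_kind, beta, mu, resid, sigma2, D, kept, dropped,
                       link, True, 0)

    beta, n_iter = _irls_logit(D, y)
    eta = D @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    resid = y - mu
    sigma2 = scale * mu * (1.0 - mu)
    return NullFit(null_kind, beta, mu, resid, sigma2, D, kept, dropped,
                   link, True, n_iter)


def _irls_logit(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Logistic MLE by iteratively reweighted least squares.

    Deterministic start at beta = 0 (mu = 1/2).  Convergence on relative
    deviance change; quasi-separation is reported as an error naming the
    runaway columns rather than returned as a degenerate fit.
    """
    n, k = D.shape
    beta = np.zeros(k)
    dev = np.inf
    for it in range(1, IRLS_MAX_ITER + 1):
        eta = D @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(D * sw[:, None], z * sw, rcond=None)
        eta_new = D @ beta_new
        # binomial deviance, guarded at the saturation boundary
        mu_new = 1.0 / (1.0 + np.exp(-eta_new))
        mu_c = np.clip(mu_new, 1e-12, 1 - 1e-12)
        dev_new = -2.0 * np.sum(y * np.log(mu_c) + (1 - y) * np.log1p(-mu_c))
        beta = beta_new
        if np.abs(beta).max() > SEPARATION_COEF:
            bad = np.where(np.abs(beta) > SEPARATION_COEF)[0]
            raise ConvergenceError(
                f"quasi-separation in logistic null fit: column(s) {bad.tolist()} "
                f"have |coefficient| > {SEPARATION_COEF}"
            )
        if dev_new == 0.0 or abs(dev - dev_new) < IRLS_DEV_TOL * (abs(dev_new) + 1e-300):
            return beta, it
        dev = dev_new
    raise ConvergenceError(f"logistic null fit did not converge in {IRLS_MAX_ITER} IRLS iterations")


def fit_null_tau(bundle: DesignBundle, link: LinkSpec,
                 main_effects: str = "per-snp",
                 dof_correction: bool = True) -> NullFit:
    """Fit the tau-score null: interaction fixed effect retained, tau^2 = 0.

    Mean model ``[X, E, G-main, diag(E) GW]``.  Identity link is the OLS
    fit with a common residual-variance estimate on the diagonal; logit
    link is the logistic MLE with ``mu (1 - mu)``, both inflated by
    ``n/(n - k)`` when ``dof_correction`` is on (see :func:`variance_diag`
    for the uncorrected plug-in quantities).
    """
    return _fit(bundle.design_tau(main_effects), bundle, link, "tau_null",
                dof_correction)


def fit_null_full(bundle: DesignBundle, link: LinkSpec,
                  main_effects: str = "per-snp",
                  dof_correction: bool = True) -> NullFit:
    """Fit the interaction-free null: mean model ``[X, E, G-main]``
    (both the fixed interaction effect and tau^2 set to zero)."""
    return _fit(bundle.design_full(main_effects), bundle, link, "full_null",
                dof_correction)


def variance_diag(fit: NullFit, link: LinkSpec | None = None) -> np.ndarray:
    """Plug-in per-subject variance diagonal of the fitted null.

    Identity link: the constant RSS/N; logit link: ``mu (1 - mu)``
    elementwise.  This is the uncorrected plug-in quantity; the fits store
    a degrees-of-freedom-inflated version in ``sigma2_diag`` when
    ``dof_correction`` is enabled.
    """
    link = link or fit.link
    if link.is_logit:
        return fit.mu * (1.0 - fit.mu)
    n = fit.residuals.shape[0]
    return np.full(n, fit.residuals @ fit.residuals / n)
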