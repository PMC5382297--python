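"""Tail probabilities for the score statistics and p-value combination.

The variance-component score statistic is a quadratic form in null
residuals and follows, under the null, a mixture of independent 1-df
chi-squares :math:`\\sum_{i=1}^s \\lambda_i \\chi^2_{1,i}` whose weights are
the non-zero eigenvalues of the variance-projected kernel.  Tail
probabilities are computed by the Liu et al. moment-matching approximation
(the 2009 refinement with a non-central chi-square surrogate).  The two
independent score p-values are merged with Fisher's or Tippett's rule,
expressed here as combined p-values so that downstream FDR has continuous
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ChiSquareMixture",
    "mixture_sf",
    "mixture_sf_mc",
    "combine_fisher",
    "combine_tippett",
    "P_FLOOR",
    "DEFAULT_SEED",
]

P_FLOOR = 1e-300          # clamp for log-combination stability
DEFAULT_SEED = 20170406   # default seed of the stochastic oracles


@dataclass(frozen=True)
class ChiSquareMixture:
    """Mixture law ``sum_i w_i chi^2_(1,i)`` with positive weights, sorted descending."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if w.size and (not np.isfinite(w).all() or (w <= 0).any()):
            raise ValueError("mixture weights must be positive and finite")
        object.__setattr__(self, "weights", np.sort(w)[::-1])

    @property
    def is_degenerate(self) -> bool:
        return self.weights.size == 0


def _liu_params(w: np.ndarray) -> tuple[float, float, float, float, float]:
    """Moment-match the mixture to a (non-central) chi-square surrogate.

    Returns (mu_Q, sigma_Q, df, ncp, sigma_X) where the surrogate is
    ``chi2(df, ncp)`` with mean ``df + ncp`` and sd ``sigma_X``.
    """
    c1 = w.sum()
    c2 = (w ** 2).sum()
    c3 = (w ** 3).sum()
    c4 = (w ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        ncp = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * ncp
    else:
        # skewness-matched central surrogate (the 2009 paper's other branch)
        ncp = 0.0
        df = c2 ** 3 / c3 ** 2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    sigma_x = np.sqrt(2.0 * (df + 2.0 * ncp))
    return mu_q, sigma_q, df, ncp, sigma_x


def mixture_sf(x: float | np.ndarray, mixture: ChiSquareMixture) -> float | np.ndarray:
    """P(sum_i w_i chi^2_1 >= x) by the Liu moment-matching approximation.

    Matches the first four cumulants of the mixture to a non-central
    chi-square and evaluates its survival function; exact when the mixture
    has a single component.  ``mixture_sf(0) = 1``; monotone non-increasing.
    Vectorised over ``x``.
    """
    if mixture.is_degenerate:
        raise ValueError("empty mixture: no positive weights (degenerate statistic)")
    x_arr = np.asarray(x, dtype=float)
    mu_q, sigma_q, df, ncp, sigma_x = _liu_params(mixture.weights)
    t = (x_arr - mu_q) / sigma_q
    p = stats.ncx2.sf(t * sigma_x + df + ncp, df, ncp)
    p = np.where(x_arr <= 0.0, 1.0, np.clip(p, 0.0, 1.0))
    return float(p) if np.isscalar(x) or x_arr.ndim == 0 else p


def mixture_sf_mc(x: float, mixture: ChiSquareMixture, reps: int = 10 ** 6,
                  seed: int = DEFAULT_SEED) -> float:
    """Monte-Carlo exceedance probability of the chi-square mixture.

    Independent validation oracle for :func:`mixture_sf`; deterministic for
    a given seed.
    """
    if reps < 10 ** 4:
        raise ValueError("use at least 10^4 draws for a meaningful tail estimate")
    rng = np.random.default_rng(seed)
    w = mixture.weights
    # draw in blocks to bound memory at ~8 MB
    block = max(1, 10 ** 6 // max(1, w.size))
    exceed = 0
    done = 0
    while done < reps:
        b = min(block, reps - done)
        draws = rng.chisquare(1.0, size=(b, w.size)) @ w
        exceed += int((draws >= x).sum())
        done += b
    return exceed / reps


def _validate_p(p: float, name: str) -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name}={p} outside [0, 1]")
    return max(p, P_FLOOR)


def combine_fisher(p_pi: float, p_tau: float) -> float:
    """Fisher combination of two independent p-values.

    The statistic ``-2 log p_pi - 2 log p_tau`` is chi-square with 4 df
    under the joint null; the combined p-value is its survival probability,
    so the rejection rule "statistic >= chi2_{4,alpha}" is recovered at
    every alpha.
    """
    p1 = _validate_p(p_pi, "p_pi")
    p2 = _validate_p(p_tau, "p_tau")
    stat = -2.0 * (np.log(p1) + np.log(p2))
    return float(max(stats.chi2.sf(stat, df=4), P_FLOOR))


def combine_tippett(p_pi: float, p_tau: float) -> float:
    """Tippett (minimum) combination of two independent p-values.

    Rejecting when ``min(p_pi, p_tau) <= 1 - (1 - alpha)^(1/2)`` is
    equivalent to the combined p-value ``1 - (1 - min)^2``.
    """
    p1 = _validate_p(p_pi, "p_pi")
    p2 = _validate_p(p_tau, "p_tau")
    m = min(p1, p2)
    # expm1 form keeps precision for tiny m
    return float(max(-np.expm1(2.0 * np.log1p(-m)), P_FLOOR)) if m < 1.0 else 1.0
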