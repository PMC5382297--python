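"""Storey q-values for voxelwise (or gene-wise) p-value collections.

Storey's procedure estimates the proportion ``pi0`` of true nulls from the
flat right tail of the p-value histogram, ``pi0 = #{p > lambda} / (m (1 -
lambda))``, and rescales the Benjamini-Hochberg step-up adjustment by it:
``q_(i) = min_{j >= i} pi0 m p_(j) / j``.  With ``pi0`` forced to 1 the
q-values reduce exactly to Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QValueResult", "storey_qvalues", "threshold_map"]

DEFAULT_LAMBDA = 0.5


@dataclass
class QValueResult:
    qvalues: np.ndarray
    pi0: float
    lambda_param: float | None
    pvalues: np.ndarray

    def threshold_mask(self, cutoff: float) -> np.ndarray:
        return threshold_map(self, cutoff)


def _pi0_smoother(pvals: np.ndarray) -> float:
    """Automatic pi0: cubic-smoothed pi0(lambda) extrapolated to lambda -> 1."""
    from scipy.interpolate import UnivariateSpline

    lams = np.arange(0.05, 0.96, 0.05)
    m = pvals.size
    pi0s = np.array([(pvals > l).sum() / (m * (1.0 - l)) for l in lams])
    spl = UnivariateSpline(lams, pi0s, k=3)
    return float(spl(lams.max()))


def storey_qvalues(pvals: np.ndarray, lambda_param: float | None = DEFAULT_LAMBDA,
                   pi0: float | None = None) -> QValueResult:
    """Storey FDR q-values.

    Parameters
    ----------
    pvals : p-values in [0, 1].
    lambda_param : tuning point for the pi0 estimate (default 0.5); ``None``
        selects the smoother-based automatic estimate.
    pi0 : override the estimate (``pi0=1`` reproduces Benjamini-Hochberg).
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambda_param is None:
            pi0 = _pi0_smoother(p)
        else:
            if not (0.0 < lambda_param < 1.0):
                raise ValueError("lambda must be in (0, 1)")
            pi0 = (p > lambda_param).sum() / (m * (1.0 - lambda_param))
    # clamp to (0, 1]: at least one effective null test, never above 1
    pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueResult(q, pi0, lambda_param, p)


def threshold_map(q: QValueResult, cutoff: float) -> np.ndarray:
    """Boolean discovery mask at q <= cutoff."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    return q.qvalues <= cutoff
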