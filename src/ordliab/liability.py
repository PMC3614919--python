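r"""Ordinal probit (threshold) likelihood and its normal pseudo-data form.

An ordinal phenotype with C categories is modeled through an unobserved
liability :math:`\lambda = \eta + \epsilon`, :math:`\epsilon \sim N(0, 1)`:
category c is observed iff the liability falls in :math:`(t_{c-1}, t_c]`
for cut points :math:`-\infty = t_0 < t_1 < \dots < t_{C-1} < t_C =
+\infty`.  The residual variance is fixed at 1 — the liability scale is
unobservable, so its unit is a free choice.

Under the probit link the category probabilities are

.. math:: p_c(\eta) = \Phi(t_c - \eta) - \Phi(t_{c-1} - \eta),

and the mixed-model machinery works on a local quadratic (normal)
approximation of the resulting log-likelihood: at a current linear
predictor each observation is replaced by a working response
:math:`y^* = \eta + g/w` with weight :math:`w`, where g is the score
:math:`\partial \log p_{y}/\partial \eta` and w the (observed, falling
back to expected) information.  This is the classic linearization used to
fit generalized linear mixed models by iteratively reweighted normal
steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: probability floor applied before taking logs
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class Thresholds:
    """Strictly increasing liability-scale cut points (length C-1)."""

    t: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.atleast_1d(np.asarray(self.t, dtype=float)))
        if not np.all(np.isfinite(self.t)):
            raise ValueError("thresholds must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got {self.t}")

    @property
    def n_categories(self) -> int:
        return len(self.t) + 1

    def padded(self) -> np.ndarray:
        """Cut points with the infinite end points attached."""
        return np.concatenate(([-np.inf], self.t, [np.inf]))


@dataclass
class PseudoData:
    """Working normal data: response ``ystar``, weight ``w``, expansion
    point ``eta``."""

    ystar: np.ndarray
    w: np.ndarray
    eta: np.ndarray


def category_probabilities(eta, th: Thresholds) -> np.ndarray:
    """Probability of each ordinal category given linear predictor(s).

    Returns an array of shape ``(n, C)`` for vector ``eta`` (or ``(C,)``
    for a scalar); rows sum to 1 by the telescoping of the normal CDF.
    """
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    cuts = th.padded()[None, :] - eta_arr[:, None]
    cdf = stats.norm.cdf(cuts)
    p = np.diff(cdf, axis=1)
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(eta) or np.asarray(eta).ndim == 0:
        return p[0]
    return p


def ordinal_loglik(y: np.ndarray, eta: np.ndarray, th: Thresholds) -> float:
    """Exact ordinal probit log-likelihood Σ_j log p_{y_j}(η_j)."""
    y = np.asarray(y, dtype=int)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError(f"length mismatch: y {y.shape} vs eta {eta.shape}")
    p = category_probabilities(eta, th)
    py = p[np.arange(len(y)), y - 1]
    return float(np.sum(np.log(np.maximum(py, PROB_FLOOR))))


def _score_curvature(y: np.ndarray, eta: np.ndarray, th: Thresholds):
    """Per-observation score and curvature of log p_y in η.

    Score  g = (φ(a) − φ(b)) / p  with a = t_{c−1}−η, b = t_c−η.
    Curvature w = −∂² log p/∂η² = g² − p''/p, with
    p'' = a·φ(a) − b·φ(b) (infinite cut points contribute 0).
    """
    pad = th.padded()
    a = pad[y - 1] - eta
    b = pad[y] - eta
    a_fin = np.where(np.isfinite(a), a, 0.0)
    b_fin = np.where(np.isfinite(b), b, 0.0)
    phi_a = np.where(np.isfinite(a), stats.norm.pdf(a_fin), 0.0)
    phi_b = np.where(np.isfinite(b), stats.norm.pdf(b_fin), 0.0)
    p_exact = np.maximum(stats.norm.cdf(b) - stats.norm.cdf(a), PROB_FLOOR)
    # the score/curvature denominator is floored higher: in such a deep tail
    # the quadratic expansion is meaningless anyway and a huge finite weight
    # pins the observation just as well, without float overflow
    p = np.maximum(p_exact, 1e-12)
    g = (phi_a - phi_b) / p
    ppp = a_fin * phi_a - b_fin * phi_b  # second derivative of p in η
    w = g * g - ppp / p
    return g, w, p_exact


def _expected_information(eta: np.ndarray, th: Thresholds) -> np.ndarray:
    """Fisher information of the ordinal probit in η: Σ_c (p_c')²/p_c."""
    eta = np.asarray(eta, dtype=float)
    pad = th.padded()
    cuts = pad[None, :] - eta[:, None]
    pdf = np.where(np.isfinite(cuts), stats.norm.pdf(np.nan_to_num(cuts)), 0.0)
    p = np.maximum(np.diff(stats.norm.cdf(cuts), axis=1), PROB_FLOOR)
    dp = pdf[:, :-1] - pdf[:, 1:]  # ∂p_c/∂η
    return np.sum(dp * dp / p, axis=1)


def pseudo_data(
    y: np.ndarray, eta: np.ndarray, th: Thresholds, floor: float = 1e-8
) -> PseudoData:
    """Build the working normal response and weights at expansion point η.

    The weight is the observed information, replaced by the expected
    information wherever it is non-positive, and floored at ``floor``.
    """
    y = np.asarray(y, dtype=int)
    eta = np.asarray(eta, dtype=float)
    g, w, _ = _score_curvature(y, eta, th)
    bad = w <= 0
    if bad.any():
        w = np.where(bad, _expected_information(eta, th), w)
    w = np.maximum(w, floor)
    ystar = eta + g / w
    return PseudoData(ystar=ystar, w=w, eta=eta.copy())


def thresholds_from_frequencies(freqs) -> Thresholds:
    """Cut points matching a target category distribution at η = 0.

    ``t_c = Φ⁻¹(cumulative proportion through category c)``.  A zero
    weight in a leading or trailing category would put a cut at ±∞, which
    is rejected.
    """
    f = np.asarray(freqs, dtype=float)
    if len(f) < 2:
        raise ValueError("need at least 2 categories")
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("category weights must be nonnegative with positive sum")
    cum = np.cumsum(f)[:-1] / f.sum()
    if np.any(cum <= 0) or np.any(cum >= 1):
        raise ValueError(
            "zero-weight leading/trailing categories give infinite thresholds"
        )
    return Thresholds(t=stats.norm.ppf(cum))
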