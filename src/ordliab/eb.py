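r"""Empirical-Bayes EM loop over effect blocks, variances, thresholds, β.

Every locus block of allelic (or allele-by-environment) effects
:math:`\gamma_k` is random with its own variance :math:`\sigma_k^2` under
a scaled-inverse-chi-square hyperprior with constants (τ, ω); fixed
effects β (environment, population structure) and the thresholds are
unpenalized.  One outer cycle linearizes the ordinal probit likelihood
into pseudo-data at the current linear predictor and then sweeps:

1. each block's posterior mean and the E-step quadratic
   :math:`E(\gamma_k^\top\gamma_k) = \hat\gamma_k^\top\hat\gamma_k +
   \mathrm{tr}\,C_k`,
2. each variance's posterior mode
   :math:`(E(\gamma_k^\top\gamma_k)+\omega)/(m_k+2+\tau)`,
3. a damped Newton step on the thresholds against the exact likelihood,
4. generalized least squares for β.

Shrinkage does model selection: blocks with no signal collapse toward
zero, so all markers stay in the model simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import DesignBlocks, ModelConfig
from .liability import (
    PROB_FLOOR,
    PseudoData,
    Thresholds,
    category_probabilities,
    ordinal_loglik,
    pseudo_data,
    thresholds_from_frequencies,
)

SIGMA2_FLOOR = 1e-10


@dataclass
class EBState:
    """Current (or converged) parameter set of the EM-EB iteration."""

    beta: np.ndarray
    gamma: list[np.ndarray]
    sigma2: np.ndarray
    th: Thresholds
    iteration: int = 0
    converged: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    def linear_predictor(self, design: DesignBlocks) -> np.ndarray:
        eta = design.x @ self.beta
        for zk, gk in zip(design.z, self.gamma):
            eta = eta + zk @ gk
        return eta


def update_effect_block(
    k: int, state: EBState, pd: PseudoData, design: DesignBlocks
) -> tuple[np.ndarray, float]:
    """Posterior mean of block k and the E-step quadratic E(γᵀγ).

    With W = diag(w) and partial residual r_k (working response minus
    every other term's fit), the block posterior is normal with mean
    ``(ZᵀWZ + σ⁻²I)⁻¹ ZᵀW r_k`` and covariance ``(ZᵀWZ + σ⁻²I)⁻¹``.
    """
    zk = design.z[k]
    r = pd.ystar - design.x @ state.beta
    for l, (zl, gl) in enumerate(zip(design.z, state.gamma)):
        if l != k:
            r = r - zl @ gl
    return _block_solve(zk, pd.w, r, state.sigma2[k])


def _block_solve(zk, w, r, sigma2):
    zw = zk * w[:, None]
    a = zk.T @ zw + np.eye(zk.shape[1]) / sigma2
    b = zw.T @ r
    cov = np.linalg.inv(a)
    gamma_hat = cov @ b
    e_quad = float(gamma_hat @ gamma_hat + np.trace(cov))
    return gamma_hat, e_quad


def update_variance(
    e_quadratic: float, m_k: int, tau: float = 0.0, omega: float = 0.0
) -> float:
    """Posterior mode of σ_k² under the scaled-inverse-chi-square prior."""
    if e_quadratic < 0:
        raise ValueError("E(gamma'gamma) must be >= 0")
    return max((e_quadratic + omega) / (m_k + 2.0 + tau), SIGMA2_FLOOR)


def update_beta(state: EBState, pd: PseudoData, design: DesignBlocks) -> np.ndarray:
    """GLS fixed-effect update: β̂ = (XᵀWX)⁻¹ XᵀW (y* − Σ Zγ)."""
    x = design.x
    r = pd.ystar.copy()
    for zl, gl in zip(design.z, state.gamma):
        r = r - zl @ gl
    xw = x * pd.w[:, None]
    xtwx = x.T @ xw
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError(
            f"fixed-effect design is rank deficient (columns {design.x_labels})"
        )
    return np.linalg.solve(xtwx, xw.T @ r)


def _threshold_gradient(t: np.ndarray, y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """∂/∂t_c of the exact ordinal log-likelihood, η held fixed."""
    th = Thresholds(t=t)
    pad = th.padded()
    a = pad[y - 1] - eta
    b = pad[y] - eta
    p = np.maximum(
        stats.norm.cdf(b) - stats.norm.cdf(a), PROB_FLOOR
    )
    phi_b = np.where(np.isfinite(b), stats.norm.pdf(b), 0.0)
    phi_a = np.where(np.isfinite(a), stats.norm.pdf(a), 0.0)
    grad = np.zeros(len(t))
    # cut c bounds category c above (+φ(b)/p) and category c+1 below (−φ(a)/p)
    for c in range(1, len(t) + 1):
        upper = y == c
        lower = y == c + 1
        grad[c - 1] = np.sum(phi_b[upper] / p[upper]) - np.sum(phi_a[lower] / p[lower])
    return grad


def update_thresholds(
    state: EBState,
    y: np.ndarray,
    eta: np.ndarray,
    max_newton: int = 1,
) -> tuple[Thresholds, bool]:
    """Damped Newton step(s) on the thresholds at fixed linear predictor.

    The Newton direction uses the analytic gradient and a
    finite-difference Hessian; the step is halved until the exact
    log-likelihood does not decrease and the ordering t_1 < … < t_{C-1}
    survives.  Returns (thresholds, updated_flag); when no admissible
    step exists the previous thresholds are kept.
    """
    t = state.th.t.copy()
    y = np.asarray(y, dtype=int)
    updated = False
    for _ in range(max_newton):
        ll0 = ordinal_loglik(y, eta, Thresholds(t=t))
        grad = _threshold_gradient(t, y, eta)
        h = 1e-5
        hess = np.zeros((len(t), len(t)))
        for i in range(len(t)):
            tp, tm = t.copy(), t.copy()
            tp[i] += h
            tm[i] -= h
            hess[:, i] = (
                _threshold_gradient(tp, y, eta) - _threshold_gradient(tm, y, eta)
            ) / (2 * h)
        hess = (hess + hess.T) / 2
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.abs(np.diag(hess)).max(), 1.0)
        if not np.all(np.isfinite(step)):
            break
        direction = -step  # Newton for a maximum: t − H⁻¹g
        scale = 1.0
        accepted = False
        for _half in range(30):
            cand = t + scale * direction
            if np.all(np.diff(cand) > 0):
                ll = ordinal_loglik(y, eta, Thresholds(t=cand))
                if ll >= ll0 - 1e-12:
                    t = cand
                    accepted = True
                    updated = True
                    break
            scale /= 2
        if not accepted:
            break
    return Thresholds(t=t), updated


def _initial_thresholds(y: np.ndarray, n_categories: int) -> Thresholds:
    """Empirical-quantile starting thresholds, 0.5-smoothed so that empty
    categories cannot produce ties or infinities."""
    counts = np.bincount(np.asarray(y, dtype=int), minlength=n_categories + 1)[1:]
    return thresholds_from_frequencies(counts + 0.5)


def fit(
    design: DesignBlocks,
    y: np.ndarray,
    config: ModelConfig | None = None,
    n_categories: int | None = None,
) -> EBState:
    """Run the EM-EB cycle to convergence.

    Parameters
    ----------
    design
        Output of :func:`ordliab.design.build_design`.
    y
        Observation-level categories (1..C), aligned with design rows.
    n_categories
        C; inferred as ``max(y)`` when omitted.

    Convergence is declared when the largest absolute change across
    (β, every γ, thresholds) drops below ``config.convergence_tol``;
    the variance components are excluded from the metric since they move
    on a slower scale.  Non-convergence returns the last state with
    ``converged=False`` and a warning.
    """
    config = config or ModelConfig()
    y = np.asarray(y, dtype=int)
    c = n_categories if n_categories is not None else int(y.max())
    rng = np.random.default_rng(config.rng_seed)

    if config.beta_init == "uniform":
        beta = rng.uniform(0.0, 1.0, size=design.x.shape[1])
    else:
        beta = np.zeros(design.x.shape[1])
    gamma = [np.zeros(zk.shape[1]) for zk in design.z]
    sigma2 = rng.gamma(shape=2.0, scale=0.5, size=design.n_blocks)
    sigma2 = np.maximum(sigma2, 1e-4)
    th = _initial_thresholds(y, c)

    state = EBState(beta=beta, gamma=gamma, sigma2=sigma2, th=th)
    x = design.x
    for it in range(1, config.max_iter + 1):
        eta = state.linear_predictor(design)
        pd = pseudo_data(y, eta, state.th, floor=config.weight_floor)

        old = np.concatenate([state.beta, *state.gamma, state.th.t])

        # step 2+3: sweep blocks, keeping the partial residual incremental
        fitted_random = eta - x @ state.beta
        resid = pd.ystar - x @ state.beta - fitted_random
        for k, zk in enumerate(design.z):
            rk = resid + zk @ state.gamma[k]
            gk, e_quad = _block_solve(zk, pd.w, rk, state.sigma2[k])
            resid = rk - zk @ gk
            state.gamma[k] = gk
            state.sigma2[k] = update_variance(
                e_quad, zk.shape[1], config.tau, config.omega
            )

        # step 4: thresholds against the exact likelihood at refreshed η
        eta_now = state.linear_predictor(design)
        state.th, _ = update_thresholds(state, y, eta_now)

        # step 5: fixed effects on the cycle's pseudo-data
        state.beta = update_beta(state, pd, design)

        state.iteration = it
        state.loglik_trace.append(
            ordinal_loglik(y, state.linear_predictor(design), state.th)
        )
        new = np.concatenate([state.beta, *state.gamma, state.th.t])
        if np.max(np.abs(new - old)) < config.convergence_tol:
            state.converged = True
            break

    if not state.converged:
        warnings.warn(
            f"EM-EB did not converge within {config.max_iter} iterations",
            stacklevel=2,
        )
    return state
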