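"""QTL declaration and downstream breeding inference.

Shrinkage in the EM-EB fit leaves most blocks near zero; a two-stage
procedure turns the survivors into declared QTL.  Stage 1 keeps every
block whose largest absolute allele effect exceeds a cutoff.  Stage 2
refits the reduced model — only the surviving blocks, unpenalized, plus
fixed effects and thresholds — by maximum likelihood, and tests each
surviving block with a likelihood-ratio test against the model without
it; LOD = LR / (2 ln 10), declared at LOD >= 2 by default.

Downstream utilities mine the elite (most favorable) allele per declared
QTL, rank hypothetical crosses by the best recombinant inbred line they
could produce, and test grade-by-factor independence with Pearson's
chi-square.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .datamodel import (
    BLOCK_MQ,
    DesignBlocks,
    GenotypePanel,
    ModelConfig,
)
from .eb import EBState, _threshold_gradient
from .liability import Thresholds, _score_curvature

LOD_PER_LR = 1.0 / (2.0 * math.log(10.0))


@dataclass
class QtlCall:
    """One declared QTL: test statistics plus per-allele effects."""

    locus_name: str
    kind: str  # "MQ" or "QE"
    block_index: int
    lr: float
    lod: float
    pve: float
    allele_effects: dict[str, float]
    sigma2: float
    var_component: float
    chromosome: str | None = None
    position_cm: float | None = None
    elite_allele: str | None = None
    elite_effect: float | None = None
    elite_carrier: str | None = None
    elite_carriers: list[str] = field(default_factory=list)


def stage1_select(
    state: EBState, threshold: float, design: DesignBlocks | None = None
) -> list[tuple[int, float]]:
    """Blocks whose largest |effect| exceeds the stage-1 cutoff.

    Returns ``[(block_index, max_abs_effect), ...]`` in block order.
    """
    out = []
    for k, gk in enumerate(state.gamma):
        m = float(np.max(np.abs(gk))) if len(gk) else 0.0
        if m > threshold:
            out.append((k, m))
    return out


# ---------------------------------------------------------------------------
# reduced-model maximum likelihood


@dataclass
class MLFit:
    loglik: float
    coef: np.ndarray
    thresholds: Thresholds
    slices: dict[int, slice]
    n_fixed: int
    converged: bool


def _reduced_fixed(design: DesignBlocks) -> np.ndarray:
    """Fixed columns in reference coding: the first environment indicator
    is dropped (its level is absorbed by the thresholds), removing the
    location aliasing between a full-rank environment design and free
    cut points.  The likelihood value is unchanged."""
    n_env = len(design.environments)
    return design.x[:, 1:] if n_env >= 1 else design.x


def ml_ordinal_fit(
    columns: np.ndarray,
    y: np.ndarray,
    n_categories: int,
    start_coef: np.ndarray | None = None,
    start_t: np.ndarray | None = None,
) -> tuple[float, np.ndarray, Thresholds, bool]:
    """Maximize the exact ordinal probit likelihood over (coef, thresholds).

    Thresholds are parametrized as (t_1, log increments) so the ordering
    constraint is built in; optimization is L-BFGS-B with analytic
    gradients.
    """
    y = np.asarray(y, dtype=int)
    n, p = columns.shape
    c = n_categories
    if start_t is None:
        counts = np.bincount(y, minlength=c + 1)[1:] + 0.5
        cum = np.cumsum(counts)[:-1] / counts.sum()
        start_t = stats.norm.ppf(cum)
    if start_coef is None:
        start_coef = np.zeros(p)
    a0 = np.concatenate(
        [[start_t[0]], np.log(np.maximum(np.diff(start_t), 1e-3))]
    )
    x0 = np.concatenate([start_coef, a0])

    def unpack(params):
        coef = params[:p]
        a = params[p:]
        t = np.concatenate([[a[0]], a[0] + np.cumsum(np.exp(a[1:]))])
        return coef, t

    def nll_and_grad(params):
        coef, t = unpack(params)
        th = Thresholds(t=t)
        eta = columns @ coef
        g, _, prob = _score_curvature(y, eta, th)
        nll = -float(np.sum(np.log(prob)))
        grad_coef = columns.T @ g  # d loglik / d coef
        gt = _threshold_gradient(t, y, eta)
        # chain rule to (t1, log-increments): t_c = t_1 + Σ_{i<=c} exp(a_i)
        grad_a = np.zeros(c - 1)
        grad_a[0] = gt.sum()
        if c > 2:
            rev = np.cumsum(gt[::-1])[::-1]
            grad_a[1:] = np.exp(params[p + 1:]) * rev[1:]
        return nll, -np.concatenate([grad_coef, grad_a])

    res = optimize.minimize(
        nll_and_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    coef, t = unpack(res.x)
    return -float(res.fun), coef, Thresholds(t=t), bool(res.success)


def fit_reduced_ml(
    selected: list[int],
    design: DesignBlocks,
    y: np.ndarray,
    n_categories: int,
    state: EBState | None = None,
) -> MLFit:
    """ML fit of the reduced model containing only the selected blocks."""
    xf = _reduced_fixed(design)
    cols = [xf]
    slices: dict[int, slice] = {}
    pos = xf.shape[1]
    for k in selected:
        zk = design.z[k]
        slices[k] = slice(pos, pos + zk.shape[1])
        cols.append(zk)
        pos += zk.shape[1]
    columns = np.hstack(cols) if cols else np.zeros((len(y), 0))
    start_coef = None
    start_t = None
    if state is not None:
        start_coef = np.zeros(pos)
        # reference-coded env effects relative to the first environment
        n_env = len(design.environments)
        if n_env >= 1 and len(state.beta) >= n_env:
            start_coef[: n_env - 1] = state.beta[1:n_env] - state.beta[0]
            start_coef[n_env - 1 : xf.shape[1]] = state.beta[n_env:]
        for k in selected:
            start_coef[slices[k]] = state.gamma[k]
        start_t = state.th.t - (state.beta[0] if n_env >= 1 else 0.0)
    ll, coef, th, ok = ml_ordinal_fit(
        columns, y, n_categories, start_coef=start_coef, start_t=start_t
    )
    return MLFit(
        loglik=ll, coef=coef, thresholds=th, slices=slices,
        n_fixed=xf.shape[1], converged=ok,
    )


def lrt_locus(
    selected: list[int],
    design: DesignBlocks,
    y: np.ndarray,
    target: int,
    n_categories: int,
    state: EBState | None = None,
    full_fit: MLFit | None = None,
) -> tuple[float, float]:
    """LR and LOD for dropping one block from the reduced ML model.

    The null fixes every effect of the target block at zero; both fits
    are exact ordinal probit maximum likelihood.  LR is floored at 0
    (the null is nested, so a negative value can only be numerical).
    """
    if target not in selected:
        raise ValueError(f"target block {target} is not among the selected blocks")
    if full_fit is None:
        full_fit = fit_reduced_ml(selected, design, y, n_categories, state)
    null_fit = fit_reduced_ml(
        [k for k in selected if k != target], design, y, n_categories, state
    )
    if not (full_fit.converged and null_fit.converged):
        warnings.warn(
            f"ML fit for block {target} LRT did not fully converge", stacklevel=2
        )
    lr = max(2.0 * (full_fit.loglik - null_fit.loglik), 0.0)
    return lr, lr * LOD_PER_LR


def pve(state: EBState, block: int, design: DesignBlocks) -> float:
    """Percent of liability variance attributed to one block.

    ``100 · Var(Z_k γ_k) / (Σ_l Var(Z_l γ_l) + 1)`` with variances taken
    over observation rows and residual liability variance fixed at 1.
    """
    contribs = [zk @ gk for zk, gk in zip(design.z, state.gamma)]
    total = sum(float(np.var(c)) for c in contribs)
    return 100.0 * float(np.var(contribs[block])) / (total + 1.0)


def block_variance_component(state: EBState, block: int, design: DesignBlocks) -> float:
    """Var over rows of the block's fitted contribution Z_k γ̂_k."""
    return float(np.var(design.z[block] @ state.gamma[block]))


# ---------------------------------------------------------------------------
# elite alleles and cross prediction


def _allele_of_label(label: str) -> str:
    """Strip the environment part of a QE column label."""
    return label.split(" x ")[0]


def _carriers(panel: GenotypePanel, locus_name: str, allele: str) -> list[str]:
    j = panel.locus_index(locus_name)
    return [
        c for c, a in zip(panel.cultivar_ids, panel.alleles[:, j]) if str(a) == allele
    ]


def elite_alleles(
    calls: list[QtlCall], panel: GenotypePanel, orientation: str = "minimize"
) -> list[QtlCall]:
    """Annotate each call with its most favorable allele and a carrier.

    ``orientation="minimize"`` (default, appropriate when low grades are
    the breeding goal) picks the allele with the smallest effect;
    ``"maximize"`` the largest.  Ties break toward the allele with more
    carriers in the panel.  For QE calls the elite unit is an
    allele-by-environment pair; carriers are determined by the allele
    part alone.
    """
    if orientation not in ("minimize", "maximize"):
        raise ValueError("orientation must be 'minimize' or 'maximize'")
    sign = 1.0 if orientation == "minimize" else -1.0
    for call in calls:
        best = None
        for label, effect in call.allele_effects.items():
            allele = _allele_of_label(label)
            carriers = _carriers(panel, call.locus_name, allele)
            if not carriers:
                continue
            key = (sign * effect, -len(carriers))
            if best is None or key < best[0]:
                best = (key, label, effect, carriers)
        assert best is not None, "a declared QTL always has observed alleles"
        _, label, effect, carriers = best
        call.elite_allele = label
        call.elite_effect = effect
        call.elite_carrier = carriers[0]
        call.elite_carriers = carriers
    return calls


def predict_best_cross(
    calls: list[QtlCall],
    panel: GenotypePanel,
    parents_per_cross: int = 2,
    orientation: str = "minimize",
    candidates: list[str] | None = None,
    top: int = 10,
) -> list[dict]:
    """Rank parent sets by the best recombinant inbred line they allow.

    For a candidate parent set, the ideal RIL carries at each declared
    locus the most favorable allele present among the parents; the cross
    score is the sum of those allele effects over loci (0 where no parent
    carries an allele with an estimated effect).  Crosses are ranked best
    first and flagged when they pyramid every elite allele.
    """
    if not 2 <= parents_per_cross <= 4:
        raise ValueError("parents_per_cross must be between 2 and 4")
    sign = 1.0 if orientation == "minimize" else -1.0
    cands = candidates if candidates is not None else list(panel.cultivar_ids)

    # per call: cultivar -> effect of its allele (NaN when not estimable)
    call_effects: list[dict[str, float]] = []
    call_elite: list[float] = []
    for call in calls:
        j = panel.locus_index(call.locus_name)
        eff_by_allele: dict[str, float] = {}
        for label, e in call.allele_effects.items():
            a = _allele_of_label(label)
            # a QE block has several labels per allele; keep the favorable one
            if a not in eff_by_allele or sign * e < sign * eff_by_allele[a]:
                eff_by_allele[a] = e
        call_effects.append(
            {
                c: eff_by_allele[str(panel.alleles[panel.row_index(c), j])]
                for c in cands
                if str(panel.alleles[panel.row_index(c), j]) in eff_by_allele
            }
        )
        call_elite.append(min(sign * e for e in eff_by_allele.values()))

    results = []
    for combo in itertools.combinations(cands, parents_per_cross):
        score = 0.0
        pyramids = True
        for effs, elite in zip(call_effects, call_elite):
            vals = [sign * effs[c] for c in combo if c in effs]
            if vals:
                best = min(vals)
                score += best
                pyramids = pyramids and (best <= elite + 1e-12)
            else:
                pyramids = False
        results.append(
            {"parents": combo, "score": sign * score, "pyramids_all_elite": pyramids}
        )
    results.sort(key=lambda r: sign * r["score"])
    return results[:top] if top else results


# ---------------------------------------------------------------------------


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2-D count table.

    Rows/columns with a zero margin are dropped with a warning; the
    statistic, (R-1)(C-1) degrees of freedom and upper-tail p are
    returned.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not (keep_r.all() and keep_c.all()):
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# end-to-end mapping pipeline


@dataclass
class FitResult:
    """Converged model plus the declared QTL."""

    state: EBState
    design: DesignBlocks
    calls: list[QtlCall]
    selected: list[tuple[int, float]]
    config: ModelConfig


def declare_qtl(
    state: EBState,
    design: DesignBlocks,
    y: np.ndarray,
    n_categories: int,
    config: ModelConfig,
    panel: GenotypePanel | None = None,
    orientation: str = "minimize",
) -> FitResult:
    """Two-stage selection + LRT, producing annotated QTL calls.

    Per-allele effects reported in the calls come from the reduced-model
    maximum-likelihood fit (all selected blocks present).
    """
    selected = stage1_select(state, config.stage1_threshold)
    sel_idx = [k for k, _ in selected]
    calls: list[QtlCall] = []
    if sel_idx:
        full = fit_reduced_ml(sel_idx, design, y, n_categories, state)
        for k in sel_idx:
            lr, lod = lrt_locus(
                sel_idx, design, y, k, n_categories, state, full_fit=full
            )
            if lod < config.lod_threshold:
                continue
            info = design.blocks[k]
            effects = dict(
                zip(info.labels, (full.coef[full.slices[k]]).tolist())
            )
            calls.append(
                QtlCall(
                    locus_name=info.locus_name,
                    kind=info.kind,
                    block_index=k,
                    lr=lr,
                    lod=lod,
                    pve=pve(state, k, design),
                    allele_effects=effects,
                    sigma2=float(state.sigma2[k]),
                    var_component=block_variance_component(state, k, design),
                )
            )
    if panel is not None:
        for call in calls:
            j = panel.locus_index(call.locus_name)
            call.chromosome = panel.loci[j].chromosome
            call.position_cm = panel.loci[j].position_cm
        elite_alleles(calls, panel, orientation)
    return FitResult(
        state=state, design=design, calls=calls,
        selected=selected, config=config,
    )


def calls_table(calls: list[QtlCall]):
    """QTL calls as a tidy DataFrame mirroring the usual report columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "marker": c.locus_name,
                "type": c.kind,
                "chromosome": c.chromosome,
                "position_cm": c.position_cm,
                "sigma2": c.sigma2,
                "variance": c.var_component,
                "LOD": c.lod,
                "PVE_percent": c.pve,
                "elite_allele": c.elite_allele,
                "effect": c.elite_effect,
                "carrier": c.elite_carrier,
            }
            for c in calls
        ]
    )
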