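# Methods

## Model

`ordliab` maps quantitative trait loci (QTL) for ordinal phenotypes in
panels of fully homozygous cultivars (inbred lines), where markers are
multi-allelic (typically SSR fragment sizes) and phenotypes are scored in
ordered grades across one or more environments (years).

The observed grade `y ∈ {1..C}` of line *j* in environment *e* is modeled
through an unobserved liability

    λ_je = x_je' β + Σ_k z_jk' γ_k + ε_je,    ε ~ N(0, 1),

with `y = c` iff `λ ∈ (t_{c-1}, t_c]` for strictly increasing thresholds
`t_1 < … < t_{C-1}` (and `t_0 = −∞`, `t_C = +∞`). The residual variance is
fixed at 1: the liability is unobservable, so its scale is a free
convention. Under the probit link the category probabilities are
`p_c = Φ(t_c − η) − Φ(t_{c-1} − η)`.

Fixed effects **β** are environment indicators and, optionally, K−1
columns of a population-structure membership matrix Q (computed
externally, e.g. by STRUCTURE; rows sum to 1, hence drop-one coding). No
global intercept is fitted: with free thresholds a free mean is not
identifiable, so the location lives in the thresholds. The environment
indicators are kept full-rank, which leaves one residual location
aliasing between β and the thresholds; the EM cycle is insensitive to it
(the likelihood is flat along that direction), and all reported
quantities — likelihood ratios, effects contrasts, centered thresholds —
are invariant to it. Reported threshold recoveries are therefore centered
as `t̂ − mean(Xβ̂)`.

Random effects come in blocks: per locus one main-effect (MQ) block with
one coefficient per observed allele, and — when at least two environments
are present — one locus-by-environment (QE) block with one coefficient
per allele×environment pair. With a single environment a QE block would
duplicate the MQ block column-for-column, so it is not built (flag
`qe=` on `build_design` overrides). A line with a missing allele call
contributes an all-zero row to that locus's blocks; the
`model_unknown_allele` flag instead treats "missing" as its own allele
class, for panels where a common null allele is believed real rather
than assay failure.

Each block `γ_k` is a priori `N(0, σ_k² I)` with its own variance, and
`σ_k²` carries a scaled-inverse-chi-square hyperprior with constants
(τ, ω). Defaults are τ = ω = 0, the non-informative choice whose
posterior mode is `E(γ_k'γ_k)/(m_k + 2)`; both constants are exposed in
`ModelConfig`. This hierarchy is what lets *all* marker blocks sit in the
model simultaneously: blocks without signal have their variance driven
toward zero and their effects shrunk out, which is the model-selection
mechanism.

## Estimation

The ordinal likelihood is handled through its local normal (pseudo-data)
approximation: at the current linear predictor η each observation is
replaced by a working response `y* = η + g/w` with weight `w`, where `g`
is the score `∂ log p_y/∂η` and `w` the observed information, falling
back to the expected (Fisher) information wherever the observed one is
non-positive and floored at `weight_floor` (default 1e-8). Probabilities
are floored at 1e-300 before logs; inside score/curvature the
denominator is floored at 1e-12 — in such a deep tail the quadratic
expansion carries no information and a large finite weight pins the
observation without float overflow.

One outer cycle then performs, in order:

1. **Effect blocks.** For each block in genome order (MQ then QE per
   locus), the posterior mean
   `γ̂_k = (Z_k'WZ_k + σ_k^{-2}I)^{-1} Z_k'W r_k` on the partial residual
   `r_k`, plus the E-step quadratic
   `E(γ_k'γ_k) = γ̂_k'γ̂_k + tr C_k` with `C_k` the posterior covariance.
2. **Variances.** `σ_k² = (E(γ_k'γ_k) + ω)/(m_k + 2 + τ)`, floored at
   1e-10.
3. **Thresholds.** One damped Newton step on the exact ordinal
   log-likelihood in t, holding η fixed; analytic gradient,
   finite-difference Hessian, step halving until the likelihood does not
   decrease and the ordering survives (otherwise the previous thresholds
   are kept).
4. **Fixed effects.** Generalized least squares on the working response
   with the random fits removed.

Pseudo-data are rebuilt once per outer cycle. Initialization: γ = 0,
β ~ U(0,1) per coordinate (a `beta_init="zero"` option exists), σ_k² from
Gamma(2, scale 0.5), thresholds from the empirical category quantiles
(counts smoothed by +0.5 so empty categories cannot produce ties or
infinite cuts). All draws come from one seeded generator
(`ModelConfig.rng_seed`); runs are bitwise reproducible.

Convergence is declared when the largest absolute change over
(β, all γ, thresholds) falls below `convergence_tol` (default 1e-6,
`max_iter` 1000). Variances are excluded from the metric — they move on
a slower scale. Note the conditional log-likelihood is *not* an ascent
function of this cycle: the iteration starts near the unpenalized fit
(diffuse variance draws) and shrinkage then lowers the conditional
likelihood as null blocks collapse. That is the estimator working as
designed; the trace is recorded for diagnostics and stabilizes at
convergence.

## QTL declaration

A two-stage test turns the shrunken fit into declared QTL:

1. **Stage 1.** Keep every block whose largest absolute effect exceeds
   `stage1_threshold` (default 0.05 on the liability scale; exposed in
   config because any such screening cutoff is a tuning choice).
2. **Stage 2.** Refit the reduced model — selected blocks unpenalized,
   plus fixed effects and free thresholds — by exact maximum likelihood,
   and test each selected block with a likelihood-ratio test against the
   model without it: `LR = 2(logL_full − logL_null)`, floored at 0, and
   `LOD = LR/(2 ln 10)`, declared at `lod_threshold` (default 2.0).

The ML fits run L-BFGS-B with analytic gradients on (coefficients, t_1,
log threshold increments), so the ordering constraint is built in.
Internally the first environment's indicator is dropped (reference
coding, its level absorbed by the thresholds) to remove the location
aliasing; the maximized likelihood is invariant to this. The fit was
cross-checked against an independent ordered-probit implementation
(statsmodels `OrderedModel`) to 1e-4 in log-likelihood.

Per declared QTL the package reports the LOD, the per-allele ML effects,
two variance summaries (the block's EB variance `σ̂_k²` and the realized
`Var(Z_k γ̂_k)` over observations), and the explained-variance share

    PVE_k = 100 · Var(Z_k γ̂_k) / (Σ_l Var(Z_l γ̂_l) + 1),

i.e. fitted genetic variance of the block over total fitted liability
variance with the unit residual.

**Elite alleles.** Per declared QTL the most favorable allele
(`orientation="minimize"` by default — for tolerance indices smaller is
better; QE calls use allele×environment pairs) with a representative
carrier (first in panel order) plus the full carrier list; ties break
toward the allele with more carriers. **Cross prediction.** For 2–4
parent sets, the best achievable recombinant inbred line takes the most
favorable available allele at each declared locus; crosses are ranked by
the summed effects and flagged when they pyramid every elite allele.
Enumeration is exhaustive over the candidate list, so restrict
`candidates` for large panels. **Independence tests.** Grade-by-year (or
grade-by-marker) contingency tables use Pearson's chi-square
(scipy, no continuity correction), dropping zero-margin rows/columns.

## Simulation engine

The validation design mirrors a two-tier pedigree: `n_founders` inbred
lines in linkage equilibrium (alleles uniform and independent per locus)
and `n_nonfounders` recombinant inbred lines (RILs), each bred from a
random founder pair. A RIL genome is a homozygous parental mosaic whose
origin switches between adjacent markers with probability
`R = 2r/(1+2r)`, `r = (1 − e^{−2d/100})/2` — the selfed-to-fixation
recombination fraction under the Haldane map at distance d cM. Selfing
is applied analytically rather than generation by generation; parent
pairs are drawn uniformly without replacement constraints (the pairing
scheme is otherwise unspecified in the reference design).

QTL sit on markers. Allele effects start equally spaced (−1…+1),
are centered against realized allele counts and scaled so the realized
genetic variance equals `h²·σ_P²`, with `σ_P² = 1/(1 − Σh²)` the total
phenotypic variance implied by a unit residual. Liability = genotypic
sum + N(0,1); thresholds from the target category frequencies are scaled
by the realized liability SD so the marginal grade proportions match the
design ratios whatever Σh². This scaling is first-order: the genotypic
part is discrete, so middle-category proportions can deviate by ~1–2%
when Σh² is large.

The reference scenario (`case1`) uses 100 founders, 200 RILs, three
100 cM chromosomes with markers every 10 cM (33 markers), three QTL at
50 cM with h² = 5/10/15%, and five grades in ratio 1:2:4:2:1 cut at
−1.2816, −0.5244, 0.5244, 1.2816. (The source design table is internally
inconsistent about genome length — 33 markers at 10 cM spacing over
three chromosomes implies 100 cM each — and that reading is used.)
Variants cover alternative grade distributions (`case2`), 2/6/9
categories (`case3`), panel size (`case4`) and the long-genome designs
(`case5`/`case6`: three 1000 cM chromosomes, 18 QTL with h² 1–15%).

`run_power_experiment` pushes each replicate through the full pipeline
(simulate → fit → two-stage LRT) and tallies per-QTL power (LOD ≥ 2 at
the true marker), FPR (false declarations over zero-effect blocks ×
replicates), centered threshold estimates and effect estimates.
Replicate r of a scenario seeds its generator with `[seed, r]`, so every
cell is reproducible and independent of execution order.

### What the simulator does and does not emulate

It reproduces the pedigree structure, multi-allelic markers, linkage,
variance-matched QTL and thresholded liabilities of the reference
validation design. It does **not** emulate population structure or
ecotype stratification (Q is an input in real analyses, never simulated
here), genotyping error or missingness, environment-specific effects
(simulated phenotypes use one environment, so QE blocks are exercised
only through real-data-shaped inputs and unit tests), epistasis, or
dominance (all lines homozygous by construction). Passing simulation
suites therefore demonstrate correct behavior under the model's own
assumptions, not robustness to structure confounding or assay artifacts.

## Problem sizes and numerical choices in the shipped checks

The shipped experiment harness fits use `convergence_tol=1e-4`,
`max_iter=200` — EM converges in ~30–50 cycles at n = 200 and the looser
tolerance changes LODs imperceptibly — with 20 replicates per cell for
power/FPR and monotonicity suites, and 5 replicates at n = 1000 for
threshold recovery. Threshold-recovery checks compare the *mean*
centered estimate over replicates with the generating cuts (±0.05): a
single replicate's estimator equals the empirical category quantiles,
whose sampling error at the outer cuts is itself ≈0.05 at n = 1000.
Monotonicity checks (power non-decreasing in heritability, category
count, sample size, founder count) allow a slack of one detection count
between adjacent cells, since cell estimates are binomial means. The
founder-count suite spreads its levels (6/25/100 founders): within a
narrow band the true power differences in this scaled design are below
any resolution attainable at reasonable replicate counts.

## Known limitations

- With one environment and full-rank environment coding, β and the
  thresholds share a flat direction; absolute values of either are not
  individually meaningful (centered quantities are).
- The EB variance mode with τ = ω = 0 can collapse to the floor for null
  blocks; this is intended (it is the selection mechanism), but it makes
  `σ̂_k²` of *selected* blocks a shrunken, not unbiased, variance
  estimate — hence the parallel `Var(Z_k γ̂_k)` report.
- Stage-2 ML refits all selected blocks jointly; with very many
  selected blocks at small n the reduced model can be rank-deficient
  along block/threshold aliasing directions. L-BFGS-B tolerates the flat
  directions, and likelihood *differences* remain well-defined.
- PVE is computed from the shrunken EB fit, so it is mildly conservative
  (simulated 10% QTL recover ≈8–10% on average).
- Cross prediction assumes additivity across loci and ignores linkage
  between declared QTL when projecting the best achievable RIL.
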