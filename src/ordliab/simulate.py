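"""Pedigree-based simulation engine and the power/FPR experiment harness.

The validation design: a base population of founder inbred lines in
linkage equilibrium (alleles drawn uniformly and independently per
locus), from which non-founder lines are bred as recombinant inbred
lines (RILs) — each the product of repeated self-pollination of a hybrid
between two randomly paired founders.  A RIL genome is a homozygous
mosaic of its two parents; along a chromosome the parental origin
switches between adjacent markers with the RIL recombination fraction

    R = 2r / (1 + 2r),      r = (1 - exp(-2 d / 100)) / 2,

r being the Haldane recombination fraction at map distance d cM.  QTL sit
on markers; their allele effects are equally spaced, centered on the
realized allele frequencies and scaled so each QTL explains its target
share h² of the total phenotypic (liability) variance.  Liabilities add
a unit-variance normal residual and are cut into ordinal categories at
thresholds matching a target category-frequency profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import eb
from .datamodel import BLOCK_MQ, GenotypePanel, LocusInfo, ModelConfig, OrdinalPhenotypes
from .design import build_design
from .inference import declare_qtl
from .liability import thresholds_from_frequencies


@dataclass(frozen=True)
class QtlSpec:
    chromosome: int  # 0-based index into scenario.chromosomes
    position_cm: float
    h2: float


@dataclass
class SimScenario:
    """All knobs of one simulation experiment.

    chromosomes
        List of (length cM, marker spacing cM); markers run from 0 to
        the length inclusive.
    qtl
        Positions must coincide with marker positions.
    category_freqs
        Relative category frequencies; they define both the number of
        categories and the generating thresholds.
    """

    n_founders: int = 100
    n_nonfounders: int = 200
    chromosomes: list[tuple[float, float]] = field(
        default_factory=lambda: [(100.0, 10.0)] * 3
    )
    n_alleles: int = 3
    qtl: list[QtlSpec] = field(
        default_factory=lambda: [
            QtlSpec(0, 50.0, 0.05),
            QtlSpec(1, 50.0, 0.10),
            QtlSpec(2, 50.0, 0.15),
        ]
    )
    category_freqs: tuple[float, ...] = (1, 2, 4, 2, 1)
    n_replicates: int = 100
    lod_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total_h2 = sum(q.h2 for q in self.qtl)
        if any(not 0 <= q.h2 < 1 for q in self.qtl) or total_h2 >= 1:
            raise ValueError("QTL heritabilities must lie in [0,1) and sum below 1")
        for q in self.qtl:
            positions = self.marker_positions(q.chromosome)
            if not np.any(np.isclose(positions, q.position_cm)):
                raise ValueError(
                    f"QTL at {q.position_cm} cM does not coincide with a marker "
                    f"on chromosome {q.chromosome}"
                )

    def marker_positions(self, chromosome: int) -> np.ndarray:
        length, spacing = self.chromosomes[chromosome]
        return np.arange(0.0, length + spacing / 2, spacing)

    def loci(self) -> list[LocusInfo]:
        out = []
        for ci in range(len(self.chromosomes)):
            for pos in self.marker_positions(ci):
                out.append(
                    LocusInfo(name=f"c{ci + 1}m{pos:g}", chromosome=str(ci + 1),
                              position_cm=float(pos))
                )
        return out

    def qtl_locus_indices(self) -> list[int]:
        names = [loc.name for loc in self.loci()]
        return [names.index(f"c{q.chromosome + 1}m{q.position_cm:g}") for q in self.qtl]

    @property
    def n_categories(self) -> int:
        return len(self.category_freqs)


def simulate_founders(scenario: SimScenario, rng: np.random.Generator) -> GenotypePanel:
    """Founder panel in linkage equilibrium, alleles uniform per locus."""
    loci = scenario.loci()
    labels = [str(a + 1) for a in range(scenario.n_alleles)]
    draws = rng.integers(0, scenario.n_alleles, size=(scenario.n_founders, len(loci)))
    alleles = np.array(labels, dtype=object)[draws]
    ids = [f"F{i + 1}" for i in range(scenario.n_founders)]
    return GenotypePanel(cultivar_ids=ids, loci=loci, alleles=alleles)


def ril_switch_probability(d_cm: float) -> float:
    """Probability that parental origin differs at two markers d cM apart
    in a RIL selfed to fixation (Haldane map function)."""
    r = (1.0 - np.exp(-2.0 * d_cm / 100.0)) / 2.0
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    chromosome_positions: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One homozygous RIL genome from two homozygous parents.

    ``chromosome_positions`` gives ordered marker positions per
    chromosome; parent rows are concatenated in the same order.
    """
    out = np.empty(len(parent_a), dtype=object)
    offset = 0
    for positions in chromosome_positions:
        positions = np.asarray(positions, dtype=float)
        if np.any(np.diff(positions) < 0):
            raise ValueError("marker positions must be ordered within a chromosome")
        m = len(positions)
        start = rng.random() < 0.5  # True = parent A
        switch_p = ril_switch_probability(np.diff(positions))
        switches = rng.random(m - 1) < switch_p
        # origin flips at every switch event: parity of cumulative switches
        parity = np.concatenate(([0], np.cumsum(switches) % 2)).astype(bool)
        origin = start ^ parity
        seg = slice(offset, offset + m)
        out[seg] = np.where(origin, parent_a[seg], parent_b[seg])
        offset += m
    return out


def simulate_nonfounders(
    scenario: SimScenario, founders: GenotypePanel, rng: np.random.Generator
) -> GenotypePanel:
    """Breed the mapping panel: each line is a RIL of a random founder pair."""
    positions = [scenario.marker_positions(ci) for ci in range(len(scenario.chromosomes))]
    rows = []
    for _ in range(scenario.n_nonfounders):
        i, j = rng.choice(scenario.n_founders, size=2, replace=False)
        rows.append(
            simulate_ril(founders.alleles[i], founders.alleles[j], positions, rng)
        )
    ids = [f"R{i + 1}" for i in range(scenario.n_nonfounders)]
    return GenotypePanel(cultivar_ids=ids, loci=list(founders.loci), alleles=np.array(rows, dtype=object))


def assign_qtl_effects(
    scenario: SimScenario, panel: GenotypePanel
) -> list[dict[str, float]]:
    """Allele effect vectors per QTL, variance-matched to the target h².

    Base effects are equally spaced (−1 … +1 over the allele labels),
    centered to zero mean over the panel's realized allele counts, then
    scaled so the realized genetic variance of the QTL equals
    ``h² · σ_P²`` with ``σ_P² = 1 / (1 − Σ h²)`` — the total phenotypic
    variance implied by a unit residual.
    """
    total_h2 = sum(q.h2 for q in scenario.qtl)
    sigma_p2 = 1.0 / (1.0 - total_h2)
    out: list[dict[str, float]] = []
    for q, j in zip(scenario.qtl, scenario.qtl_locus_indices()):
        col = panel.alleles[:, j]
        labels = [str(a + 1) for a in range(scenario.n_alleles)]
        base = np.linspace(-1.0, 1.0, scenario.n_alleles)
        values = np.array([base[labels.index(str(a))] for a in col])
        centered = base - values.mean()
        realized = np.array([centered[labels.index(str(a))] for a in col])
        var0 = float(np.var(realized))
        if q.h2 == 0 or var0 == 0:
            if q.h2 > 0 and var0 == 0:
                warnings.warn(
                    f"QTL locus {panel.loci[j].name} is monomorphic; effects set to 0",
                    stacklevel=2,
                )
            out.append({lab: 0.0 for lab in labels})
            continue
        scale = np.sqrt(q.h2 * sigma_p2 / var0)
        out.append({lab: float(e * scale) for lab, e in zip(labels, centered)})
    return out


def simulate_phenotypes(
    panel: GenotypePanel,
    scenario: SimScenario,
    effects: list[dict[str, float]],
    rng: np.random.Generator,
    environment: str = "E1",
) -> OrdinalPhenotypes:
    """Liability = Σ QTL genotypic values + N(0,1); cut into categories.

    The standard-normal thresholds implied by ``category_freqs`` are
    scaled by the realized liability standard deviation so the marginal
    category proportions match the design frequencies whatever the total
    genetic variance.
    """
    genetic = np.zeros(panel.n_cultivars)
    var_g = 0.0
    for eff, j in zip(effects, scenario.qtl_locus_indices()):
        contrib = np.array([eff[str(a)] for a in panel.alleles[:, j]])
        genetic += contrib
        var_g += float(np.var(contrib))
    liability = genetic + rng.standard_normal(panel.n_cultivars)
    base_t = thresholds_from_frequencies(scenario.category_freqs).t
    cuts = base_t * np.sqrt(1.0 + var_g)
    categories = np.searchsorted(cuts, liability, side="left") + 1
    return OrdinalPhenotypes(
        cultivar_ids=list(panel.cultivar_ids),
        environment_ids=[environment] * panel.n_cultivars,
        categories=categories,
        n_categories=scenario.n_categories,
    )


@dataclass
class SimReplicateResult:
    qtl_lod: list[float]
    detected: list[bool]
    false_positives: int
    zero_blocks: int
    thresholds: np.ndarray
    qtl_effects: list[dict[str, float]]
    true_effects: list[dict[str, float]]
    category_counts: np.ndarray


@dataclass
class PowerResult:
    power: list[float]
    fpr: float
    replicates: list[SimReplicateResult]
    n_excluded: int
    scenario: SimScenario

    def mean_threshold_estimates(self) -> np.ndarray:
        return np.mean([r.thresholds for r in self.replicates], axis=0)


def run_replicate(
    scenario: SimScenario, rep: int, config: ModelConfig
) -> SimReplicateResult:
    """Simulate one dataset and push it through the full mapping pipeline."""
    rng = np.random.default_rng([scenario.seed, rep])
    founders = simulate_founders(scenario, rng)
    panel = simulate_nonfounders(scenario, founders, rng)
    effects = assign_qtl_effects(scenario, panel)
    phen = simulate_phenotypes(panel, scenario, effects, rng)

    design = build_design(panel, phen)
    cfg = config.replace(
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        lod_threshold=scenario.lod_threshold,
    )
    state = eb.fit(design, phen.categories, cfg, n_categories=scenario.n_categories)
    result = declare_qtl(
        state, design, phen.categories, scenario.n_categories, cfg, panel=panel
    )

    qtl_loci = scenario.qtl_locus_indices()
    block_by_locus = {
        b.locus_index: i
        for i, b in enumerate(design.blocks)
        if b.kind == BLOCK_MQ
    }
    calls_by_block = {c.block_index: c for c in result.calls}
    qtl_lod, detected, est_effects = [], [], []
    for j, true_eff in zip(qtl_loci, effects):
        blk = block_by_locus.get(j)
        call = calls_by_block.get(blk)
        lod = call.lod if call is not None else 0.0
        qtl_lod.append(lod)
        detected.append(lod >= scenario.lod_threshold)
        est_effects.append(dict(call.allele_effects) if call is not None else {})
    qtl_blocks = {block_by_locus[j] for j in qtl_loci if j in block_by_locus}
    fp = sum(
        1 for c in result.calls if c.block_index not in qtl_blocks
    )
    zero_blocks = design.n_blocks - len(qtl_blocks)
    return SimReplicateResult(
        qtl_lod=qtl_lod,
        detected=detected,
        false_positives=fp,
        zero_blocks=zero_blocks,
        # only thresholds relative to the fixed-effect location are
        # identifiable; report them centered on mean(Xβ̂)
        thresholds=state.th.t - float(np.mean(design.x @ state.beta)),
        qtl_effects=est_effects,
        true_effects=effects,
        category_counts=phen.category_counts(),
    )


def run_power_experiment(
    scenario: SimScenario, config: ModelConfig | None = None
) -> PowerResult:
    """Replicate the simulate→fit→test pipeline; tally power and FPR.

    Power per QTL = share of replicates with LOD >= threshold at the
    true marker; FPR = false-positive declarations over (zero-effect
    blocks × replicates).  A replicate whose pipeline fails is excluded
    and counted.
    """
    config = config or ModelConfig()
    reps: list[SimReplicateResult] = []
    excluded = 0
    for rep in range(scenario.n_replicates):
        try:
            reps.append(run_replicate(scenario, rep, config))
        except Exception as exc:  # noqa: BLE001 - harness isolates replicates
            excluded += 1
            warnings.warn(f"replicate {rep} failed and was excluded: {exc}",
                          stacklevel=2)
    if not reps:
        raise RuntimeError("every replicate failed")
    n_qtl = len(scenario.qtl)
    power = [
        float(np.mean([r.detected[i] for r in reps])) for i in range(n_qtl)
    ]
    total_zero = sum(r.zero_blocks for r in reps)
    fpr = sum(r.false_positives for r in reps) / total_zero if total_zero else 0.0
    return PowerResult(
        power=power, fpr=fpr, replicates=reps, n_excluded=excluded,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# shipped experiment presets (Table-style cases)


def case1(**overrides) -> SimScenario:
    """100 founders, 200 RILs, three 100 cM chromosomes with markers every
    10 cM (33 markers), QTL at 50 cM with h² = 5/10/15%, five categories
    in ratio 1:2:4:2:1."""
    return replace(SimScenario(), **overrides)


def case2(distribution: tuple[float, ...], **overrides) -> SimScenario:
    """Case 1 with an alternative five-category frequency profile
    (uniform 1:1:1:1:1 or skewed 8:5:3:1:1)."""
    return replace(SimScenario(), category_freqs=distribution, **overrides)


_CASE3_FREQS = {
    2: (1, 1),
    6: (1, 3, 6, 6, 3, 1),
    9: (1, 2, 4, 6, 9, 6, 4, 2, 1),
}


def case3(n_categories: int, **overrides) -> SimScenario:
    """Case 1 with 2, 6 or 9 ordinal categories."""
    return replace(
        SimScenario(), category_freqs=_CASE3_FREQS[n_categories], **overrides
    )


def case4(n_nonfounders: int, **overrides) -> SimScenario:
    """Case 1 genome at varying mapping-panel size."""
    return replace(SimScenario(), n_nonfounders=n_nonfounders, **overrides)


_LONG_QTL_POSITIONS = [
    (0, [90.0, 240.0, 390.0, 540.0, 690.0, 840.0]),
    (1, [80.0, 230.0, 380.0, 530.0, 680.0, 830.0]),
    (2, [120.0, 270.0, 420.0, 570.0, 720.0, 870.0]),
]
_LONG_H2 = [0.01] * 5 + [0.03] * 5 + [0.05] * 6 + [0.10, 0.15]


def _long_genome_qtl() -> list[QtlSpec]:
    flat = [(c, p) for c, ps in _LONG_QTL_POSITIONS for p in ps]
    return [QtlSpec(c, p, h) for (c, p), h in zip(flat, _LONG_H2)]


def case5(n_nonfounders: int, **overrides) -> SimScenario:
    """50 founders, three 1000 cM chromosomes (101 markers each), 18 QTL
    with h² from 1% to 15%, varying panel size."""
    return replace(
        SimScenario(),
        n_founders=50,
        n_nonfounders=n_nonfounders,
        chromosomes=[(1000.0, 10.0)] * 3,
        qtl=_long_genome_qtl(),
        **overrides,
    )


def case6(n_founders: int, **overrides) -> SimScenario:
    """Long-genome design at 200 RILs, varying founder count."""
    return replace(
        SimScenario(),
        n_founders=n_founders,
        n_nonfounders=200,
        chromosomes=[(1000.0, 10.0)] * 3,
        qtl=_long_genome_qtl(),
        **overrides,
    )
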