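"""Domain containers shared by every stage of the pipeline.

All lines in a cultivar panel are assumed fully homozygous, so a genotype
is a single allele label per locus rather than a pair.  Marker alleles are
arbitrary hashable labels (SSR fragment sizes such as ``"260"`` are the
typical case); the distinguished :data:`UNKNOWN` label marks a failed or
missing assay and is never counted among a locus's known alleles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Distinguished missing-allele label.
UNKNOWN = "?"


@dataclass(frozen=True)
class LocusInfo:
    """Marker metadata: name plus optional genetic-map coordinates."""

    name: str
    chromosome: str | None = None
    position_cm: float | None = None


@dataclass
class GenotypePanel:
    """Cultivar x locus allele assignments for a panel of homozygous lines.

    Parameters
    ----------
    cultivar_ids
        Unique line identifiers, one per row of `alleles`.
    loci
        Per-column marker metadata.
    alleles
        2-D object array, shape ``(n_cultivars, n_loci)``; entries are
        allele labels (strings) or :data:`UNKNOWN`.
    """

    cultivar_ids: list[str]
    loci: list[LocusInfo]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=object)
        if len(set(self.cultivar_ids)) != len(self.cultivar_ids):
            dupes = sorted(
                {c for c in self.cultivar_ids if self.cultivar_ids.count(c) > 1}
            )
            raise ValueError(f"duplicate cultivar ids: {dupes}")
        if self.alleles.shape != (len(self.cultivar_ids), len(self.loci)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.cultivar_ids)} cultivars x {len(self.loci)} loci"
            )

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivar_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def known_alleles(self, locus_index: int) -> list[str]:
        """Sorted labels observed at a locus, excluding :data:`UNKNOWN`."""
        col = self.alleles[:, locus_index]
        return sorted({a for a in col if a != UNKNOWN})

    def locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise KeyError(name)

    def row_index(self, cultivar_id: str) -> int:
        return self.cultivar_ids.index(cultivar_id)


@dataclass
class OrdinalPhenotypes:
    """Ordinal category observations per (cultivar, environment).

    Categories are integers ``1..C``; every environment shares the same C.
    Each (cultivar, environment) pair appears at most once.
    """

    cultivar_ids: list[str]
    environment_ids: list[str]
    categories: np.ndarray
    n_categories: int

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=int)
        n = len(self.cultivar_ids)
        if not (len(self.environment_ids) == n == len(self.categories)):
            raise ValueError("record columns have unequal lengths")
        if n == 0:
            raise ValueError("no phenotype records")
        if self.n_categories < 2:
            raise ValueError("need at least 2 ordinal categories")
        bad = (self.categories < 1) | (self.categories > self.n_categories)
        if bad.any():
            raise ValueError(
                f"categories outside 1..{self.n_categories}: "
                f"{sorted(set(self.categories[bad].tolist()))}"
            )
        pairs = list(zip(self.cultivar_ids, self.environment_ids))
        if len(set(pairs)) != len(pairs):
            seen: set[tuple[str, str]] = set()
            dupes = set()
            for p in pairs:
                if p in seen:
                    dupes.add(p)
                seen.add(p)
            raise ValueError(f"duplicate (cultivar, environment) records: {sorted(dupes)}")

    @property
    def n_records(self) -> int:
        return len(self.categories)

    @property
    def environments(self) -> list[str]:
        """Distinct environment labels in first-appearance order."""
        out: list[str] = []
        for e in self.environment_ids:
            if e not in out:
                out.append(e)
        return out

    def category_counts(self) -> np.ndarray:
        """Counts of each category 1..C over all records."""
        return np.bincount(self.categories, minlength=self.n_categories + 1)[1:]


@dataclass
class StructureCovariates:
    """Population-structure membership proportions (the Q matrix).

    Computed externally (e.g. STRUCTURE/ADMIXTURE); each row sums to 1.
    """

    cultivar_ids: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.cultivar_ids):
            raise ValueError("Q matrix shape does not match cultivar ids")
        if self.q.shape[1] < 1:
            raise ValueError("Q must have K >= 1 columns")
        sums = self.q.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("Q rows must each sum to 1 (tolerance 1e-6)")

    @property
    def n_subpopulations(self) -> int:
        return self.q.shape[1]


BLOCK_MQ = "MQ"
BLOCK_QE = "QE"


@dataclass(frozen=True)
class BlockInfo:
    """Identity of one random-effect block: a locus, main or interaction."""

    locus_index: int
    locus_name: str
    kind: str  # BLOCK_MQ or BLOCK_QE
    #: column labels: allele labels (MQ) or "allele x environment" (QE)
    labels: tuple[str, ...]


@dataclass
class DesignBlocks:
    """Observation-level design: fixed matrix plus per-block random matrices.

    The fixed part carries full-rank environment indicators (no global
    intercept; the model's location lives in the thresholds) and, when a Q
    matrix is supplied, K-1 structure covariates in drop-one coding.
    Each random block is either a locus's main-effect allele-indicator
    matrix (one column per known allele; all-zero row where the line's
    allele is unknown) or its allele-by-environment product matrix.
    """

    x: np.ndarray
    x_labels: list[str]
    z: list[np.ndarray]
    blocks: list[BlockInfo]
    environments: list[str]
    row_cultivars: list[str]
    row_environments: list[str]

    @property
    def n_obs(self) -> int:
        return self.x.shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.z)

    def blocks_of_kind(self, kind: str) -> list[int]:
        return [i for i, b in enumerate(self.blocks) if b.kind == kind]


@dataclass
class ModelConfig:
    """Tuning constants for fitting and testing.

    tau, omega
        Scaled-inverse-chi-square hyperprior constants for the per-block
        effect variances; (0, 0) gives the non-informative posterior mode
        E/(m+2).
    stage1_threshold
        Minimum absolute effect (liability scale) for a block to enter
        the reduced maximum-likelihood model of the likelihood-ratio test.
    lod_threshold
        LOD needed to declare a QTL (default 2.0).
    weight_floor
        Lower bound on pseudo-data weights.
    model_unknown_allele
        When True, the missing-allele label is modeled as its own allele
        class instead of contributing zero to the design.
    beta_init
        "uniform" draws starting fixed effects from U(0,1); "zero" starts
        at 0.
    """

    tau: float = 0.0
    omega: float = 0.0
    stage1_threshold: float = 0.05
    lod_threshold: float = 2.0
    max_iter: int = 1000
    convergence_tol: float = 1e-6
    weight_floor: float = 1e-8
    rng_seed: int = 0
    model_unknown_allele: bool = False
    beta_init: str = "uniform"

    def __post_init__(self) -> None:
        if self.tau < 0 or self.omega < 0:
            raise ValueError("tau and omega must be >= 0")
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.weight_floor <= 0:
            raise ValueError("weight_floor must be > 0")
        if self.beta_init not in ("uniform", "zero"):
            raise ValueError("beta_init must be 'uniform' or 'zero'")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)
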