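"""Readers and writers for the delimited-table interchange formats.

Genotype tables are cultivar x marker grids of allele labels; phenotype
tables are long-form (cultivar, environment, category) records.  Comma and
tab delimiters are auto-detected; the tokens ``""``, ``"NA"`` and ``"-"``
mean a missing allele.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    UNKNOWN,
    GenotypePanel,
    LocusInfo,
    ModelConfig,
    OrdinalPhenotypes,
    StructureCovariates,
)

MISSING_TOKENS = {"", "NA", "-"}


def _read_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Load a delimited table, sniffing comma vs tab unless told."""
    sep = {"csv": ",", "tsv": "\t", None: None}[dialect]
    return pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c",
        dtype=str, keep_default_na=False,
    )


def read_genotypes(path: str | Path, dialect: str | None = None) -> GenotypePanel:
    """Read a cultivar x marker allele table into a :class:`GenotypePanel`.

    First column is the cultivar id; every other column is one marker whose
    cells hold allele labels or a missing token.  A marker at which every
    line is missing is kept (for map bookkeeping) but triggers a warning
    since it can never enter the model.
    """
    df = _read_table(path, dialect)
    cultivars = [str(c).strip() for c in df.iloc[:, 0]]
    loci = [LocusInfo(name=str(c).strip()) for c in df.columns[1:]]
    alleles = np.empty((len(cultivars), len(loci)), dtype=object)
    for j in range(len(loci)):
        col = df.iloc[:, j + 1].astype(str).str.strip()
        alleles[:, j] = [UNKNOWN if a in MISSING_TOKENS else a for a in col]
    panel = GenotypePanel(cultivar_ids=cultivars, loci=loci, alleles=alleles)
    for j, loc in enumerate(loci):
        if not panel.known_alleles(j):
            warnings.warn(
                f"locus {loc.name!r} has no known alleles; it is retained "
                "but will be excluded from mapping",
                stacklevel=2,
            )
    return panel


def write_genotypes(panel: GenotypePanel, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        {loc.name: panel.alleles[:, j] for j, loc in enumerate(panel.loci)},
        index=pd.Index(panel.cultivar_ids, name="cultivar"),
    )
    df = df.replace({UNKNOWN: "NA"})
    df.to_csv(path, sep=sep)


def read_phenotypes(
    path: str | Path,
    category_count: int | None = None,
    dialect: str | None = None,
) -> OrdinalPhenotypes:
    """Read long-form (cultivar, environment, category) records.

    ``category_count`` fixes C; when omitted, C is inferred as the maximum
    observed category.
    """
    df = _read_table(path, dialect)
    cultivars = [str(c).strip() for c in df.iloc[:, 0]]
    envs = [str(e).strip() for e in df.iloc[:, 1]]
    raw = df.iloc[:, 2].astype(str).str.strip()
    cats = np.empty(len(raw), dtype=int)
    for i, tok in enumerate(raw):
        try:
            v = float(tok)
        except ValueError:
            raise ValueError(f"non-numeric category {tok!r} at row {i}") from None
        if v != int(v):
            raise ValueError(f"non-integer category {tok!r} at row {i}")
        cats[i] = int(v)
    c = category_count if category_count is not None else int(cats.max())
    return OrdinalPhenotypes(
        cultivar_ids=cultivars, environment_ids=envs, categories=cats, n_categories=c
    )


def write_phenotypes(phen: OrdinalPhenotypes, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "cultivar": phen.cultivar_ids,
            "environment": phen.environment_ids,
            "category": phen.categories,
        }
    ).to_csv(path, sep=sep, index=False)


def read_qmatrix(path: str | Path, dialect: str | None = None) -> StructureCovariates:
    """Read a Q matrix: first column cultivar id, then K membership columns."""
    df = _read_table(path, dialect)
    cultivars = [str(c).strip() for c in df.iloc[:, 0]]
    q = df.iloc[:, 1:].astype(float).to_numpy()
    return StructureCovariates(cultivar_ids=cultivars, q=q)


def read_map(path: str | Path, dialect: str | None = None) -> dict[str, LocusInfo]:
    """Read a genetic map (marker, chromosome, position_cM) as a lookup."""
    df = _read_table(path, dialect)
    out: dict[str, LocusInfo] = {}
    for _, row in df.iterrows():
        name = str(row.iloc[0]).strip()
        out[name] = LocusInfo(
            name=name,
            chromosome=str(row.iloc[1]).strip(),
            position_cm=float(row.iloc[2]),
        )
    return out


def attach_map(panel: GenotypePanel, genetic_map: dict[str, LocusInfo]) -> GenotypePanel:
    """Return a panel whose loci carry chromosome/position from the map."""
    loci = [genetic_map.get(loc.name, loc) for loc in panel.loci]
    return GenotypePanel(
        cultivar_ids=list(panel.cultivar_ids), loci=loci, alleles=panel.alleles.copy()
    )


def grade_of_index(value: float, n_grades: int = 5) -> int:
    """Bin one tolerance-index fraction into an ordinal grade.

    Grades ``g = 1..n_grades`` cover equal-width bins
    ``((g-1)/n_grades, g/n_grades]``; grade 1 additionally includes 0
    exactly.  Values above 1 clamp to the top grade with a warning
    (a treated/control ratio can exceed 1 when treatment helps).
    """
    if value < 0:
        raise ValueError(f"tolerance index must be >= 0, got {value}")
    if value > 1:
        warnings.warn(f"index {value} > 1 clamped to grade {n_grades}", stacklevel=2)
        return n_grades
    if value == 0:
        return 1
    width = 1.0 / n_grades
    # left-open, right-closed bins: g is the smallest g with value <= g*width
    g = int(np.ceil(value / width - 1e-12))
    return min(max(g, 1), n_grades)


def grades_from_index(
    index_values: pd.DataFrame, n_grades: int = 5
) -> OrdinalPhenotypes:
    """Convert a table of tolerance-index fractions into ordinal grades.

    ``index_values`` needs three columns: cultivar id, environment id and
    the index value in [0, 1] (columns are taken positionally).
    """
    cultivars = [str(c).strip() for c in index_values.iloc[:, 0]]
    envs = [str(e).strip() for e in index_values.iloc[:, 1]]
    vals = index_values.iloc[:, 2].astype(float)
    cats = np.array([grade_of_index(v, n_grades) for v in vals], dtype=int)
    return OrdinalPhenotypes(
        cultivar_ids=cultivars,
        environment_ids=envs,
        categories=cats,
        n_categories=n_grades,
    )


def read_config(path: str | Path) -> ModelConfig:
    """Load a :class:`ModelConfig` from YAML; absent keys use defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelConfig(**raw)


def write_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.__dict__, fh, sort_keys=False)
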