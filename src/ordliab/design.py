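"""Design-matrix construction for the liability model.

One observation row per (cultivar, environment) phenotype record.  The
fixed part X holds full-rank environment indicators — no global intercept,
since the model's location is absorbed by the thresholds — plus K-1
population-structure covariates when a Q matrix is given.  Each locus
contributes a main-effect (MQ) random block with one indicator column per
known allele; with two or more environments it also contributes a
locus-by-environment (QE) block whose columns are elementwise products of
an allele indicator and an environment indicator.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    BLOCK_MQ,
    BLOCK_QE,
    UNKNOWN,
    BlockInfo,
    DesignBlocks,
    GenotypePanel,
    OrdinalPhenotypes,
    StructureCovariates,
)


def build_design(
    panel: GenotypePanel,
    phen: OrdinalPhenotypes,
    q: StructureCovariates | None = None,
    qe: str | bool = "auto",
    model_unknown_allele: bool = False,
) -> DesignBlocks:
    """Assemble fixed and random design matrices from panel + phenotypes.

    Parameters
    ----------
    qe
        Whether to build QE interaction blocks.  ``"auto"`` (default)
        builds them only when >= 2 environments are observed; with a
        single environment a QE block would duplicate the MQ block.
    model_unknown_allele
        Treat the missing-allele label as its own allele class rather
        than an all-zero design row.

    Raises
    ------
    KeyError
        If a phenotyped cultivar is absent from the genotype panel.
    """
    missing = sorted(set(phen.cultivar_ids) - set(panel.cultivar_ids))
    if missing:
        raise KeyError(f"phenotyped cultivars missing from genotype panel: {missing}")

    environments = phen.environments
    n_env = len(environments)
    if qe == "auto":
        build_qe = n_env >= 2
    else:
        build_qe = bool(qe)

    n_obs = phen.n_records
    row_of_cultivar = {c: i for i, c in enumerate(panel.cultivar_ids)}
    obs_cultivar_row = np.array([row_of_cultivar[c] for c in phen.cultivar_ids])
    env_index = {e: i for i, e in enumerate(environments)}
    obs_env = np.array([env_index[e] for e in phen.environment_ids])

    # fixed part: environment indicators, then K-1 structure covariates
    x_env = np.zeros((n_obs, n_env))
    x_env[np.arange(n_obs), obs_env] = 1.0
    x_labels = [f"env:{e}" for e in environments]
    parts = [x_env]
    if q is not None:
        qrow = {c: i for i, c in enumerate(q.cultivar_ids)}
        missing_q = sorted(set(phen.cultivar_ids) - set(q.cultivar_ids))
        if missing_q:
            raise KeyError(f"phenotyped cultivars missing from Q matrix: {missing_q}")
        qs = q.q[[qrow[c] for c in phen.cultivar_ids], :]
        if q.n_subpopulations > 1:
            parts.append(qs[:, :-1])  # drop-one: rows sum to 1
            x_labels += [f"Q{k + 1}" for k in range(q.n_subpopulations - 1)]
    x = np.hstack(parts)

    z: list[np.ndarray] = []
    blocks: list[BlockInfo] = []
    for j, loc in enumerate(panel.loci):
        alleles = panel.known_alleles(j)
        if model_unknown_allele and UNKNOWN in panel.alleles[:, j]:
            alleles = alleles + [UNKNOWN]
        if not alleles:
            continue  # empty locus: excluded from mapping
        a_index = {a: k for k, a in enumerate(alleles)}
        zm = np.zeros((n_obs, len(alleles)))
        for i in range(n_obs):
            a = panel.alleles[obs_cultivar_row[i], j]
            k = a_index.get(a)
            if k is not None:
                zm[i, k] = 1.0
        z.append(zm)
        blocks.append(
            BlockInfo(
                locus_index=j, locus_name=loc.name, kind=BLOCK_MQ,
                labels=tuple(str(a) for a in alleles),
            )
        )
        if build_qe:
            zq = np.zeros((n_obs, len(alleles) * n_env))
            labels = []
            for k, a in enumerate(alleles):
                for e, env in enumerate(environments):
                    zq[:, k * n_env + e] = zm[:, k] * x_env[:, e]
                    labels.append(f"{a} x {env}")
            z.append(zq)
            blocks.append(
                BlockInfo(
                    locus_index=j, locus_name=loc.name, kind=BLOCK_QE,
                    labels=tuple(labels),
                )
            )

    return DesignBlocks(
        x=x,
        x_labels=x_labels,
        z=z,
        blocks=blocks,
        environments=environments,
        row_cultivars=list(phen.cultivar_ids),
        row_environments=list(phen.environment_ids),
    )
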