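import numpy as np
import pytest

from ordliab.datamodel import GenotypePanel, LocusInfo, ModelConfig, OrdinalPhenotypes

#: symmetric five-category profile and its standard-normal cut points
SYMMETRIC_FREQS = (1, 2, 4, 2, 1)
SYMMETRIC_CUTS = np.array([-1.2816, -0.5244, 0.5244, 1.2816])


@pytest.fixture
def toy_panel() -> GenotypePanel:
    """Five homozygous lines at two multi-allelic loci."""
    alleles = np.array(
        [
            ["A", "x"],
            ["A", "y"],
            ["B", "x"],
            ["B", "z"],
            ["C", "y"],
        ],
        dtype=object,
    )
    return GenotypePanel(
        cultivar_ids=["cv1", "cv2", "cv3", "cv4", "cv5"],
        loci=[LocusInfo("m1", "1", 0.0), LocusInfo("m2", "2", 10.0)],
        alleles=alleles,
    )


@pytest.fixture
def toy_phenotypes() -> OrdinalPhenotypes:
    """Two-environment ordinal records for the toy panel."""
    cultivars = ["cv1", "cv2", "cv3", "cv4", "cv5"] * 2
    envs = ["2009"] * 5 + ["2010"] * 5
    cats = np.array([1, 2, 3, 4, 5, 2, 2, 3, 4, 4])
    return OrdinalPhenotypes(
        cultivar_ids=cultivars, environment_ids=envs, categories=cats, n_categories=5
    )


@pytest.fixture
def fast_config() -> ModelConfig:
    """Looser convergence for simulation-heavy tests."""
    return ModelConfig(convergence_tol=1e-4, max_iter=300)
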