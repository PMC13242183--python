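import numpy as np
import pytest

from omicsfuse.preprocess import LabeledCohort, OmicsMatrix
from omicsfuse.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small cohort with clear planted signal in both modalities."""
    return SimConfig(
        n_class0=25,
        n_class1=25,
        n_genes_rna=60,
        n_genes_cnv=50,
        n_shared_informative=5,
        n_rna_only_informative=3,
        n_cnv_only_informative=2,
        effect_size_rna=2.0,
        effect_size_cnv=1.5,
        block_size=5,
        block_rho=0.2,
        dropout_fraction_rna=0.04,
        dropout_fraction_cnv=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    raw, truth = generate_cohort(tiny_config)
    return raw.to_labeled(normalize=False), truth


@pytest.fixture()
def small_matrix() -> OmicsMatrix:
    rng = np.random.default_rng(3)
    return OmicsMatrix(
        "RNA",
        [f"S{i}" for i in range(6)],
        [f"G{j}" for j in range(4)],
        rng.normal(size=(6, 4)),
    )


def make_labeled(n0: int, n1: int, n_genes: int, effect: float, seed: int) -> LabeledCohort:
    """Direct two-modality Gaussian cohort without dropout, for bench tests."""
    rng = np.random.default_rng(seed)
    n = n0 + n1
    ids = [f"T-{i:02d}-{i:04d}-01" for i in range(n)]
    genes = [f"G{j:03d}" for j in range(n_genes)]
    y = np.array([0] * n0 + [1] * n1)
    mats = []
    for modality in ("RNA", "CNV"):
        v = rng.normal(size=(n, n_genes))
        v[y == 1, : max(1, n_genes // 4)] += effect
        mats.append(OmicsMatrix(modality, ids, genes, v))
    return LabeledCohort(mats[0], mats[1], y, ids)
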