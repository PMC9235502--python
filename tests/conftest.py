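import numpy as np
import pytest

from mhc2bind import (
    AffinityRecord,
    AlleleRegistry,
    GeneratorConfig,
    ModelConfig,
    TrainConfig,
    make_dataset,
)

#: Tiny architecture used by most model-level tests.
TINY_MODEL = ModelConfig(
    embed_dim=4,
    kernel_sizes=(9, 11),
    kernels_per_size=(3, 2),
    fc_sizes=(6, 5),
    dropout_rate=0.0,
)


@pytest.fixture(scope="session")
def registry():
    return AlleleRegistry(
        {
            "DRB1*01:01": "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQ",
            "H-2-IAb": "WYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMN",
        }
    )


@pytest.fixture(scope="session")
def tiny_records():
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for i in range(40):
        L = int(rng.integers(9, 18))
        pep = "".join(letters[rng.integers(0, 20, L)])
        allele = "DRB1*01:01" if i % 2 else "H-2-IAb"
        records.append(
            AffinityRecord(pep, allele, float(rng.random()), fold=i % 3)
        )
    return records


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic dataset shared by generator/evaluation tests."""
    return make_dataset(
        GeneratorConfig(n_alleles=3, peptides_per_allele=60, seed=11)
    )
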