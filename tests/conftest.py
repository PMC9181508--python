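import numpy as np
import pandas as pd
import pytest

from inherimet.design_io import FactorialDesign, TraitMatrix, study_design
from inherimet.synthetic_data import study_bundle


@pytest.fixture(scope="session")
def design() -> FactorialDesign:
    return study_design()


@pytest.fixture(scope="session")
def bundle():
    """Small study-shaped synthetic bundle shared across tests."""
    return study_bundle(11, n_genes=600)


def make_trait_matrix(values: dict[str, np.ndarray], genotypes: list[str],
                      n_reps: int = 3) -> TraitMatrix:
    """Build a TraitMatrix from per-trait flat value arrays (genotype-major)."""
    idx = [f"{g}_h{j + 1}" for g in genotypes for j in range(n_reps)]
    meta = pd.DataFrame({
        "genotype": [g for g in genotypes for _ in range(n_reps)],
        "harvest": [j + 1 for _ in genotypes for j in range(n_reps)],
    }, index=pd.Index(idx, name="sample"))
    return TraitMatrix(pd.DataFrame(values, index=meta.index), meta)


@pytest.fixture(scope="session")
def trait_matrix_factory():
    return make_trait_matrix
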