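import numpy as np
import pytest

from pivotalnet import ExpressionMatrix, PlantedDesign, correlation_network, generate


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down planted design: the core is a third of the module, as in
    the study-scale defaults, so every detector family is well-posed."""
    return PlantedDesign(
        n_subjects=250, core_genes=12, module_genes=36, seed=5
    )


@pytest.fixture(scope="session")
def small_planted(small_design):
    matrix, core = generate(small_design)
    return matrix, core


@pytest.fixture(scope="session")
def small_network(small_planted):
    matrix, _ = small_planted
    return correlation_network(matrix)


@pytest.fixture()
def toy_matrix():
    """4 genes x 6 subjects with fixed, varied values."""
    rng = np.random.default_rng(99)
    return ExpressionMatrix(
        gene_ids=["A", "B", "C", "D"],
        subject_ids=[f"S{i}" for i in range(6)],
        values=rng.normal(size=(4, 6)),
    )
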