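import numpy as np
import pytest

from genefs import ExpressionDataset, SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_dataset():
    """3 samples x 2 genes, labels [0, 1, 1]."""
    return ExpressionDataset(
        sample_ids=["s1", "s2", "s3"],
        gene_ids=["GA", "GB"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        labels=np.array([0, 1, 1]),
    )


@pytest.fixture
def balanced_dataset():
    """Synthetic 40 + 40 two-class dataset with 3 strong planted genes."""
    spec = SyntheticSpec(
        n_tumor=40, n_normal=40, n_genes=30, n_informative=3,
        effect_sizes=(1.5, 1.5, 1.5), base_sd_range=(0.5, 0.5), seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture
def imbalanced_dataset():
    """Synthetic 176 tumor / 10 normal dataset (study-shaped imbalance)."""
    spec = SyntheticSpec(n_tumor=176, n_normal=10, n_genes=60, n_informative=4,
                         seed=7)
    return generate_dataset(spec)
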