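import numpy as np
import pytest

from gedinet import ExpressionDataset, GroupCatalog


def make_dataset(values, labels, genes=None, samples=None) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionDataset(
        samples=tuple(samples) if samples else tuple(f"s{i}" for i in range(n)),
        genes=tuple(genes) if genes else tuple(f"g{j}" for j in range(m)),
        values=values,
        labels=tuple(labels),
    )


def random_two_class(rng, n_pos=10, n_neg=10, n_genes=5, shift=0.0) -> ExpressionDataset:
    values = rng.normal(size=(n_pos + n_neg, n_genes))
    values[:n_pos] += shift
    return make_dataset(values, ["pos"] * n_pos + ["neg"] * n_neg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_catalog():
    return GroupCatalog(
        groups={
            "dA": frozenset({"g0", "g1", "g2"}),
            "dB": frozenset({"g2", "g3"}),
            "dC": frozenset({"gX", "gY"}),  # absent from most toy datasets
        }
    )
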