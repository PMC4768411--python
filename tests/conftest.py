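import numpy as np
import pytest

from mdfdr.data import ExpressionMatrix, GroupDesign


@pytest.fixture
def balanced_design():
    """4 groups of 10 samples, reference last (the study configuration)."""
    labels = [f"g{i}" for i in (1, 2, 3) for _ in range(10)] + ["ref"] * 10
    return GroupDesign(labels, "ref")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(rng, design, m=50, effects=None):
    """Gaussian dataset; ``effects`` is an optional {feature: (q,) mean} map."""
    values = rng.standard_normal((m, design.n_samples))
    if effects:
        for j, mu in effects.items():
            for i, g in enumerate(design.experimental_labels):
                values[j, design.indices(g)] += mu[i]
    return ExpressionMatrix(values, [f"f{j}" for j in range(m)])


@pytest.fixture
def make_data(rng):
    def _make(design, m=50, effects=None):
        return make_dataset(rng, design, m=m, effects=effects)

    return _make
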