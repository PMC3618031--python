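import numpy as np
import pandas as pd
import pytest

import orthomix as om
from orthomix.mixture import N_COMPONENTS


def build_params(weights, mean_a=None, mean_h=None, var_a=None, var_h=None, corr=None):
    """Construct valid MixtureParameters with sensible defaults."""
    z = np.zeros(N_COMPONENTS)
    return om.MixtureParameters(
        weights=np.asarray(weights, dtype=float),
        mean_a=z if mean_a is None else np.asarray(mean_a, dtype=float),
        mean_h=z if mean_h is None else np.asarray(mean_h, dtype=float),
        var_a=np.ones(N_COMPONENTS) if var_a is None else np.asarray(var_a, dtype=float),
        var_h=np.ones(N_COMPONENTS) if var_h is None else np.asarray(var_h, dtype=float),
        corr=z if corr is None else np.asarray(corr, dtype=float),
    )


@pytest.fixture
def make_params():
    return build_params


@pytest.fixture
def reference_params():
    return om.reference_mixture()


@pytest.fixture
def null_params():
    """All mass in the null component, unit variances."""
    w = np.zeros(N_COMPONENTS)
    w[0] = 1.0
    return build_params(w)


@pytest.fixture
def separated_params():
    """Three well-separated active components (0, 1, 2); means >= 5 SDs apart."""
    w = np.zeros(N_COMPONENTS)
    w[[0, 1, 2]] = [0.5, 0.25, 0.25]
    return build_params(
        w,
        mean_a=[0, 2, -2, 0, 0, 0, 0, 0, 0],
        mean_h=[0, 2, -2, 0, 0, 0, 0, 0, 0],
        var_a=np.full(N_COMPONENTS, 0.04),
        var_h=np.full(N_COMPONENTS, 0.04),
    )


def make_expression(values, treatment, gene_ids=None, sample_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
    return om.ExpressionSet(values=frame, treatment=np.asarray(treatment, dtype=int))


@pytest.fixture
def expression_factory():
    return make_expression
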