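"""Shared fixtures: small synthetic studies and pre-trained models.

Everything is generated programmatically and seeded; the "small" study
keeps gene counts low so model-training fixtures stay fast while
exercising the full pipeline.
"""

import numpy as np
import pytest

from cpop import (
    CPOPConfig,
    GeneExpressionMatrix,
    SyntheticStudyConfig,
    fit_cpop,
    generate_multiplatform_study,
)


@pytest.fixture(scope="session")
def small_study():
    """Three small platforms (n=80, p=20, 3 signal ratios) plus truth."""
    cfg = SyntheticStudyConfig(seed=11, n_datasets=3, n_per_dataset=80, p=20,
                               n_signal_ratios=3)
    return generate_multiplatform_study(cfg)


@pytest.fixture(scope="session")
def small_model(small_study):
    """CPOP model trained on the first two small platforms."""
    datasets, _ = small_study
    (X1, y1), (X2, y2) = datasets[0], datasets[1]
    return fit_cpop(X1, y1, X2, y2, CPOPConfig(family="binomial", seed=3))


@pytest.fixture(scope="session")
def small_survival_study():
    """Survival-outcome version of the small study."""
    cfg = SyntheticStudyConfig(seed=13, n_datasets=3, n_per_dataset=80, p=20,
                               n_signal_ratios=3, outcome_kind="survival")
    return generate_multiplatform_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_expression(rng, n=6, p=4, prefix="G"):
    genes = [f"{prefix}{j:02d}" for j in range(p)]
    samples = [f"S{i}" for i in range(n)]
    return GeneExpressionMatrix(rng.normal(8.0, 1.0, size=(n, p)), samples,
                                genes)


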