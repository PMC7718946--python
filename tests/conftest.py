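import numpy as np
import pytest

from mycstrat import CohortSimConfig, ExpressionMatrix, GeneSet, PhenotypeLabels, simulate_cohort


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with a clean two-class difference in gene A."""
    values = np.array(
        [
            [2.0, 2.0, 0.0, 0.0],  # up in first two samples
            [1.0, 1.0, 1.0, 1.0],  # flat
            [0.0, 1.0, 2.0, 3.0],  # gradient
        ]
    )
    return ExpressionMatrix(["A", "B", "C"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def two_class_labels() -> PhenotypeLabels:
    return PhenotypeLabels(["s1", "s2", "s3", "s4"], ["pos", "pos", "neg", "neg"], ("pos", "neg"))


@pytest.fixture
def planted_cohort():
    """Default study conditions: n=80, 10% MYC-high, effect 1.5 SD."""
    return simulate_cohort(CohortSimConfig(n_samples=80, seed=11))


@pytest.fixture
def wide_separation_cohort():
    """Strong effect (3 SD) for exact-recovery clustering checks."""
    return simulate_cohort(CohortSimConfig(n_samples=60, effect_size=3.0, seed=5))


@pytest.fixture
def myc_signature() -> GeneSet:
    return GeneSet("SIG", {"A", "B"}, "test signature")
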