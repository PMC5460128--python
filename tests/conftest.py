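import numpy as np
import pytest

from peristroma import CohortConfig
from peristroma.classify import EAConfig, REDUCED_EA, ea_feature_pool
from peristroma.features import feature_matrix
from peristroma.pipeline import PipelineConfig, compute_feature_table


@pytest.fixture(scope="session")
def small_table():
    """Feature table of a 16-case synthetic cohort (cheap shared fixture)."""
    config = PipelineConfig(cohort=CohortConfig(n_cases=16, seed=2), seed=2)
    return compute_feature_table(config)


@pytest.fixture(scope="session")
def cohort80():
    """Default 80-case study cohort: (table, X, y, names)."""
    config = PipelineConfig(cohort=CohortConfig(n_cases=80, seed=3), seed=3)
    table = compute_feature_table(config)
    X, y, names = feature_matrix(table)
    return table, X, y, names


@pytest.fixture(scope="session")
def ea_pool80(cohort80):
    """EA feature pool for the default cohort at the reduced budget."""
    _, X, y, _ = cohort80
    return ea_feature_pool(X, y, EAConfig(**REDUCED_EA, seed=3))


def random_blob(rng: np.random.Generator, shape=(56, 56)) -> np.ndarray:
    """A random single-component blob mask with room for all shells."""
    from scipy import ndimage

    margin = 24
    centre = rng.integers(margin, np.array(shape) - margin + 1)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    a, b = rng.uniform(3, 8, size=2)
    theta = rng.uniform(0, np.pi)
    x = (rr - centre[0]) * np.cos(theta) + (cc - centre[1]) * np.sin(theta)
    z = -(rr - centre[0]) * np.sin(theta) + (cc - centre[1]) * np.cos(theta)
    blob = (x / a) ** 2 + (z / b) ** 2 <= 1.0
    lab, n = ndimage.label(blob)
    if n > 1:  # keep one component so the precondition holds
        sizes = ndimage.sum_labels(blob, lab, index=range(1, n + 1))
        blob = lab == (int(np.argmax(sizes)) + 1)
    return blob
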