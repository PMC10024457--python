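import numpy as np
import pytest

from leafpol.synthetic import (
    ScanSetSpec,
    SurfaceSpec,
    default_feature_spec,
    generate_feature_dataset,
    generate_polarized_scanset,
    generate_surface,
)


@pytest.fixture(scope="session")
def default_surface():
    return generate_surface(SurfaceSpec(), seed=11)


@pytest.fixture(scope="session")
def default_scanset():
    return generate_polarized_scanset(ScanSetSpec(), seed=11)


@pytest.fixture(scope="session")
def balanced_features():
    """4 x 50 labeled feature rows from the default phenotype clouds."""
    return generate_feature_dataset(default_feature_spec(50), seed=11)


def shoelace_area(vertices: np.ndarray) -> float:
    """Independent polygon-area oracle (shoelace formula)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
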