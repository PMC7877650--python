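import numpy as np
import pytest

from lgclust import (
    SyntheticSpec,
    ValidityDomain,
    build_lgc,
    generate_csr,
    generate_fixture,
    make_radius_grid,
    preprocess,
)


@pytest.fixture(scope="session")
def unit_square():
    return ValidityDomain.box(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def square_with_hole():
    """Unit square with a central square hole of 20% area."""
    hole_side = np.sqrt(0.2)
    lo, hi = 0.5 - hole_side / 2, 0.5 + hole_side / 2
    return ValidityDomain.from_rings(
        [(0, 0), (1, 0), (1, 1), (0, 1)],
        [[(lo, lo), (hi, lo), (hi, hi), (lo, hi)]],
    )


@pytest.fixture(scope="session")
def csr_square_pattern(unit_square):
    return generate_csr(unit_square, 20000, seed=42)


@pytest.fixture(scope="session")
def blobs_pattern():
    return generate_fixture(SyntheticSpec("blobs", 3000, seed=3))


@pytest.fixture(scope="session")
def blobs_features(blobs_pattern):
    radii = make_radius_grid(300, 10000, 25)
    lgc = build_lgc(blobs_pattern, radii)
    return preprocess(lgc), lgc
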