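import numpy as np
import pytest

import nemaglide as ng


@pytest.fixture(scope="session")
def canonical_plus_half():
    """φ = θ/2 comet defect at the grid centre, 0.5 µm/px, 50×50 µm."""
    spec = ng.FieldSpec(
        (101, 101), 0.5, 0.0, [ng.DefectSpec((25.0, 25.0), 0.5)]
    )
    return ng.make_field(spec)


@pytest.fixture(scope="session")
def uniform_field():
    """Uniform horizontal director on a 40×40 µm grid."""
    return ng.DirectorField(np.zeros((81, 81)), 0.5)


@pytest.fixture(scope="session")
def random_six_defect():
    """Seeded random field with 6 half-integer defects, net charge 0."""
    spec = ng.random_field_spec((201, 201), 0.5, 6, 0.0, seed=5)
    return spec, ng.make_field(spec)


@pytest.fixture(scope="session")
def pair_field():
    """Two +1/2 defects whose axes point at each other (background −π/2)."""
    spec = ng.FieldSpec(
        (121, 121),
        0.5,
        -np.pi / 2,
        [ng.DefectSpec((20.0, 30.0), 0.5), ng.DefectSpec((40.0, 30.0), 0.5)],
    )
    return spec, ng.make_field(spec)
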