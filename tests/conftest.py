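import numpy as np
import pytest

import cranioquant as cq


@pytest.fixture(scope="session")
def circle_spec():
    return cq.PhantomSpec(base_length_mm=120.0, base_width_mm=120.0)


@pytest.fixture(scope="session")
def ellipse_spec():
    # semi-axes 80 x 50 mm
    return cq.PhantomSpec(base_length_mm=160.0, base_width_mm=100.0)


@pytest.fixture(scope="session")
def scapho_spec():
    """A clearly scaphocephalic phantom: long, narrow, bossed and bulged."""
    return cq.PhantomSpec(
        base_length_mm=172.0,
        base_width_mm=112.0,
        frontal_bossing=0.03,
        occipital_bulge=0.04,
        temporal_narrowing=0.03,
    )


@pytest.fixture(scope="session")
def scapho_curve(scapho_spec):
    return cq.outline_to_curve(cq.make_outline(scapho_spec))


@pytest.fixture(scope="session")
def cohort_features():
    """Aligned-curve features for the standard 21-phantom cohort."""
    specs = cq.make_cohort(21, seed=7)
    return [cq.extract_features(cq.outline_to_curve(cq.make_outline(s))) for s in specs]


@pytest.fixture(scope="session")
def sphere_mask():
    """Digital sphere of radius 50 mm at 1 mm isotropic spacing."""
    return cq.make_volume(
        cq.PhantomSpec(base_length_mm=100.0, base_width_mm=100.0),
        n_slices=100,
        slice_spacing_mm=1.0,
    )


@pytest.fixture(scope="session")
def normative_table():
    return cq.make_normative_table()
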