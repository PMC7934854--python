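import numpy as np
import pytest
from hypothesis import settings

import retmosaic as rm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_mosaic():
    """The reference mosaic: 2000 nuclei, 20% dim, 10% clustered, default noise."""
    truth = rm.generate_flatmount(rm.FlatMountSpec(seed=0))
    cone_set = rm.count_cones(truth.image, truth.retina_mask)
    return truth, cone_set


@pytest.fixture(scope="session")
def small_mosaic():
    """A quick mosaic for unit tests (384 px, 300 nuclei)."""
    spec = rm.FlatMountSpec(
        seed=9, image_height_px=384, image_width_px=384, retina_radius_px=180.0, n_cones=300
    )
    truth = rm.generate_flatmount(spec)
    cone_set = rm.count_cones(truth.image, truth.retina_mask)
    return truth, cone_set


@pytest.fixture(scope="session")
def de_bundle():
    spec = rm.DETableSpec(seed=2)
    table_a, table_b, term_map, planted = rm.generate_de_tables(spec)
    return spec, table_a, table_b, term_map, planted


@pytest.fixture(scope="session")
def em_field():
    spec = rm.EMFieldSpec(seed=4)
    image, masks, fractions = rm.generate_em_field(spec)
    return spec, image, masks, fractions


def noiseless_spec(**kw):
    base = dict(noise_sd=0.0, shot_noise=False)
    base.update(kw)
    return rm.FlatMountSpec(**base)


@pytest.fixture(scope="session")
def uniform_points_10k():
    """10,000 points uniform over the default retina disc, with its mask."""
    rng = np.random.default_rng(0)
    n = 10_000
    R = 480.0
    u = rng.uniform(0, 1, n)
    th = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack(
        [511.5 + R * np.sqrt(u) * np.cos(th), 511.5 + R * np.sqrt(u) * np.sin(th)]
    )
    rr, cc = np.ogrid[:1024, :1024]
    mask = (rr - 511.5) ** 2 + (cc - 511.5) ** 2 <= R**2
    return pts, mask
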