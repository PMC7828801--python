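import numpy as np
import pytest
from hypothesis import settings

import dismap as dm
from dismap.models import build_design, fit_model, model_spec
from dismap.spatial import SpatialWeights

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lattice():
    return dm.generate_lattice(40, (14, 12, 14), seed=3)


@pytest.fixture(scope="session")
def small_bundle():
    """40 areas, 2 years, IID area heterogeneity; the workhorse fixture."""
    return dm.make_bundle(
        n_areas=40, subarea_sizes=(14, 12, 14), years=[2010, 2011], seed=7,
        re_kind="iid", re_sd=0.15,
    )


@pytest.fixture(scope="session")
def small_design(small_bundle):
    return build_design(small_bundle)


@pytest.fixture(scope="session")
def small_weights(small_bundle):
    return SpatialWeights.from_lattice(small_bundle.lattice)


@pytest.fixture(scope="session")
def m2a_fit(small_design, small_weights):
    """A reference-quality M2A fit on the small bundle (4 chains)."""
    return fit_model(
        model_spec("M2A"), small_design, weights=small_weights,
        chains=4, draws=800, warmup=800, seed=42,
    )
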