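import numpy as np
import pandas as pd
import pytest

from pikasdm import evaluation as ev
from pikasdm import synthetic_data as sd
from pikasdm.raster_core import GridSpec, Layer, LayerStack


@pytest.fixture
def small_spec():
    return GridSpec(x_origin=0.0, y_origin=10.0, cell_size=1.0, n_rows=10, n_cols=10)


@pytest.fixture
def small_stack(small_spec):
    rng = np.random.default_rng(42)
    a = rng.normal(size=(10, 10))
    b = rng.normal(size=(10, 10))
    b[0, 0] = np.nan  # one nodata cell
    return LayerStack(
        small_spec,
        [Layer("alpha", "continuous", a), Layer("beta", "continuous", b)],
    )


@pytest.fixture(scope="session")
def default_study():
    """One default-profile synthetic study shared by the slower tests."""
    return sd.generate_study(seed=1)


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced hinge-knot count keeps replicate fits quick in tests."""
    return ev.ModelSettings(hinge_knots=8, threshold_knots=8)


@pytest.fixture
def toy_tables():
    """Tiny two-variable presence/background tables with a road-like signal."""
    rng = np.random.default_rng(7)
    n_bg = 200
    bg = pd.DataFrame(
        {"dist": rng.uniform(0, 30, n_bg), "noise": rng.normal(size=n_bg)}
    )
    pres = pd.DataFrame(
        {"dist": rng.uniform(0, 5, 40), "noise": rng.normal(size=40)}
    )
    kinds = {"dist": "continuous", "noise": "continuous"}
    return pres, bg, kinds
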