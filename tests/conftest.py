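import numpy as np
import pytest

from firerisk.features import build_features
from firerisk.maxent import fit, sample_background, split_sample
from firerisk.raster import Grid, Layer
from firerisk.synthetic import LandscapeConfig, generate_landscape, sample_hotspots


@pytest.fixture
def grid5():
    return Grid(5, 5, cell_size=1.0)


@pytest.fixture(scope="session")
def small_landscape():
    """60x60 synthetic landscape shared by the cheaper integration tests."""
    return generate_landscape(LandscapeConfig(n_rows=60, n_cols=60), seed=7)


@pytest.fixture(scope="session")
def small_fit(small_landscape):
    """One fitted model on the small landscape, with its supporting pieces."""
    ls = small_landscape
    presences = sample_hotspots(ls.truth, 1200, seed=11)
    train, test = split_sample(presences, 0.25, seed=12)
    background = sample_background(ls.stack.grid, seed=13)
    expansion = build_features(ls.stack, background_cells=background)
    model = fit(train, background, expansion, ls.stack)
    return {
        "landscape": ls,
        "presences": presences,
        "train": train,
        "test": test,
        "background": background,
        "expansion": expansion,
        "model": model,
    }


def constant_layer(grid, value, name="const"):
    return Layer(grid=grid, name=name, values=np.full(grid.shape, float(value)))
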