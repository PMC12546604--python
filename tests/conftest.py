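import numpy as np
import pytest

import cpcausal as cp
from cpcausal.render import RenderParams


@pytest.fixture(scope="session")
def library():
    return cp.make_compound_library(12, 3, 6, seed=7)


@pytest.fixture(scope="session")
def design(library):
    return cp.make_design(
        n_sources=2,
        n_batches_per_source=2,
        n_plates_per_batch=1,
        plate_rows=4,
        plate_cols=6,
        fovs_per_well=1,
        compounds=library,
        allocation_bias=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def params(design):
    return cp.ScmParams.random(7, 64, cp.confounder_code_dim(design), seed=7)


@pytest.fixture(scope="session")
def render_params():
    return RenderParams()


@pytest.fixture(scope="session")
def small_dataset(design, params, library, render_params):
    """One simulated experiment: 96 images with ground truth."""
    records, table = cp.generate_dataset(design, params, library, render_params, rng=7)
    return records, table


@pytest.fixture(scope="session")
def example_image(render_params):
    return cp.render_image(np.zeros(7), render_params=render_params, rng=0)
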