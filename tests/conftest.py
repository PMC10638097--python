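"""Shared fixtures: phantom series and pipeline runs are expensive, so the
separation sweep and the whole-cell run are computed once per session."""

import numpy as np
import pytest

from contactsites import (
    DetectParams,
    cell_phantom_spec,
    contact_response,
    make_cell_phantom,
    make_two_object_phantom,
    run_detect,
    PhantomSpec,
)

#: separations (nm) from direct interaction up to the lateral resolution
SWEEP_SEPS = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0)
#: twice the lateral resolution: no contact can exist here
FAR_SEP = 240.0


@pytest.fixture(scope="session")
def default_params():
    return DetectParams()


@pytest.fixture(scope="session")
def sweep_phantoms():
    """Noise-free two-sphere phantoms over the sub-resolution sweep."""
    out = {}
    for sep in SWEEP_SEPS + (FAR_SEP,):
        pair, gt = make_two_object_phantom(PhantomSpec(separation_nm=sep, seed=1))
        out[sep] = (pair, gt)
    return out


@pytest.fixture(scope="session")
def sweep_responses(sweep_phantoms, default_params):
    """Raw gated responses for every phantom in the sweep."""
    return {
        sep: contact_response(pair, default_params)
        for sep, (pair, _) in sweep_phantoms.items()
    }


@pytest.fixture(scope="session")
def cell_bundle():
    """Standard whole-cell phantom and its full pipeline run."""
    spec = cell_phantom_spec(seed=7)
    pair, gt = make_cell_phantom(spec)
    result = run_detect(pair, DetectParams())
    return spec, pair, gt, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
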