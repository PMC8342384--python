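import warnings

import numpy as np
import pytest

from ocusim import wavefront
from ocusim.eye_model import (build_phakic_eye, build_pseudophakic_eye,
                              design_aberration_correcting_iol,
                              make_equiconvex_iol)

FOCUS_GRID_N = 48


@pytest.fixture(scope="session")
def phakic_focused():
    eye = build_phakic_eye()
    wavefront.focus_system(eye, grid_n=FOCUS_GRID_N)
    return eye


@pytest.fixture(scope="session")
def aspheric_iol():
    return design_aberration_correcting_iol()


@pytest.fixture(scope="session")
def spherical_iol():
    return make_equiconvex_iol()


@pytest.fixture(scope="session")
def pseudophakic_focused(phakic_focused, aspheric_iol):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_pseudophakic_eye(phakic_focused, aspheric_iol,
                                      focus_grid_n=FOCUS_GRID_N)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
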