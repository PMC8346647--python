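"""Shared fixtures: models, noise-free curves, and the expensive fits.

Session scope keeps the two nonlinear fits (cellulose 1-component,
lignin 4-component) shared between the unit suite and the acceptance
round-trip checks.
"""

import numpy as np
import pytest

from pyrodaem import (
    FitConfig,
    RateCurve,
    cellulose_fixture,
    default_grid,
    fit_daem,
    lignin_fixture,
    mixture_rate,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def cellulose_model():
    return cellulose_fixture("gaussian")[0]


@pytest.fixture(scope="session")
def lignin_model():
    return lignin_fixture("gaussian")[0]


def as_measured(curve: RateCurve) -> RateCurve:
    return RateCurve(curve.temperature, curve.rate, source="measured")


@pytest.fixture(scope="session")
def cellulose_curve(cellulose_model, grid):
    """Noise-free cellulose DTG on the analysis grid."""
    return as_measured(mixture_rate(cellulose_model, grid))


@pytest.fixture(scope="session")
def lignin_curve(lignin_model, grid):
    """Noise-free 4-component lignin DTG on the analysis grid."""
    return as_measured(mixture_rate(lignin_model, grid))


@pytest.fixture(scope="session")
def cellulose_fit(cellulose_curve):
    return fit_daem(
        cellulose_curve, FitConfig(n_components=1, family="gaussian", seed=1)
    )


@pytest.fixture(scope="session")
def lignin_fit(lignin_curve):
    return fit_daem(
        lignin_curve, FitConfig(n_components=4, family="gaussian", seed=1)
    )
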