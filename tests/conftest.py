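"""Shared fixtures: generated studies and fitted models at several scales."""

import dataclasses

import pytest

import baclopk as b
from baclopk.engine import FitSettings
from baclopk.study import default_design


def small_design(sizes=(4, 5, 5, 6)):
    """The trial design scaled down to fewer subjects per dose group."""
    d = default_design()
    groups = tuple(dataclasses.replace(g, n=m) for g, m in zip(d.groups, sizes))
    return dataclasses.replace(d, groups=groups)


@pytest.fixture(scope="session")
def fast_settings():
    """Looser outer tolerances for refit-heavy procedures (search, bootstrap)."""
    return FitSettings(outer_tol=1e-7, outer_maxiter=60, outer_restarts=0,
                       inner_gtol=1e-6)


@pytest.fixture(scope="session")
def init_model():
    return (b.ThetaVector(10.0, 50.0, 1.0), b.OmegaMatrix.from_sd(0.3, 0.3, 0.3),
            b.SigmaModel(0.3))


@pytest.fixture(scope="session")
def study1():
    """One full-scale (57-subject) virtual study at the published truth."""
    return b.simulate_study(seed=1)


@pytest.fixture(scope="session")
def fit1(study1, init_model):
    """Converged fit of the full-scale study."""
    fr = b.fit(study1.dataset, *init_model)
    assert fr.converged
    return fr


@pytest.fixture(scope="session")
def small_study():
    """20-subject study for cheap estimation tests."""
    return b.simulate_study(design=small_design(), seed=42)


@pytest.fixture(scope="session")
def small_fit(small_study, init_model, fast_settings):
    fr = b.fit(small_study.dataset, *init_model, settings=fast_settings)
    assert fr.converged
    return fr
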