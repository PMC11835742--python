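"""Shared fixtures: small synthetic geometries, couplings, and simulated subjects."""

import numpy as np
import pytest

import neuroturb as nt


@pytest.fixture(scope="session")
def geom60():
    return nt.generate_geometry(60, seed=1)


@pytest.fixture(scope="session")
def connectome60(geom60):
    return nt.generate_connectome(geom60, n_longrange=40, seed=2)


@pytest.fixture(scope="session")
def coupling60(geom60, connectome60):
    return nt.build_coupling(geom60, connectome60)


@pytest.fixture(scope="session")
def omegas60():
    rng = np.random.default_rng(0)
    return 2 * np.pi * rng.uniform(0.04, 0.07, 60)


@pytest.fixture(scope="session")
def subject_bold(coupling60, omegas60):
    """One simulated 60-region, 300-volume subject at TR = 2 s."""
    params = nt.HopfParams(omegas=omegas60, G=1.3, duration=600.0, seed=37)
    return nt.simulate(params, coupling60, out_tr=2.0)


@pytest.fixture(scope="session")
def subject_profile(subject_bold, geom60):
    return nt.compute_profile(subject_bold, geom60)


@pytest.fixture(scope="session")
def geom20():
    return nt.generate_geometry(20, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
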