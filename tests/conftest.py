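"""Shared fixtures: analytic oracles and small synthetic datasets."""

import numpy as np
import pytest

from saxstruct.curves import ScatteringCurve
from saxstruct.synth import DomainSpec, make_toy_structure, sphere_oracles


@pytest.fixture(scope="session")
def sphere30():
    """Analytic uniform-sphere oracle, R = 30 A."""
    return sphere_oracles(30.0)


@pytest.fixture(scope="session")
def sphere_curve_clean(sphere30):
    """Noiseless sphere curve on the standard q grid."""
    return sphere30.curve(noise=(0.0, 0.0))


@pytest.fixture(scope="session")
def sphere_curve_noisy(sphere30):
    """Sphere curve with the default 1% q-growing noise."""
    return sphere30.curve(noise=(0.01, 4.0), seed=11)


@pytest.fixture(scope="session")
def exact_guinier_curve():
    """Pure Guinier curve: I = 100 exp(-q^2 25^2 / 3)."""
    q = np.linspace(0.005, 0.05, 60)
    I = 100.0 * np.exp(-(q**2) * 25.0**2 / 3.0)
    return ScatteringCurve(q=q, I=I, sigma=0.01 * I, label="exact guinier")


@pytest.fixture(scope="session")
def dumbbell_toy():
    """Two ellipsoidal domains joined by a 10-residue linker."""
    return make_toy_structure(
        [DomainSpec(shape="ellipsoid", radius=(16, 10, 8)),
         DomainSpec(shape="ellipsoid", radius=(16, 10, 8))],
        linker_residues=[10], seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
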