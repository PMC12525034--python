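"""Shared fixtures: a session-scoped Monte Carlo lookup table and a fast
analytic (diffusion-based) synthetic table for mechanics-only tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swirsfdi import (
    ExtinctionTable,
    MCConfig,
    MediumSpec,
    ReflectanceLUT,
    build_lut,
    diffusion_rd,
    intralipid_phantom_spec,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Coarse full-range build: 24x24 nodes over the default grid spans at 1e5
# photons per reduced-scattering value (enough for strict monotonicity to
# resolve above Monte Carlo noise).
MC_LUT_SHAPE = (24, 24)
MC_LUT_PHOTONS = 100_000
MC_LUT_SEED = 20260926 % (2**31)


@pytest.fixture(scope="session")
def mc_lut() -> ReflectanceLUT:
    """Full-range Monte Carlo lookup table shared across the session."""
    mu_a = np.geomspace(1e-3, 0.5, MC_LUT_SHAPE[0])
    mu_s = np.geomspace(0.3, 5.0, MC_LUT_SHAPE[1])
    return build_lut(
        mu_a,
        mu_s,
        (0.0, 0.1),
        MCConfig(n_photons=MC_LUT_PHOTONS),
        seed=MC_LUT_SEED,
    )


def make_synthetic_lut(
    n_mu_a: int = 40,
    n_mu_s: int = 40,
    n_rel: float = 1.0,
    fx_ac: float = 0.1,
) -> ReflectanceLUT:
    """Analytic stand-in lookup table built from the closed-form diffusion
    reflectance (synthetic; smooth and exactly monotone, no Monte Carlo).

    Useful for testing interpolation, inversion and rendering mechanics
    without paying for photon transport. The mu_s' floor stays in the
    diffusive domain (fx * transport mfp small) where the closed form is
    monotone in absorption.
    """
    import warnings

    mu_a_grid = np.geomspace(1e-3, 0.5, n_mu_a)
    mu_s_grid = np.geomspace(0.3, 5.0, n_mu_s)
    R = np.zeros((n_mu_a, n_mu_s, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # low-albedo corners of the grid
        for i, mua in enumerate(mu_a_grid):
            for j, mus in enumerate(mu_s_grid):
                m = MediumSpec(float(mua), float(mus), 0.9, n_rel, 1.0)
                R[i, j, 0] = diffusion_rd(m, 0.0)
                R[i, j, 1] = diffusion_rd(m, fx_ac)
    lut = ReflectanceLUT(
        mu_a_grid=mu_a_grid,
        mu_s_prime_grid=mu_s_grid,
        fx_list=np.array([0.0, fx_ac]),
        R=R,
        meta={"synthetic": "diffusion closed form", "n_medium": n_rel},
    )
    lut.validate()
    return lut


@pytest.fixture(scope="session")
def synthetic_lut() -> ReflectanceLUT:
    return make_synthetic_lut()


@pytest.fixture(scope="session")
def extinction() -> ExtinctionTable:
    return ExtinctionTable.from_csv()


@pytest.fixture(scope="session")
def wavelengths():
    return [970.0, 1050.0, 1200.0]


@pytest.fixture(scope="session")
def phantom(extinction, wavelengths):
    return intralipid_phantom_spec(wavelengths, extinction)
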