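"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

import thermoprof as tp
from thermoprof.constants import K_B


def harmonic_delta_f_quadrature(
    k_a: float, k_b: float, temperature: float, dimensionality: int = 1
) -> float:
    """Independent oracle: dF from numerical quadrature of both partition
    functions, -kT ln(Z_B/Z_A) per dimension."""
    kt = K_B * temperature

    def z(k):
        val, _ = quad(lambda x: np.exp(-0.5 * k * x * x / kt), -np.inf, np.inf)
        return val

    return dimensionality * (-kt * np.log(z(k_b) / z(k_a)))


def gaussian_trans_entropy_oracle(sd: float, occupancy: float, bulk_density: float):
    """Closed-form S_trans for an isotropic Gaussian site, kcal/(mol K)."""
    h = 1.5 * np.log(2.0 * np.pi * np.e * sd * sd)
    return K_B * (h - np.log(occupancy / bulk_density))


def vmf_orient_entropy_oracle(kappa: float) -> float:
    """Closed-form S_orient for a von Mises-Fisher orientation distribution."""
    if kappa == 0.0:
        return 0.0
    a = 1.0 / np.tanh(kappa) - 1.0 / kappa
    h = -kappa * a + np.log(4.0 * np.pi * np.sinh(kappa) / kappa)
    return K_B * (h - np.log(4.0 * np.pi))


@pytest.fixture(scope="session")
def harmonic_spec():
    return tp.HarmonicSpec(force_constant_a=1.0, force_constant_b=2.0,
                           temperature=300.0)


@pytest.fixture(scope="session")
def small_planted_network():
    """Three well-separated sites over a sparse bulk, 2000 frames."""
    sites = (
        tp.SiteSpec((0.0, 0.0, 0.0), 0.25, 6.0, 1.0),
        tp.SiteSpec((3.0, 0.0, 0.0), 0.25, 3.0, 0.78),
        tp.SiteSpec((0.0, 3.0, 0.0), 0.25, 0.0, 0.9),
    )
    spec = tp.PlantedNetworkSpec(
        sites=sites, bulk_density=0.003, region_radius=6.0, n_frames=2000, seed=1234
    )
    return spec, tp.generate_water_network(spec)
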