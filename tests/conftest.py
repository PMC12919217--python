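import numpy as np
import pytest

import attsx
from attsx.atts import ScreenedPoissonConfig, compute_flux, solve_potential


@pytest.fixture(scope="session")
def toy_atlas():
    return attsx.make_toy_atlas()


@pytest.fixture(scope="session")
def curved_tube():
    """Noise-free curved-tube phantom on 48^3 with its ground-truth centerline."""
    n = 48
    t = np.linspace(0, np.pi / 2, 60)
    curve = np.stack(
        [6 + 30 * np.sin(t), 36 - 30 * np.cos(t), np.full_like(t, 24.0)], axis=1
    )
    spec = attsx.PhantomSpec(shape=(n, n, n), centerlines=[curve], tube_radius=1.5)
    vol, injection, _ = attsx.make_tube_phantom(spec)
    return vol, injection, curve


@pytest.fixture(scope="session")
def curved_tube_flux(curved_tube):
    """Solved potential and flux for the curved-tube phantom.

    alpha=1e-5 puts the decay length on the scale of the tube length so
    the flux carries current all the way to the distal end.
    """
    vol, injection, curve = curved_tube
    phi = solve_potential(vol, injection, ScreenedPoissonConfig(alpha=1e-5))
    flux = compute_flux(vol, phi)
    return vol, injection, curve, phi, flux


@pytest.fixture(scope="session")
def balanced_baseline():
    """Uniform 7x6 cortico-subcortical baseline after Sinkhorn balancing."""
    m = attsx.LabeledMatrix(
        np.ones((7, 6)), list(attsx.CORTICAL_PARCELS), list(attsx.SUBCORTICAL_PARCELS)
    )
    return attsx.sinkhorn_balance(m)
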