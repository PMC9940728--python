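import numpy as np
import pytest

import phantomkit as pk


@pytest.fixture(scope="session")
def grid():
    return pk.DEFAULT_GRID


@pytest.fixture(scope="session")
def basis():
    """Synthetic 20-pigment basis shared across the suite."""
    return pk.generate_synthetic_basis(seed=1)


@pytest.fixture(scope="session")
def record_epoxy():
    """Reference white-MC record at the epoxy refractive index (n=1.56)."""
    cfg = pk.TransportConfig(n_medium=1.56, g=0.8, n_photons=20_000, seed=7)
    return pk.run_reference(cfg)


@pytest.fixture(scope="session")
def record_matched():
    """Index-matched record for energy-conservation and diffusion checks."""
    cfg = pk.TransportConfig(n_medium=1.0, g=0.8, n_photons=50_000, seed=11)
    return pk.run_reference(cfg)


@pytest.fixture(scope="session")
def chromophores():
    return pk.synthetic_chromophores()


@pytest.fixture(scope="session")
def hemoglobin_like_target(basis, chromophores):
    """A skin-like optical-property target on the full design grid.

    Absorption from the chromophore model resampled/extended to 370-950 nm,
    scattering from a tissue-like Mie-Rayleigh power law.  Not representable
    by the pigment basis, emulating a real tissue target.
    """
    grid = basis.grid
    ch = pk.synthetic_chromophores(grid)  # analytic, so any grid works
    mua = pk.skin_mua(pk.SkinParams(StO2=0.7), ch)
    musp = pk.power_law_eval(pk.PowerLawParams(2.0, 0.15, 1.3), grid)
    return pk.TissueTarget(mua, musp, label="skin-like")
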