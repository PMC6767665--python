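import numpy as np
import pytest

from dcoct import SpectrometerSpec, build_grid, demos


@pytest.fixture(scope="session")
def spec960() -> SpectrometerSpec:
    """The 790 nm / 40 nm, 960-pixel bench spectrometer."""
    return SpectrometerSpec()


@pytest.fixture(scope="session")
def grid960(spec960):
    return build_grid(spec960)


@pytest.fixture(scope="session")
def phase1024() -> np.ndarray:
    """Mirror-experiment dispersion phase on the 1024-pixel simulation grid."""
    return demos.spectral_phase(1024, "mirror")


@pytest.fixture(scope="session")
def fig3_signal() -> np.ndarray:
    """The three-reflector sparse full-range signal on 1024 bins."""
    from dcoct import sparse_reflectors

    c = demos.FIG3_CONDITIONS
    return sparse_reflectors(c["bins"], c["amplitudes"], c["n"]).amplitude
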