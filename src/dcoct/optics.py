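"""Spectrometer pixel grids, unit conversions, and the dispersion-encoding phase.

A spectral-domain OCT spectrometer disperses the interference light onto a
line camera.  Depending on the optics, the pixel axis is (to good
approximation) linear either in wavelength or in wavenumber.  Depth
reconstruction by discrete Fourier transform assumes a uniform wavenumber
axis, so wavelength-linear data must be resampled first
(:func:`resample_to_linear_k`).

Dispersion encoding works by deliberately introducing a large unbalanced
dispersion between the reference and sample arms.  The resulting spectral
phase is modelled as a polynomial in the optical angular-frequency detuning

    phi(omega) = a2 * (omega - omega0)**2 + a3 * (omega - omega0)**3

with ``a2`` in s^2 (group-delay-dispersion scale, ~1e-27 s^2 = 1000 fs^2) and
``a3`` in s^3.  The bare coefficients quoted for dispersion-compensation of
BK7/ZF-type prism pairs (e.g. a2 = 7680e-30, a3 = 376e-45) only produce the
observed O(10 rad) band-edge phase under this seconds/angular-frequency
convention, which is therefore the one adopted and documented here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

#: Speed of light in vacuum [m/s].
C_M_S = 2.99792458e8


class GridDialect(str, enum.Enum):
    """Which variable is uniformly spaced across the pixel axis."""

    WAVELENGTH = "linear-wavelength"
    WAVENUMBER = "linear-wavenumber"


@dataclass(frozen=True)
class SpectrometerSpec:
    """Static description of the spectrometer.

    Parameters
    ----------
    center_wavelength_nm
        Center wavelength of the source/detection band [nm].
    bandwidth_nm
        Full detected bandwidth [nm].
    spectral_resolution_nm
        Wavelength extent of one resolvable spectral element [nm]; sets the
        maximum one-sided imaging depth lambda0^2 / (4 delta-lambda).
    n_pixels
        Number of camera pixels read out.
    """

    center_wavelength_nm: float = 790.0
    bandwidth_nm: float = 40.0
    spectral_resolution_nm: float = 0.05
    n_pixels: int = 960

    def __post_init__(self) -> None:
        for name in ("center_wavelength_nm", "bandwidth_nm", "spectral_resolution_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_pixels < 8:
            raise ValueError("n_pixels must be >= 8")
        if not self.bandwidth_nm > self.spectral_resolution_nm:
            raise ValueError("bandwidth must exceed the spectral resolution")

    @property
    def omega0_rad_s(self) -> float:
        """Angular optical frequency at the center wavelength [rad/s]."""
        return 2.0 * np.pi * C_M_S / (self.center_wavelength_nm * 1e-9)


@dataclass(frozen=True)
class SpectralGrid:
    """Pixel axis of a spectrometer in all three spectral variables.

    ``wavelength_nm`` is stored; omega = 2*pi*c/lambda and k = 2*pi/lambda are
    derived exactly, so the elementwise identities hold to machine precision.
    """

    wavelength_nm: np.ndarray
    dialect: GridDialect

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength axis must be a 1-D array of length >= 2")
        d = np.diff(wl)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotone")

    def __len__(self) -> int:
        return self.wavelength_nm.size

    @property
    def n_pixels(self) -> int:
        return self.wavelength_nm.size

    @property
    def wavenumber_rad_m(self) -> np.ndarray:
        """k = 2*pi/lambda [rad/m]."""
        return 2.0 * np.pi / (self.wavelength_nm * 1e-9)

    @property
    def omega_rad_s(self) -> np.ndarray:
        """omega = 2*pi*c/lambda = c*k [rad/s]."""
        return C_M_S * self.wavenumber_rad_m


@dataclass(frozen=True)
class DispersionSpec:
    """Polynomial dispersion phase coefficients.

    phi(omega) = a2*(omega-omega0)**2 + a3*(omega-omega0)**3, a2 in s^2 and a3
    in s^3 applied to the angular-optical-frequency detuning.
    """

    a2_s2: float
    a3_s3: float
    omega0_rad_s: float

    def __post_init__(self) -> None:
        if not self.omega0_rad_s > 0:
            raise ValueError("omega0 must be strictly positive")
        if not (np.isfinite(self.a2_s2) and np.isfinite(self.a3_s3)):
            raise ValueError("dispersion coefficients must be finite")

    @classmethod
    def from_center_wavelength(
        cls, a2_s2: float, a3_s3: float, center_wavelength_nm: float = 790.0
    ) -> "DispersionSpec":
        omega0 = 2.0 * np.pi * C_M_S / (center_wavelength_nm * 1e-9)
        return cls(a2_s2=a2_s2, a3_s3=a3_s3, omega0_rad_s=omega0)


def build_grid(
    spec: SpectrometerSpec, dialect: GridDialect = GridDialect.WAVENUMBER
) -> SpectralGrid:
    """Build the pixel axis spanning center +/- bandwidth/2.

    The axis is uniform in the dialect's linear variable.  For the
    wavenumber dialect the pixel axis ascends in k (wavelengths descend);
    for the wavelength dialect it ascends in wavelength.
    """
    dialect = GridDialect(dialect)
    lo = spec.center_wavelength_nm - spec.bandwidth_nm / 2.0
    hi = spec.center_wavelength_nm + spec.bandwidth_nm / 2.0
    if lo <= 0:
        raise ValueError("bandwidth too large: non-positive wavelength endpoint")
    if dialect is GridDialect.WAVELENGTH:
        wl = np.linspace(lo, hi, spec.n_pixels)
    else:
        k_lo = 2.0 * np.pi / (hi * 1e-9)
        k_hi = 2.0 * np.pi / (lo * 1e-9)
        k = np.linspace(k_lo, k_hi, spec.n_pixels)
        wl = 2.0 * np.pi / k * 1e9
    return SpectralGrid(wavelength_nm=wl, dialect=dialect)


def dispersion_phase(grid: SpectralGrid, disp: DispersionSpec) -> np.ndarray:
    """Per-pixel dispersion phase phi_i [rad].

    Zero coefficients give an identically zero phase; phi(omega0) = 0 always.
    """
    domega = grid.omega_rad_s - disp.omega0_rad_s
    return disp.a2_s2 * domega**2 + disp.a3_s3 * domega**3


def resample_to_linear_k(
    spectrum: np.ndarray, grid: SpectralGrid
) -> tuple[np.ndarray, SpectralGrid]:
    """Cubic-spline resample a spectrum onto a uniform-wavenumber axis.

    The output grid shares the input's wavenumber endpoints and pixel count.
    Input already uniform in k is returned unchanged (idempotence).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (grid.n_pixels,):
        raise ValueError("spectrum length does not match grid")
    k = grid.wavenumber_rad_m
    k_uniform = np.linspace(k[0], k[-1], k.size)
    if np.allclose(k, k_uniform, rtol=0, atol=1e-9 * abs(k_uniform[1] - k_uniform[0])):
        out_grid = SpectralGrid(grid.wavelength_nm.copy(), GridDialect.WAVENUMBER)
        return spectrum.copy(), out_grid
    # CubicSpline needs ascending abscissae; k descends on an ascending-
    # wavelength axis.
    if k[0] > k[-1]:
        spline = CubicSpline(k[::-1], spectrum[::-1])
    else:
        spline = CubicSpline(k, spectrum)
    resampled = spline(k_uniform)
    out_grid = SpectralGrid(2.0 * np.pi / k_uniform * 1e9, GridDialect.WAVENUMBER)
    return resampled, out_grid
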