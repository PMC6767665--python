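"""Synthetic sample structures (depth profiles and two-channel scenes).

The reconstruction assumes the object's depth profile is sparse or at least
compressible, so the phantoms here are sparse reflector sets, single mirrors,
and layered scattering media with optional speckle — stand-ins for the
mirror / fish-fin / fish-eye / onion samples commonly imaged with bench
SD-OCT systems.

Depth is expressed in integer depth bins.  One bin corresponds to the axial
pixel of the Fourier-reconstructed A-scan: bin size = L / (N/2) where L is
the one-sided maximum imaging depth and N the spectral pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class DepthProfile:
    """Complex backscatter amplitude S_j on an integer depth-bin grid.

    ``amplitude[j]`` is the (dimensionless) backscattered field amplitude at
    depth-bin j of one interferometer channel; bin 0 sits at the channel's
    zero-path reference.
    """

    amplitude: np.ndarray
    bin_size_m: float | None = None
    channel: int | None = None

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=complex)
        if amp.ndim != 1:
            raise ValueError("depth profile must be 1-D")
        if not np.all(np.isfinite(amp)):
            raise ValueError("depth profile must be finite")
        self.amplitude = amp

    def __len__(self) -> int:
        return self.amplitude.size

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.amplitude))


@dataclass
class Scene:
    """Laterally ordered pairs of channel depth profiles.

    Mode 1: the two channels scan laterally adjacent regions of the same
    depth range (doubling the effective A-line rate).  Mode 2: channel 1
    holds the upper part of the object and channel 2 the part one full depth
    range deeper (doubling the depth range).
    """

    s1: np.ndarray  # (n_lateral, n_bins) complex
    s2: np.ndarray  # (n_lateral, n_bins) complex
    mode: int
    lateral_pitch_m: float = 10e-6
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=complex)
        self.s2 = np.asarray(self.s2, dtype=complex)
        if self.s1.shape != self.s2.shape or self.s1.ndim != 2:
            raise ValueError("s1/s2 must be 2-D arrays of equal shape")
        if self.mode not in (1, 2):
            raise ValueError("mode must be 1 or 2")

    @property
    def n_lateral(self) -> int:
        return self.s1.shape[0]

    @property
    def lateral_positions_m(self) -> np.ndarray:
        return np.arange(self.n_lateral) * self.lateral_pitch_m

    def profiles(self) -> list[tuple[DepthProfile, DepthProfile]]:
        return [
            (DepthProfile(self.s1[i], channel=1), DepthProfile(self.s2[i], channel=2))
            for i in range(self.n_lateral)
        ]


def sparse_reflectors(
    indices: Sequence[int],
    amplitudes: Sequence[complex],
    n: int,
    bin_size_m: float | None = None,
) -> DepthProfile:
    """Discrete reflectors: S_j = amplitude at the listed bins, 0 elsewhere."""
    indices = list(indices)
    amplitudes = list(amplitudes)
    if len(indices) != len(amplitudes):
        raise ValueError("indices and amplitudes must have equal length")
    if len(set(indices)) != len(indices):
        raise ValueError("reflector indices must be distinct")
    amp = np.zeros(n, dtype=complex)
    for j, a in zip(indices, amplitudes):
        if not 0 <= j < n:
            raise ValueError(f"reflector index {j} outside [0, {n})")
        amp[j] = a
    return DepthProfile(amp, bin_size_m=bin_size_m)


def mirror_phantom(
    depth_bin: int, amplitude: complex, n: int, bin_size_m: float | None = None
) -> DepthProfile:
    """A single specular reflector (bench mirror) at one depth bin."""
    if amplitude == 0:
        return DepthProfile(np.zeros(n, dtype=complex), bin_size_m=bin_size_m)
    return sparse_reflectors([depth_bin], [amplitude], n, bin_size_m=bin_size_m)


def layered_phantom(
    layer_bins: Sequence[int],
    layer_amps: Sequence[float],
    n: int,
    speckle_fraction: float = 0.0,
    attenuation_per_bin: float = 0.0,
    layer_width: int = 1,
    seed: int | None = None,
) -> DepthProfile:
    """Layered scattering medium with attenuation and optional speckle.

    Each layer occupies ``layer_width`` consecutive bins starting at its
    layer bin.  Amplitudes decay as exp(-attenuation_per_bin * j) with depth
    j, emulating signal loss in scattering tissue.  Speckle is circular
    complex Gaussian per occupied bin with relative strength
    ``speckle_fraction`` in [0, 1]; the deterministic part carries the
    remaining (1 - speckle_fraction) weight.  Deterministic given ``seed``.
    """
    if not 0.0 <= speckle_fraction <= 1.0:
        raise ValueError("speckle_fraction must lie in [0, 1]")
    if attenuation_per_bin < 0:
        raise ValueError("attenuation must be non-negative")
    if len(layer_bins) != len(layer_amps):
        raise ValueError("layer_bins and layer_amps must have equal length")
    rng = np.random.default_rng(seed)
    amp = np.zeros(n, dtype=complex)
    for b, a in zip(layer_bins, layer_amps):
        for j in range(b, min(b + layer_width, n)):
            base = a * np.exp(-attenuation_per_bin * j)
            if speckle_fraction > 0:
                g = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
                amp[j] += base * ((1.0 - speckle_fraction) + speckle_fraction * g)
            else:
                amp[j] += base
    return DepthProfile(amp)


def confocal_window(
    profile: DepthProfile, focal_bin: float, fwhm_bins: float
) -> DepthProfile:
    """Apply a Gaussian confocal-gate amplitude envelope (peak 1 at focus).

    Models the suppression of backscatter from outside the depth of focus;
    the envelope never exceeds 1, so it never increases |S| at any bin.
    """
    if fwhm_bins <= 0:
        raise ValueError("fwhm_bins must be positive")
    j = np.arange(len(profile))
    sigma = fwhm_bins / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    env = np.exp(-0.5 * ((j - focal_bin) / sigma) ** 2)
    return DepthProfile(
        profile.amplitude * env, bin_size_m=profile.bin_size_m, channel=profile.channel
    )


def two_channel_scene(
    mode: int,
    object_profiles: np.ndarray,
    channel_bins: int,
    lateral_pitch_m: float = 10e-6,
    lateral_offset_px: int = 0,
    seed: int | None = None,
) -> Scene:
    """Split an object into the two channels of the chosen imaging mode.

    Parameters
    ----------
    object_profiles
        2-D complex array (n_lateral_total, n_z) of the object's depth
        profiles, one row per lateral position.
    channel_bins
        Depth range (in bins) of one channel, i.e. 2*d.
    mode
        1: channels image laterally adjacent halves of the object at the
        same depth (n_z <= channel_bins; n_lateral_total must be even).
        2: channels image the upper and deeper halves of a thick object
        (n_z <= 2*channel_bins); channel 2 may be laterally offset by
        ``lateral_offset_px`` to emulate instrument misalignment.
    """
    obj = np.asarray(object_profiles, dtype=complex)
    if obj.ndim != 2:
        raise ValueError("object_profiles must be 2-D (lateral, depth)")
    n_x, n_z = obj.shape
    if mode == 1:
        if n_z > channel_bins:
            raise ValueError("mode-1 object deeper than one channel range")
        if n_x % 2:
            raise ValueError("mode 1 needs an even number of lateral positions")
        half = n_x // 2
        s1 = np.zeros((half, channel_bins), dtype=complex)
        s2 = np.zeros((half, channel_bins), dtype=complex)
        s1[:, :n_z] = obj[:half]
        s2[:, :n_z] = obj[half:]
    elif mode == 2:
        if n_z > 2 * channel_bins:
            raise ValueError("mode-2 object deeper than the combined range")
        upper = obj[:, : min(n_z, channel_bins)]
        deep = obj[:, channel_bins:] if n_z > channel_bins else obj[:, :0]
        s1 = np.zeros((n_x, channel_bins), dtype=complex)
        s2 = np.zeros((n_x, channel_bins), dtype=complex)
        s1[:, : upper.shape[1]] = upper
        if lateral_offset_px:
            # channel 2 sees the object shifted laterally; out-of-range
            # columns are empty
            shifted = np.zeros_like(deep)
            if lateral_offset_px < n_x:
                shifted[lateral_offset_px:] = deep[: n_x - lateral_offset_px]
            deep = shifted
        s2[:, : deep.shape[1]] = deep
    else:
        raise ValueError("mode must be 1 or 2")
    return Scene(
        s1=s1,
        s2=s2,
        mode=mode,
        lateral_pitch_m=lateral_pitch_m,
        seed=seed,
        meta={"lateral_offset_px": lateral_offset_px},
    )
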