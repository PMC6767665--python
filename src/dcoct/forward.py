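"""Forward interferogram model for the dual-channel single-spectrometer system.

Both channels share one spectrometer.  A pre-introduced reference path offset
of +d (channel 1) and -d (channel 2) depth bins separates their depth windows
so that channel 1 occupies [0, 2d) and channel 2 (-2d, 0] after
reconstruction.  Writing the combined full-range complex profile as u (length
N, negative depths stored at index N-j under the DFT wraparound convention),
the detected real spectrum is

    f_i = 2 R * Re[ exp(i*phi_i) * (F u)_i ]          (F = unnormalised DFT)

where R is the reference-arm amplitude and phi the deliberately introduced
dispersion phase.  With the default R = 1/2 a unit reflector at bin m yields
exactly f_i = cos(2*pi*m*i/N), and the matched-phase inverse transform
(see :mod:`dcoct.recon`) returns the input amplitudes unchanged — the whole
pipeline is amplitude preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phantom import DepthProfile, Scene


@dataclass
class ForwardConfig:
    """Detection model parameters.

    ``reference_amplitude`` is R in the 2R*Re[...] spectrum model.  DC and
    autocorrelation terms are omitted by default (real systems subtract the
    reference DC; sample autocorrelation is weak for dilute scatterers);
    ``include_autocorrelation`` adds a stylised |sample field|^2 term plus a
    reference DC pedestal for stress testing.
    """

    reference_amplitude: float = 0.5
    include_autocorrelation: bool = False
    noise_sigma: float = 0.0
    shot_noise: bool = False
    shot_floor: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.reference_amplitude > 0:
            raise ValueError("reference amplitude must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass
class Interferogram:
    """A real single-spectrometer spectrum (counts per pixel)."""

    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1:
            raise ValueError("interferogram must be 1-D")
        if not np.all(np.isfinite(c)):
            raise ValueError("interferogram must be finite")
        self.counts = c

    def __len__(self) -> int:
        return self.counts.size


def as_spectrum(f) -> np.ndarray:
    """Return the raw counts array of an Interferogram or array-like."""
    if isinstance(f, Interferogram):
        return f.counts
    return np.asarray(f, dtype=float)


def embed_full_range(
    s1: DepthProfile | np.ndarray | None,
    s2: DepthProfile | np.ndarray | None,
    d: int,
    n: int,
) -> np.ndarray:
    """Place the two channel profiles on the length-N full-range depth axis.

    Channel-1 bin j maps to index j (depth +j); channel-2 bin j maps to index
    (N - j) % N (depth -j, stored in the upper half under the DFT wraparound
    convention).  Bin 0 of both channels is the shared zero-path bin at
    index 0.  Each profile must fit within its 2d-bin window.
    """
    if not 0 < d <= n // 2:
        raise ValueError("offset d must satisfy 0 < d <= N/2 bins")
    u = np.zeros(n, dtype=complex)
    for which, prof in ((1, s1), (2, s2)):
        if prof is None:
            continue
        amp = prof.amplitude if isinstance(prof, DepthProfile) else np.asarray(prof, dtype=complex)
        if amp.size > 2 * d:
            raise ValueError(
                f"channel-{which} profile of {amp.size} bins exceeds the "
                f"2d = {2 * d} bin window (channel overlap)"
            )
        if which == 1:
            u[: amp.size] += amp
        else:
            idx = (n - np.arange(amp.size)) % n
            np.add.at(u, idx, amp)
    return u


def synthesize(
    u: np.ndarray,
    phase: np.ndarray,
    config: ForwardConfig | None = None,
) -> Interferogram:
    """Synthesize the real spectrum f = 2R*Re[exp(i*phi) . DFT(u)].

    ``u`` is the combined full-range complex profile (from
    :func:`embed_full_range`, or built directly for single-channel tests).
    Noise is *not* added here; see :func:`add_noise`.
    """
    config = config or ForwardConfig()
    u = np.asarray(u, dtype=complex)
    phase = np.asarray(phase, dtype=float)
    if u.shape != phase.shape:
        raise ValueError("u and phase must have equal length")
    fu = np.fft.fft(u)
    f = 2.0 * config.reference_amplitude * np.real(np.exp(1j * phase) * fu)
    if config.include_autocorrelation:
        n = u.size
        f = f + np.abs(fu) ** 2 / n + 2.0 * config.reference_amplitude**2
    return Interferogram(f, meta={"n": u.size, "r": config.reference_amplitude})


def add_noise(
    f: Interferogram,
    config: ForwardConfig,
    rng: np.random.Generator | None = None,
) -> Interferogram:
    """Add seed-reproducible detection noise.

    Additive zero-mean Gaussian of std ``noise_sigma`` counts; optionally a
    shot-noise term with variance equal to the offset-shifted counts
    (Gaussian approximation of Poisson statistics).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = f.counts.copy()
    if config.shot_noise:
        var = np.clip(counts + config.shot_floor, 0.0, None)
        counts = counts + rng.normal(0.0, 1.0, counts.size) * np.sqrt(var)
    if config.noise_sigma > 0:
        counts = counts + rng.normal(0.0, config.noise_sigma, counts.size)
    meta = dict(f.meta)
    meta["noise_sigma"] = config.noise_sigma
    return Interferogram(counts, meta=meta)


def simulate_bscan(
    scene: Scene,
    d: int,
    n: int,
    phase: np.ndarray,
    config: ForwardConfig | None = None,
) -> list[Interferogram]:
    """One interferogram per lateral position of the scene, in order.

    Noise (if configured) uses independent per-A-line streams spawned from
    ``config.seed`` so the whole B-scan is reproducible from one seed.
    """
    config = config or ForwardConfig()
    noisy = config.noise_sigma > 0 or config.shot_noise
    child_rngs: Sequence[np.random.Generator | None]
    if noisy:
        ss = np.random.SeedSequence(config.seed)
        child_rngs = [np.random.default_rng(s) for s in ss.spawn(scene.n_lateral)]
    else:
        child_rngs = [None] * scene.n_lateral
    frames = []
    for i in range(scene.n_lateral):
        u = embed_full_range(scene.s1[i], scene.s2[i], d, n)
        f = synthesize(u, phase, config)
        if noisy:
            f = add_noise(f, config, rng=child_rngs[i])
        f.meta.update({"lateral_index": i, "mode": scene.mode})
        frames.append(f)
    return frames
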