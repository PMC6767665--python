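"""Random spectral undersampling (the sampling matrix T) and its adjoint.

Compressive reconstruction works from a random subset of the spectrometer
pixels.  ``T`` keeps M of the N pixels (sampling rate M/N); its adjoint is
zero filling — placing the kept values back at their pixel positions with
zeros elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .forward import as_spectrum


@dataclass(frozen=True)
class SamplingMask:
    """Sorted unique pixel indices retained out of N spectrometer pixels."""

    indices: np.ndarray
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size < 1 or idx.size > self.n:
            raise ValueError("mask needs 1 <= M <= N indices")
        if np.any(idx < 0) or np.any(idx >= self.n):
            raise ValueError("mask indices outside [0, N)")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("mask indices must be strictly increasing")

    @property
    def m(self) -> int:
        return self.indices.size

    @property
    def rate(self) -> float:
        return self.indices.size / self.n

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": int(self.n),
                "rate": self.rate,
                "seed": self.seed,
                "indices": [int(i) for i in self.indices],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SamplingMask":
        d = json.loads(text)
        return cls(indices=np.asarray(d["indices"], dtype=np.intp), n=int(d["n"]), seed=d.get("seed"))


def make_mask(n: int, rate: float, seed: int | None = None) -> SamplingMask:
    """Draw M = round(rate*N) pixel indices uniformly without replacement."""
    if not 0.0 < rate <= 1.0:
        raise ValueError("sampling rate must lie in (0, 1]")
    m = max(1, int(round(rate * n)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    return SamplingMask(indices=idx, n=n, seed=seed)


def apply_mask(f, mask: SamplingMask) -> np.ndarray:
    """Undersample: f_u[t] = f[index_t] (length M)."""
    x = as_spectrum(f)
    if x.size != mask.n:
        raise ValueError("mask length does not match spectrum")
    return x[mask.indices]


def zero_fill(f_u: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Adjoint of :func:`apply_mask`: kept values at their pixels, 0 elsewhere."""
    f_u = np.asarray(f_u, dtype=float)
    if f_u.size != mask.m:
        raise ValueError("undersampled vector length does not match mask")
    out = np.zeros(mask.n, dtype=float)
    out[mask.indices] = f_u
    return out
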