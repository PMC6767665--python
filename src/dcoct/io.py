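"""File I/O: two-column text spectra, HDF5 containers, images, tables.

Formats
-------
- Single spectra: two-column delimited text (wavelength_nm, counts) with
  ``# key = value`` header lines carrying grid metadata.
- Frame stacks / B-scans / reconstruction results: one HDF5 container with
  datasets plus attributes echoing the acquisition metadata (complex arrays
  stored as real/imag pairs).
- Sampling masks: JSON (see :meth:`dcoct.sampling.SamplingMask.to_json`).
- Images: 8-bit PNG (log-compressed) and 16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
from PIL import Image

from .forward import Interferogram
from .imaging import BScan, to_db_image
from .optics import GridDialect, SpectralGrid
from .recon import ReconResult
from .sampling import SamplingMask


def write_spectrum_txt(path, wavelength_nm, counts, meta: dict | None = None) -> None:
    """Write a (wavelength_nm, counts) spectrum as two-column text."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if wavelength_nm.shape != counts.shape:
        raise ValueError("wavelength and counts must have equal length")
    lines = []
    for k, v in (meta or {}).items():
        lines.append(f"# {k} = {v}")
    for wl, c in zip(wavelength_nm, counts):
        lines.append(f"{wl:.9f}\t{c:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_txt(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column text spectrum; returns (wavelength_nm, counts, meta)."""
    meta: dict = {}
    wl, counts = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        a, b = line.split()
        wl.append(float(a))
        counts.append(float(b))
    return np.asarray(wl), np.asarray(counts), meta


def grid_from_meta(wavelength_nm: np.ndarray, meta: dict) -> SpectralGrid:
    dialect = GridDialect(meta.get("dialect", GridDialect.WAVELENGTH.value))
    return SpectralGrid(wavelength_nm=wavelength_nm, dialect=dialect)


def save_interferograms_h5(path, frames: list[Interferogram], attrs: dict | None = None) -> None:
    """Write a (frames x pixels) interferogram stack to an HDF5 container."""
    stack = np.stack([f.counts for f in frames])
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("spectra", data=stack)
        for k, v in (attrs or {}).items():
            if v is not None:
                ds.attrs[k] = v


def load_interferograms_h5(path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as h5:
        ds = h5["spectra"]
        return ds[()], dict(ds.attrs)


def save_bscan_h5(path, bscan: BScan) -> None:
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("bscan", data=bscan.image)
        ds.attrs["axial_pitch_mm"] = bscan.axial_pitch_mm
        ds.attrs["lateral_pitch_mm"] = bscan.lateral_pitch_mm
        ds.attrs["scale"] = bscan.scale
        if bscan.mode is not None:
            ds.attrs["mode"] = bscan.mode
        if bscan.channel is not None:
            ds.attrs["channel"] = bscan.channel


def load_bscan_h5(path) -> BScan:
    with h5py.File(path, "r") as h5:
        ds = h5["bscan"]
        a = dict(ds.attrs)
        return BScan(
            ds[()],
            axial_pitch_mm=float(a.get("axial_pitch_mm", 1.0)),
            lateral_pitch_mm=float(a.get("lateral_pitch_mm", 1.0)),
            scale=str(a.get("scale", "linear")),
            mode=int(a["mode"]) if "mode" in a else None,
            channel=int(a["channel"]) if "channel" in a else None,
        )


def save_recon_h5(path, result: ReconResult) -> None:
    """Serialise a reconstruction result (complex data as real/imag pairs)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("u_hat_real", data=result.u_hat.real)
        h5.create_dataset("u_hat_imag", data=result.u_hat.imag)
        h5.create_dataset("residual", data=result.residual)
        h5.create_dataset("residual_energy", data=np.asarray(result.residual_energy))
        comp = np.asarray(
            [(c.bin, c.amplitude.real, c.amplitude.imag, c.iteration) for c in result.components]
        )
        h5.create_dataset("components", data=comp.reshape(-1, 4))
        h5.attrs["mask_json"] = result.mask.to_json()
        h5.attrs["empty"] = result.empty


def write_component_table(path, result: ReconResult, bin_size_m: float | None = None) -> None:
    """Delimited-text component table (bin, depth_mm, |amp|, phase_rad)."""
    lines = ["bin\tdepth_mm\tmagnitude\tphase_rad"]
    n = result.mask.n
    for c in sorted(result.components, key=lambda c: c.bin):
        # signed depth: upper-half indices are negative depths
        signed = c.bin if c.bin <= n // 2 else c.bin - n
        depth_mm = signed * bin_size_m * 1e3 if bin_size_m else float("nan")
        lines.append(
            f"{c.bin}\t{depth_mm:.6f}\t{abs(c.amplitude):.6g}\t{np.angle(c.amplitude):.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def save_bscan_png(path, bscan: BScan, floor_db: float = -40.0) -> None:
    Image.fromarray(to_db_image(bscan, floor_db)).save(path)


def save_bscan_tiff(path, bscan: BScan) -> None:
    img = bscan.image
    peak = img.max()
    scaled = (img / peak * 65535.0).astype(np.uint16) if peak > 0 else np.zeros_like(img, dtype=np.uint16)
    tifffile.imwrite(path, scaled)


def write_mask_json(path, mask: SamplingMask) -> None:
    Path(path).write_text(mask.to_json() + "\n")


def read_mask_json(path) -> SamplingMask:
    return SamplingMask.from_json(Path(path).read_text())


def write_provenance(path, config: dict, seed, version: str) -> None:
    """Config + seed echo sufficient to replay a deterministic run."""
    Path(path).write_text(
        json.dumps({"config": config, "seed": seed, "version": version}, indent=2, default=str)
        + "\n"
    )
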