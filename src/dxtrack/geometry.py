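"""Detector geometry: pixel ↔ angular coordinate mapping and ring gating.

In diffracted X-ray tracking (DXT) a nanocrystal attached to the protein of
interest emits a Laue diffraction spot onto a 2-D photon-counting detector.
Crystal *twist* about the beam axis (χ) moves the spot azimuthally along its
Debye–Scherrer ring; crystal *tilt* (θ) changes the Bragg angle and moves the
spot radially.  This module converts sub-pixel detector positions into the
(χ, θ) angular coordinates used throughout the package, and gates spots to the
radial band a named reflection can occupy given the white beam's energy
bandwidth.

Conventions
-----------
* χ is the azimuth of the spot about the beam centre, counter-clockwise,
  zero along the +x detector axis.
* θ is *half* the change in scattering angle: tilting the lattice plane by δ
  moves the reflected beam by 2δ, so θ = ½·arctan(r·pitch / L).
* Both angles are expressed in milliradians (mrad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

#: hc in keV·Å — converts photon energy to wavelength, λ[Å] = HC_KEV_A / E[keV]
HC_KEV_A = 12.398419

#: ZnO (wurtzite) lattice constants in Å; d-spacings of the default
#: reflections follow from 1/d² = 4/3·(h²+hk+k²)/a² + l²/c²:
#:   d(110) = a/2            = 1.62475 Å
#:   d(103) = 1/√(4/(3a²)+9/c²) = 1.47726 Å
ZNO_A = 3.2495
ZNO_C = 5.2069


def zno_d_spacing(h: int, k: int, l: int) -> float:
    """d-spacing of a ZnO (wurtzite, hexagonal) reflection in Å."""
    inv_d2 = 4.0 / 3.0 * (h * h + h * k + k * k) / ZNO_A**2 + l * l / ZNO_C**2
    return 1.0 / math.sqrt(inv_d2)


DEFAULT_REFLECTIONS = {
    "ZnO_110": zno_d_spacing(1, 1, 0),
    "ZnO_103": zno_d_spacing(1, 0, 3),
}


@dataclass
class AngularPosition:
    """A spot position expressed as twist/tilt angles, both in mrad.

    ``chi`` is only defined modulo the full circle (2π·1000 mrad);
    displacement computations unwrap it to the branch nearest the previous
    sample (see :mod:`dxtrack.trajectory`).
    """

    chi: float
    theta: float


@dataclass
class DetectorGeometry:
    """Flat-detector geometry for angle conversion and ring gating.

    Parameters
    ----------
    beam_center_x, beam_center_y : float
        Beam centre on the detector, pixels.
    camera_length : float
        Sample-to-detector distance, mm.
    pixel_pitch : float
        Pixel size, mm (default 0.172 mm — PILATUS).
    energy_band : tuple of float
        (E_min, E_max) of the white beam, keV.  Placeholder default 10–20 keV;
        the band is fully configurable because the experiment only specifies a
        "white" beam.
    reflections : dict
        Reflection label → d-spacing in Å.
    """

    beam_center_x: float
    beam_center_y: float
    camera_length: float
    pixel_pitch: float = 0.172
    energy_band: tuple[float, float] = (10.0, 20.0)
    reflections: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIONS)
    )

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.camera_length <= 0:
            raise ValueError("camera_length must be positive")
        e_min, e_max = self.energy_band
        if not e_min < e_max:
            raise ValueError("energy_band must satisfy E_min < E_max")
        for label, d in self.reflections.items():
            if d <= 0:
                raise ValueError(f"d-spacing of {label!r} must be positive")

    # -- angle conversion ---------------------------------------------------

    def pixel_to_angles(self, x, y) -> AngularPosition:
        """Convert detector position(s) to (χ, θ) in mrad.

        Rejects observations at the exact beam centre, where the azimuth is
        undefined.  Accepts scalars or arrays (broadcast together).
        """
        dx = np.asarray(x, dtype=float) - self.beam_center_x
        dy = np.asarray(y, dtype=float) - self.beam_center_y
        r = np.hypot(dx, dy)
        if np.any(r == 0):
            raise ValueError("spot at the exact beam center: azimuth undefined")
        chi = np.arctan2(dy, dx) * 1e3
        theta = 0.5 * np.arctan(r * self.pixel_pitch / self.camera_length) * 1e3
        if chi.ndim == 0:
            return AngularPosition(float(chi), float(theta))
        return AngularPosition(chi, theta)

    def angles_to_pixel(self, chi, theta):
        """Inverse of :meth:`pixel_to_angles`; returns (x, y) in pixels."""
        chi_rad = np.asarray(chi, dtype=float) * 1e-3
        theta_rad = np.asarray(theta, dtype=float) * 1e-3
        r = self.camera_length * np.tan(2.0 * theta_rad) / self.pixel_pitch
        x = self.beam_center_x + r * np.cos(chi_rad)
        y = self.beam_center_y + r * np.sin(chi_rad)
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    # -- ring gating ----------------------------------------------------------

    def ring_radius(self, reflection: str, energy_kev: float) -> float:
        """Radius (pixels) of a reflection's Debye–Scherrer ring at one energy.

        Bragg's law λ = 2d·sinθ_B with λ = hc/E gives the Bragg angle; the
        reflected beam leaves at 2θ_B, so r = L·tan(2θ_B)/pitch.
        """
        d = self._d_spacing(reflection)
        s = HC_KEV_A / (2.0 * d * energy_kev)
        if s >= 1.0:
            raise ValueError(
                f"energy {energy_kev} keV below the Bragg cutoff for "
                f"{reflection!r} (d = {d:.4f} Å)"
            )
        theta_b = math.asin(s)
        return self.camera_length * math.tan(2.0 * theta_b) / self.pixel_pitch

    def ring_band(self, reflection: str) -> tuple[float, float]:
        """Radial band [r_min, r_max] (pixels) a reflection occupies.

        Higher energy → shorter wavelength → smaller Bragg angle, so the band
        runs from r(E_max) to r(E_min).
        """
        e_min, e_max = self.energy_band
        return (self.ring_radius(reflection, e_max),
                self.ring_radius(reflection, e_min))

    def ring_gate(self, x, y, reflection: str):
        """True where (x, y) lies in the reflection's radial band."""
        lo, hi = self.ring_band(reflection)
        dx = np.asarray(x, dtype=float) - self.beam_center_x
        dy = np.asarray(y, dtype=float) - self.beam_center_y
        r = np.hypot(dx, dy)
        accepted = (r >= lo) & (r <= hi)
        if accepted.ndim == 0:
            return bool(accepted)
        return accepted

    def _d_spacing(self, reflection: str) -> float:
        try:
            return self.reflections[reflection]
        except KeyError:
            raise KeyError(
                f"unknown reflection {reflection!r}; available: "
                f"{sorted(self.reflections)}"
            ) from None


_GEOMETRY_KEYS = {
    "beam_center_x", "beam_center_y", "camera_length", "pixel_pitch",
    "energy_band", "reflections",
}


def geometry_from_dict(cfg: dict) -> DetectorGeometry:
    """Build a :class:`DetectorGeometry` from a config mapping.

    Unknown keys are an error: geometry files are short, and a typo that is
    silently ignored produces silently wrong angles.
    """
    unknown = set(cfg) - _GEOMETRY_KEYS
    if unknown:
        raise ValueError(
            f"unknown geometry keys: {sorted(unknown)}; "
            f"allowed: {sorted(_GEOMETRY_KEYS)}"
        )
    cfg = dict(cfg)
    if "energy_band" in cfg:
        cfg["energy_band"] = tuple(float(e) for e in cfg["energy_band"])
    if "reflections" in cfg:
        cfg["reflections"] = {k: float(v) for k, v in cfg["reflections"].items()}
    return DetectorGeometry(**cfg)


def load_geometry(path) -> DetectorGeometry:
    """Read geometry from a YAML config file (see geometry_from_dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: geometry config must be a mapping")
    return geometry_from_dict(cfg)
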