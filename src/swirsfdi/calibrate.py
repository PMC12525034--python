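"""Phantom-based calibration of demodulated images to diffuse reflectance.

A reference phantom with known optical properties is imaged under the same
conditions as the sample. The Monte Carlo lookup table predicts the
phantom's diffuse reflectance, and the per-pixel ratio

    R_sample = R_phantom * M_sample / M_phantom

converts demodulated pixel values to calibrated reflectance while
flat-field-correcting illumination nonuniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demodulate import DemodulatedImage
from .lut import ReflectanceLUT

R_VALID_CEILING = 1.2  # headroom above 1 for noise before a pixel is masked
DEFAULT_NOISE_FLOOR_FRACTION = 0.01  # of the phantom's median signal


@dataclass
class ReflectanceImage:
    """Calibrated diffuse reflectance with a per-pixel validity mask."""

    wavelength: float
    fx: float
    R: np.ndarray
    valid_mask: np.ndarray


@dataclass
class CalibrationPhantomSpec:
    """Known optical properties of the calibration phantom.

    ``properties`` maps wavelength (nm) to (mu_a, mu_s_prime) in mm^-1.
    """

    properties: dict
    label: str = "calibration-phantom"

    def optical_properties(self, wavelength: float) -> tuple:
        for wl, props in self.properties.items():
            if np.isclose(float(wl), wavelength):
                return float(props[0]), float(props[1])
        raise KeyError(
            f"phantom {self.label!r} has no properties at {wavelength} nm"
        )


def predict_phantom_reflectance(
    phantom: CalibrationPhantomSpec,
    lut: ReflectanceLUT,
    wavelength: float,
    fx: float,
) -> float:
    """LUT-predicted diffuse reflectance of the phantom at one condition.

    Bilinear interpolation in the table's axis (log) coordinates; phantom
    properties outside the grid are rejected with the offending axis named.
    """
    mu_a, mu_s_prime = phantom.optical_properties(wavelength)
    return float(lut.forward(mu_a, mu_s_prime, fx))


def calibrate_reflectance(
    M_sample: DemodulatedImage,
    M_phantom: DemodulatedImage,
    R_phantom_predicted: float,
    noise_floor_fraction: float = DEFAULT_NOISE_FLOOR_FRACTION,
) -> ReflectanceImage:
    """Convert sample demodulated values to diffuse reflectance.

    Pixels where the phantom signal is at or below the noise floor
    (``noise_floor_fraction`` of its median) are masked invalid rather than
    divided through; calibrated values above ``R_VALID_CEILING`` are also
    masked, never clipped.
    """
    if not np.isclose(M_sample.wavelength, M_phantom.wavelength):
        raise ValueError(
            f"wavelength mismatch: sample {M_sample.wavelength} nm vs "
            f"phantom {M_phantom.wavelength} nm"
        )
    if not np.isclose(M_sample.fx, M_phantom.fx):
        raise ValueError(
            f"fx mismatch: sample {M_sample.fx} vs phantom {M_phantom.fx} mm^-1"
        )
    if M_sample.M.shape != M_phantom.M.shape:
        raise ValueError("sample and phantom shapes differ")
    if not (0.0 < R_phantom_predicted < 1.0):
        raise ValueError("R_phantom_predicted must lie in (0, 1)")

    floor = noise_floor_fraction * np.median(M_phantom.M)
    denominator_ok = M_phantom.M > floor
    R = np.zeros_like(M_sample.M, dtype=float)
    np.divide(
        R_phantom_predicted * M_sample.M,
        M_phantom.M,
        out=R,
        where=denominator_ok,
    )
    valid = denominator_ok & (R <= R_VALID_CEILING) & np.isfinite(R)
    return ReflectanceImage(M_sample.wavelength, M_sample.fx, R, valid)
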