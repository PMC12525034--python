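"""Demodulation of raw phase-shifted SFDI image stacks.

Planar (DC) illumination uses a light-on / light-off pair:

    I_DC = I_ON - I_OFF

Structured (AC) illumination uses four frames with projected phases
0, 90, 180 and 270 degrees:

    I_AC = 1/2 * sqrt((I_phi2 - I_phi4)^2 + (I_phi1 - I_phi3)^2)

which recovers the envelope amplitude of the reflected sinusoid exactly for
ideal frames and is invariant to a common global phase offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DC_FRAME_KEYS = ("on", "off")
AC_FRAME_KEYS = ("phase_0", "phase_90", "phase_180", "phase_270")


@dataclass
class PhaseImageSet:
    """Raw frames for one {wavelength, spatial frequency} condition.

    ``frames`` maps role names to 2D nonnegative intensity arrays:
    DC mode requires ``on``/``off``; AC mode requires ``phase_0``,
    ``phase_90``, ``phase_180``, ``phase_270``.
    """

    wavelength: float
    fx: float
    pixel_pitch: float
    mode: str
    frames: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("dc", "ac"):
            raise ValueError(f"mode must be 'dc' or 'ac', got {self.mode!r}")
        if (self.fx == 0.0) != (self.mode == "dc"):
            raise ValueError("fx must be 0 exactly for DC mode and nonzero for AC")
        keys = DC_FRAME_KEYS if self.mode == "dc" else AC_FRAME_KEYS
        missing = [k for k in keys if k not in self.frames]
        if missing:
            raise ValueError(f"{self.mode.upper()} mode missing frames: {missing}")
        shapes = {np.asarray(self.frames[k]).shape for k in keys}
        if len(shapes) != 1:
            raise ValueError(f"frames have mismatched shapes: {shapes}")
        for k in keys:
            arr = np.asarray(self.frames[k], dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"frame {k!r} contains negative intensities")
            self.frames[k] = arr

    @property
    def shape(self) -> tuple:
        key = DC_FRAME_KEYS[0] if self.mode == "dc" else AC_FRAME_KEYS[0]
        return self.frames[key].shape


@dataclass
class DemodulatedImage:
    """Demodulated pixel values M for one {wavelength, fx} condition."""

    wavelength: float
    fx: float
    M: np.ndarray
    n_clamped: int = 0


def demodulate_dc(images: PhaseImageSet) -> DemodulatedImage:
    """I_DC = I_ON - I_OFF; negative pixels (sensor noise) clamp to 0.

    The clamped-pixel count is recorded on the result and logged.
    """
    if images.mode != "dc":
        raise ValueError("demodulate_dc requires a DC-mode PhaseImageSet")
    M = images.frames["on"] - images.frames["off"]
    negative = M < 0
    n_clamped = int(negative.sum())
    if n_clamped:
        logger.warning(
            "demodulate_dc: clamped %d negative pixels at %g nm", n_clamped,
            images.wavelength,
        )
        M = np.where(negative, 0.0, M)
    return DemodulatedImage(images.wavelength, images.fx, M, n_clamped)


def demodulate_ac(images: PhaseImageSet) -> DemodulatedImage:
    """Four-phase quadrature demodulation of the sinusoidal envelope."""
    if images.mode != "ac":
        raise ValueError("demodulate_ac requires an AC-mode PhaseImageSet")
    f = images.frames
    M = 0.5 * np.sqrt(
        (f["phase_90"] - f["phase_270"]) ** 2 + (f["phase_0"] - f["phase_180"]) ** 2
    )
    return DemodulatedImage(images.wavelength, images.fx, M)
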