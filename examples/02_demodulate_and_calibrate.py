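"""Demodulate raw phase-shifted frames and calibrate to reflectance.

Renders a homogeneous sample and a 10% Intralipid calibration phantom
under nonuniform illumination, then shows that the four-phase quadrature
demodulation plus the per-pixel phantom ratio recovers a flat, quantitative
diffuse reflectance image (the illumination pattern cancels).
"""

import numpy as np

from swirsfdi import (
    AcquisitionModel,
    calibrate_reflectance,
    demodulate_ac,
    demodulate_dc,
    intralipid_phantom_spec,
    make_dilution_series,
    predict_phantom_reflectance,
    render_raw,
)

from _common import example_lut

lut = example_lut()
phantom = intralipid_phantom_spec([970.0])
(scene,) = make_dilution_series([0.10], shape=(16, 16))

illum = np.tile(np.linspace(0.8, 1.2, 16), (16, 1))  # 40% ramp across the field
model = AcquisitionModel(illumination_profile=illum, read_sigma=5.0, seed=1)
raw = render_raw(scene, model, lut, [970.0], (0.0, 0.1), phantom, seed=1)

for fx, dm in ((0.0, demodulate_dc), (0.1, demodulate_ac)):
    m_sample = dm(raw["sample"][(970.0, fx)])
    m_phantom = dm(raw["phantom"][(970.0, fx)])
    r_pred = predict_phantom_reflectance(phantom, lut, 970.0, fx)
    refl = calibrate_reflectance(m_sample, m_phantom, r_pred)
    vals = refl.R[refl.valid_mask]
    print(
        f"fx={fx:>4} mm^-1: raw demod ramp {m_sample.M.min():7.0f}..."
        f"{m_sample.M.max():7.0f} counts -> calibrated R = "
        f"{vals.mean():.4f} +- {vals.std():.4f}"
    )
print(
    "\nThe raw demodulated counts vary ~40% with the illumination ramp;"
    "\nthe calibrated reflectance is flat to camera-noise level because the"
    "\nphantom ratio removes gain and illumination pixel by pixel."
)
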