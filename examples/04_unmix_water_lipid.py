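"""Full chain on an emulated Intralipid dilution series.

Renders raw frames for four water/lipid mixtures (95/5 to 80/20), runs
demodulation, calibration, inversion and unmixing, and prints the
recovered water and lipid contents against ground truth.
"""

import numpy as np

from swirsfdi import (
    AcquisitionModel,
    intralipid_phantom_spec,
    make_dilution_series,
    process_stacks,
    render_raw,
    to_percent,
)

from _common import example_lut

WAVELENGTHS = [970.0, 1050.0, 1200.0]

lut = example_lut()
phantom = intralipid_phantom_spec(WAVELENGTHS)
model = AcquisitionModel(seed=4)  # default camera noise

print(f"{'lipid truth':>12} {'water truth':>12} {'water est':>10} {'lipid est':>10}")
for k, frac in enumerate((0.05, 0.10, 0.15, 0.20)):
    (scene,) = make_dilution_series([frac], shape=(24, 24))
    raw = render_raw(
        scene, model, lut, WAVELENGTHS, (0.0, 0.1), phantom, seed=10 + k
    )
    _, chromo = process_stacks(
        raw["sample"], raw["phantom"], phantom, lut, residual_tol=0.05
    )
    water_pct, lipid_pct = to_percent(chromo)
    print(
        f"{100 * frac:11.0f}% {100 * (1 - frac):11.0f}% "
        f"{np.nanmean(water_pct):9.2f}% {np.nanmean(lipid_pct):9.2f}%"
    )
print(
    "\nWater is recovered to within a couple of percentage points under"
    "\nrealistic camera noise; the three SWIR wavelengths separate the"
    "\nwater and lipid absorption signatures."
)
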