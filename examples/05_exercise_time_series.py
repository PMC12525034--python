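"""Emulated pre/post-exercise hand imaging with an in-frame phantom.

A skin-like scene loses dermal water abruptly at the exercise boundary
(with coupled reduced scattering) and recovers exponentially; a static
reference phantom shares the frame. The percent-change trend table
separates the physiological change from instrument noise.
"""

import numpy as np

from swirsfdi import (
    AcquisitionModel,
    TimeSeriesSpec,
    intralipid_phantom_spec,
    make_exercise_series,
    make_skin_scene,
    process_stacks,
    render_raw,
    roi_stats,
)

from _common import example_lut

WAVELENGTHS = [970.0, 1050.0, 1200.0]
N_BASELINE, N_POST = 5, 10

lut = example_lut()
phantom = intralipid_phantom_spec(WAVELENGTHS)
base = make_skin_scene(
    shape=(24, 24), phantom_region=(0, 8, 0, 8), heterogeneity=0.03, seed=5
)
spec = TimeSeriesSpec(
    n_timepoints=N_BASELINE + N_POST,
    n_baseline=N_BASELINE,
    phantom_region="phantom",
    exercise_drop=0.05,  # 5% relative dermal water loss at the boundary
    coupling_k=2.0,  # each 1% water loss lowers mu_s' by 2%
    recovery_tau=8.0,  # minutes
)
scenes = make_exercise_series(spec, base)
model = AcquisitionModel(seed=6)

skin_roi, phantom_roi = (8, 24, 8, 24), (0, 8, 0, 8)
skin, ph = [], []
for t, scene in enumerate(scenes):
    raw = render_raw(
        scene, model, lut, WAVELENGTHS, (0.0, 0.1), phantom, seed=100 + t
    )
    maps, _ = process_stacks(
        raw["sample"], raw["phantom"], phantom, lut, residual_tol=0.05
    )
    m = maps[1200.0]
    skin.append(roi_stats(m.mu_s_prime, skin_roi, m.valid_mask).mean)
    ph.append(roi_stats(m.mu_s_prime, phantom_roi, m.valid_mask).mean)

skin, ph = np.asarray(skin), np.asarray(ph)
base_skin, base_ph = skin[:N_BASELINE].mean(), ph[:N_BASELINE].mean()
print("minute  skin mu_s' %change   phantom mu_s' %change   (1200 nm)")
for t in range(len(scenes)):
    marker = "  <- exercise" if t == N_BASELINE else ""
    print(
        f"{t:6d} {100 * (skin[t] - base_skin) / base_skin:15.2f} "
        f"{100 * (ph[t] - base_ph) / base_ph:21.2f}{marker}"
    )
print(
    "\nSkin reduced scattering drops ~10% right after exercise and climbs"
    "\nback toward baseline, while the in-frame phantom stays flat at the"
    "\nnoise level - the change is physiological, not instrumental."
)
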