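"""Disk formats: raw TIFF stacks with a YAML manifest, and HDF5 outputs.

Raw frames are 16-bit grayscale TIFFs named
``{role}_{wavelength}nm_fx{fx}_{tag}.tif`` (tags: ``on``/``off`` for DC,
``phase_0``/``phase_90``/``phase_180``/``phase_270`` for AC); a YAML
manifest records the acquisition geometry, the calibration phantom's known
optical properties, and the frame files per timepoint. Where filename and
manifest disagree, the manifest wins.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

from .calibrate import CalibrationPhantomSpec
from .demodulate import AC_FRAME_KEYS, DC_FRAME_KEYS, PhaseImageSet

MANIFEST_NAME = "run.yaml"


@dataclass
class RunData:
    """In-memory contents of a raw acquisition directory."""

    pixel_pitch: float
    wavelengths: list
    fx_list: list
    phantom_spec: CalibrationPhantomSpec
    phantom_stacks: dict  # (wavelength, fx) -> PhaseImageSet
    timepoint_stacks: list  # list of dicts like phantom_stacks
    timepoint_ids: list = field(default_factory=list)


def _frame_filename(role: str, wavelength: float, fx: float, tag: str) -> str:
    return f"{role}_{wavelength:g}nm_fx{fx:g}_{tag}.tif"


def _write_stack(dirpath, role, stack: PhaseImageSet) -> dict:
    entry = {}
    keys = DC_FRAME_KEYS if stack.mode == "dc" else AC_FRAME_KEYS
    for tag in keys:
        fname = _frame_filename(role, stack.wavelength, stack.fx, tag)
        tifffile.imwrite(
            dirpath / fname, np.asarray(stack.frames[tag], dtype=np.uint16)
        )
        entry[tag] = fname
    return entry


def write_run(
    dirpath,
    timepoint_stacks,
    phantom_stacks,
    phantom_spec: CalibrationPhantomSpec,
    pixel_pitch: float,
) -> pathlib.Path:
    """Write raw TIFF frames plus the YAML manifest; returns manifest path.

    ``timepoint_stacks`` is a list (one per timepoint) of dicts mapping
    (wavelength, fx) to PhaseImageSet; ``phantom_stacks`` one such dict.
    """
    dirpath = pathlib.Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    wavelengths = sorted({wl for wl, _ in phantom_stacks})
    fx_list = sorted({fx for _, fx in phantom_stacks})

    manifest = {
        "pixel_pitch_mm": float(pixel_pitch),
        "wavelengths_nm": [float(w) for w in wavelengths],
        "fx_mm": [float(f) for f in fx_list],
        "phantom": {
            "label": phantom_spec.label,
            "properties": {
                str(wl): [float(v) for v in phantom_spec.optical_properties(wl)]
                for wl in wavelengths
            },
            "frames": {},
        },
        "timepoints": [],
    }
    for (wl, fx), stack in phantom_stacks.items():
        manifest["phantom"]["frames"].setdefault(str(wl), {})[str(fx)] = _write_stack(
            dirpath, "phantom", stack
        )
    for t, stacks in enumerate(timepoint_stacks):
        tid = f"t{t:03d}"
        frames = {}
        for (wl, fx), stack in stacks.items():
            frames.setdefault(str(wl), {})[str(fx)] = _write_stack(
                dirpath, f"sample-{tid}", stack
            )
        manifest["timepoints"].append({"id": tid, "frames": frames})

    path = dirpath / MANIFEST_NAME
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def _read_stack(dirpath, wl, fx, entry, pixel_pitch) -> PhaseImageSet:
    mode = "dc" if float(fx) == 0.0 else "ac"
    frames = {
        tag: tifffile.imread(dirpath / fname).astype(float)
        for tag, fname in entry.items()
    }
    return PhaseImageSet(
        wavelength=float(wl),
        fx=float(fx),
        pixel_pitch=pixel_pitch,
        mode=mode,
        frames=frames,
    )


def read_run(manifest_path) -> RunData:
    """Load a raw acquisition directory from its YAML manifest."""
    manifest_path = pathlib.Path(manifest_path)
    dirpath = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    pixel_pitch = float(manifest["pixel_pitch_mm"])
    phantom_props = {
        float(wl): tuple(v)
        for wl, v in manifest["phantom"]["properties"].items()
    }
    phantom_spec = CalibrationPhantomSpec(
        properties=phantom_props, label=manifest["phantom"].get("label", "phantom")
    )
    phantom_stacks = {}
    for wl, by_fx in manifest["phantom"]["frames"].items():
        for fx, entry in by_fx.items():
            phantom_stacks[(float(wl), float(fx))] = _read_stack(
                dirpath, wl, fx, entry, pixel_pitch
            )
    timepoint_stacks, timepoint_ids = [], []
    for tp in manifest["timepoints"]:
        stacks = {}
        for wl, by_fx in tp["frames"].items():
            for fx, entry in by_fx.items():
                stacks[(float(wl), float(fx))] = _read_stack(
                    dirpath, wl, fx, entry, pixel_pitch
                )
        timepoint_stacks.append(stacks)
        timepoint_ids.append(tp.get("id", f"t{len(timepoint_ids):03d}"))
    return RunData(
        pixel_pitch=pixel_pitch,
        wavelengths=[float(w) for w in manifest["wavelengths_nm"]],
        fx_list=[float(f) for f in manifest["fx_mm"]],
        phantom_spec=phantom_spec,
        phantom_stacks=phantom_stacks,
        timepoint_stacks=timepoint_stacks,
        timepoint_ids=timepoint_ids,
    )


# ---------------------------------------------------------------------------
# HDF5 result files


def save_property_maps(path, maps_per_timepoint, attrs=None) -> None:
    """Write optical-property maps: /{tid}/wl_{wavelength}/{mu_a,mu_s_prime,...}."""
    import h5py

    with h5py.File(path, "w") as f:
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for tid, maps in maps_per_timepoint.items():
            for wl, m in maps.items():
                grp = f.create_group(f"{tid}/wl_{wl:g}")
                grp.create_dataset("mu_a", data=m.mu_a)
                grp.create_dataset("mu_s_prime", data=m.mu_s_prime)
                grp.create_dataset("valid_mask", data=m.valid_mask)
                grp.create_dataset("reason", data=m.reason)
                grp.create_dataset("residual", data=m.residual)


def save_chromophore_maps(path, cmaps_per_timepoint, attrs=None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for tid, cm in cmaps_per_timepoint.items():
            grp = f.create_group(str(tid))
            grp.create_dataset("C_water", data=cm.C_water)
            grp.create_dataset("C_lipid", data=cm.C_lipid)
            grp.create_dataset("residual", data=cm.residual)
            grp.create_dataset("valid_mask", data=cm.valid_mask)
            grp.create_dataset("negativity_mask", data=cm.negativity_mask)


def save_demodulated(path, demod_per_timepoint, attrs=None) -> None:
    """Write demodulated images: /{tid}/wl_{w}/fx_{f}/M."""
    import h5py

    with h5py.File(path, "w") as f:
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for tid, by_cond in demod_per_timepoint.items():
            for (wl, fx), dm in by_cond.items():
                grp = f.create_group(f"{tid}/wl_{wl:g}/fx_{fx:g}")
                grp.create_dataset("M", data=dm.M)
                grp.attrs["n_clamped"] = dm.n_clamped
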