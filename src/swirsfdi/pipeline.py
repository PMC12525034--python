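"""End-to-end orchestration, ROI analytics, and percent-change trends.

``run_pipeline`` drives demodulate -> calibrate -> invert -> unmix for
every wavelength and timepoint of a raw acquisition, persisting all
intermediates to HDF5 with a structured log (config hash, LUT hash, seeds,
invalid-pixel fractions). ROI statistics and percent-change-vs-baseline
tables realize the time-series analyses of the desiccation and exercise
experiments.

Conventions: pixel coordinates are 0-based row-major; ROIs are half-open
rectangles (r0, r1, c0, c1).
"""

from __future__ import annotations

import hashlib
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .calibrate import calibrate_reflectance, predict_phantom_reflectance
from .chromophores import ExtinctionTable, unmix
from .demodulate import demodulate_ac, demodulate_dc
from .invert import invert_map
from .io import read_run, save_chromophore_maps, save_demodulated, save_property_maps
from .lut import ReflectanceLUT

logger = logging.getLogger(__name__)

QUANTITIES = ("mu_a", "mu_s_prime", "C_water", "C_lipid")
BASELINE_RULES = ("first", "pre_event_mean")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run.

    ``rois`` maps roi_id to half-open pixel rectangles (r0, r1, c0, c1).
    ``baseline_rule`` selects the percent-change reference: the first
    timepoint, or the mean of the first ``n_baseline`` timepoints.
    """

    manifest: str
    lut: str
    out_dir: str
    extinction: str | None = None  # packaged table when None
    wavelengths: list | None = None  # manifest order when None
    fx_list: list | None = None
    rois: dict = field(default_factory=dict)
    seed: int = 0
    noise_floor_fraction: float = 0.01
    inversion_residual_tol: float = 1e-3
    baseline_rule: str = "first"
    n_baseline: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        for name in ("manifest", "lut"):
            p = getattr(self, name)
            if not pathlib.Path(p).exists():
                raise FileNotFoundError(f"config {name} path does not exist: {p}")
        if self.extinction and not pathlib.Path(self.extinction).exists():
            raise FileNotFoundError(
                f"config extinction path does not exist: {self.extinction}"
            )
        if self.baseline_rule not in BASELINE_RULES:
            raise ValueError(f"baseline_rule must be one of {BASELINE_RULES}")


@dataclass
class ROIStats:
    """Mean/sd over the valid pixels of one ROI."""

    mean: float
    sd: float
    n_valid: int
    n_excluded: int
    flagged: bool = False  # True when the ROI held no valid pixels


@dataclass
class PipelineResult:
    """In-memory products of one end-to-end run."""

    timepoint_ids: list
    property_maps: dict  # tid -> {wavelength: OpticalPropertyMap}
    chromophore_maps: dict  # tid -> ChromophoreMap
    log: dict


def _rect_mask(shape, roi) -> np.ndarray:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"ROI {roi} outside image bounds {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def roi_stats(values, roi, valid_mask=None) -> ROIStats:
    """Mean and sd of ``values`` over a half-open rectangular ROI.

    Only valid pixels contribute; the excluded count is reported. A fully
    invalid ROI returns a flagged result rather than a number.
    """
    values = np.asarray(values, dtype=float)
    sel = _rect_mask(values.shape, roi)
    if valid_mask is not None:
        ok = sel & np.asarray(valid_mask, dtype=bool) & np.isfinite(values)
    else:
        ok = sel & np.isfinite(values)
    n_valid = int(ok.sum())
    n_excluded = int(sel.sum()) - n_valid
    if n_valid == 0:
        return ROIStats(np.nan, np.nan, 0, n_excluded, flagged=True)
    vals = values[ok]
    return ROIStats(float(vals.mean()), float(vals.std()), n_valid, n_excluded)


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(
        {k: getattr(config, k) for k in config.__dataclass_fields__},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _lut_hash(lut: ReflectanceLUT) -> str:
    return hashlib.sha256(lut.R.tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Demodulate, calibrate, invert and unmix every wavelength/timepoint.

    All intermediates are persisted under ``config.out_dir`` (demod.h5,
    props.h5, chromo.h5); any stage failure aborts with a stage-tagged
    error.
    """
    config.validate_paths()
    try:
        run = read_run(config.manifest)
    except Exception as exc:  # noqa: BLE001 - re-tagged for diagnostics
        raise PipelineStageError("load", str(exc)) from exc
    try:
        lut = ReflectanceLUT.load(config.lut)
        table = ExtinctionTable.from_csv(config.extinction)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("load", str(exc)) from exc

    wavelengths = config.wavelengths or run.wavelengths
    fx_list = config.fx_list or run.fx_list
    f_ac = [f for f in fx_list if f != 0.0]
    if 0.0 not in fx_list or len(f_ac) != 1:
        raise PipelineStageError(
            "config", f"need fx_list = [0, f_ac], got {fx_list}"
        )
    f_ac = f_ac[0]

    log = {
        "config_hash": _config_hash(config),
        "lut_hash": _lut_hash(lut),
        "seed": config.seed,
        "invalid_fraction": {},
        "clamped_pixels": {},
    }

    # Phantom demodulation and LUT predictions are shared by all timepoints.
    demod_phantom, r_pred = {}, {}
    for wl in wavelengths:
        for fx in (0.0, f_ac):
            key = (wl, fx)
            if key not in run.phantom_stacks:
                raise PipelineStageError(
                    "calibration", f"missing phantom frames for {wl} nm fx={fx}"
                )
            dm = demodulate_dc if fx == 0.0 else demodulate_ac
            demod_phantom[key] = dm(run.phantom_stacks[key])
            try:
                r_pred[key] = predict_phantom_reflectance(
                    run.phantom_spec, lut, wl, fx
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("calibration", str(exc)) from exc

    demod_all, props_all, chromo_all = {}, {}, {}
    for tid, stacks in zip(run.timepoint_ids, run.timepoint_stacks):
        demod_t, maps_t = {}, {}
        for wl in wavelengths:
            refl = {}
            for fx in (0.0, f_ac):
                key = (wl, fx)
                if key not in stacks:
                    raise PipelineStageError(
                        "demodulation", f"{tid}: missing sample frames {key}"
                    )
                dm = demodulate_dc if fx == 0.0 else demodulate_ac
                demod_t[key] = dm(stacks[key])
                if demod_t[key].n_clamped:
                    log["clamped_pixels"][f"{tid}/{wl}/{fx}"] = demod_t[key].n_clamped
                refl[fx] = calibrate_reflectance(
                    demod_t[key],
                    demod_phantom[key],
                    r_pred[key],
                    noise_floor_fraction=config.noise_floor_fraction,
                )
            try:
                maps_t[wl] = invert_map(
                    refl[0.0],
                    refl[f_ac],
                    lut,
                    residual_tol=config.inversion_residual_tol,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("inversion", str(exc)) from exc
            log["invalid_fraction"][f"{tid}/{wl}"] = float(
                1.0 - maps_t[wl].valid_mask.mean()
            )
        try:
            chromo_all[tid] = unmix(maps_t, table)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("unmixing", str(exc)) from exc
        demod_all[tid] = demod_t
        props_all[tid] = maps_t

    out_dir = pathlib.Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    attrs = {
        "config_hash": log["config_hash"],
        "lut_hash": log["lut_hash"],
        "seed": config.seed,
    }
    save_demodulated(out_dir / "demod.h5", demod_all, attrs)
    save_property_maps(out_dir / "props.h5", props_all, attrs)
    save_chromophore_maps(out_dir / "chromo.h5", chromo_all, attrs)
    logger.info(
        "pipeline complete: %d timepoints, %d wavelengths, config %s, lut %s",
        len(run.timepoint_ids),
        len(wavelengths),
        log["config_hash"],
        log["lut_hash"],
    )
    return PipelineResult(
        timepoint_ids=list(run.timepoint_ids),
        property_maps=props_all,
        chromophore_maps=chromo_all,
        log=log,
    )


def process_stacks(
    sample_stacks: dict,
    phantom_stacks: dict,
    phantom_spec,
    lut: ReflectanceLUT,
    table: ExtinctionTable | None = None,
    noise_floor_fraction: float = 0.01,
    residual_tol: float = 1e-3,
):
    """In-memory single-timepoint pipeline on rendered or loaded stacks.

    ``sample_stacks``/``phantom_stacks`` map (wavelength, fx) to
    PhaseImageSet, as produced by the renderer or the manifest reader.
    Returns (property maps per wavelength, ChromophoreMap).
    """
    table = table or ExtinctionTable.from_csv()
    wavelengths = sorted({wl for wl, _ in sample_stacks})
    f_ac = sorted({fx for _, fx in sample_stacks if fx != 0.0})
    if len(f_ac) != 1:
        raise ValueError(f"need exactly one AC frequency, got {f_ac}")
    f_ac = f_ac[0]
    maps = {}
    for wl in wavelengths:
        refl = {}
        for fx in (0.0, f_ac):
            dm = demodulate_dc if fx == 0.0 else demodulate_ac
            refl[fx] = calibrate_reflectance(
                dm(sample_stacks[(wl, fx)]),
                dm(phantom_stacks[(wl, fx)]),
                predict_phantom_reflectance(phantom_spec, lut, wl, fx),
                noise_floor_fraction=noise_floor_fraction,
            )
        maps[wl] = invert_map(refl[0.0], refl[f_ac], lut, residual_tol=residual_tol)
    return maps, unmix(maps, table)


# ---------------------------------------------------------------------------
# Trend tables


@dataclass
class TrendTable:
    """Tidy per-ROI time-series statistics with percent change vs baseline."""

    df: pd.DataFrame

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrendTable":
        return cls(pd.read_csv(path))


def _quantity_arrays(result: PipelineResult, tid, quantity, wavelength):
    if quantity in ("mu_a", "mu_s_prime"):
        m = result.property_maps[tid][wavelength]
        return getattr(m, quantity), m.valid_mask
    cm = result.chromophore_maps[tid]
    return getattr(cm, quantity), cm.valid_mask


def percent_change_series(
    result: PipelineResult,
    rois: dict,
    quantities=QUANTITIES,
    wavelengths=None,
    baseline_rule: str = "first",
    n_baseline: int = 1,
    absolute: bool = False,
) -> TrendTable:
    """Per-ROI mean/sd over time with percent change vs baseline.

    ``baseline_rule='first'`` normalizes to the first timepoint;
    ``'pre_event_mean'`` to the mean of the first ``n_baseline``
    timepoints. ``absolute=True`` reports |percent change|. Rows with a
    zero baseline are flagged (NaN percent change) rather than divided.
    """
    if baseline_rule not in BASELINE_RULES:
        raise ValueError(f"baseline_rule must be one of {BASELINE_RULES}")
    if len(result.timepoint_ids) < 2:
        raise ValueError("percent-change series needs >= 2 timepoints")
    if wavelengths is None:
        wavelengths = sorted(next(iter(result.property_maps.values())))

    rows = []
    for quantity in quantities:
        wl_iter = wavelengths if quantity in ("mu_a", "mu_s_prime") else [None]
        for wl in wl_iter:
            for roi_id, roi in rois.items():
                means, sds = [], []
                for tid in result.timepoint_ids:
                    values, mask = _quantity_arrays(result, tid, quantity, wl)
                    st = roi_stats(values, roi, mask)
                    means.append(st.mean)
                    sds.append(st.sd)
                means = np.asarray(means)
                if baseline_rule == "first":
                    base = means[0]
                else:
                    base = float(np.nanmean(means[:n_baseline]))
                for t, tid in enumerate(result.timepoint_ids):
                    if base == 0 or not np.isfinite(base):
                        pct = np.nan
                    else:
                        pct = 100.0 * (means[t] - base) / base
                        if absolute:
                            pct = abs(pct)
                    rows.append(
                        {
                            "timepoint": tid,
                            "t_index": t,
                            "wavelength": wl,
                            "quantity": quantity,
                            "roi_id": roi_id,
                            "mean": means[t],
                            "sd": sds[t],
                            "percent_change_vs_baseline": pct,
                        }
                    )
    return TrendTable(pd.DataFrame(rows))
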