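"""Synthetic scenes and a forward renderer for the imaging pipeline.

A :class:`Scene` holds per-pixel water and lipid volume fractions plus a
power-law reduced-scattering model mu_s'(lambda) = a * (lambda/lambda0)^-b.
The renderer maps scene optical properties through the Monte Carlo lookup
table to (R_DC, R_AC) per pixel and synthesizes the raw phase-shifted
frames a structured-illumination camera would record, including
illumination nonuniformity, ambient offset, read and shot noise, and
16-bit quantization. Scenario generators emulate the three laboratory
experiments the pipeline is designed for: Intralipid dilution series,
slow desiccation time series, and pre/post-exercise time series with an
in-frame reference phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibrate import CalibrationPhantomSpec
from .chromophores import ExtinctionTable
from .demodulate import PhaseImageSet
from .invert import REASON_OK, OpticalPropertyMap
from .lut import ReflectanceLUT

AC_PHASES_DEG = (0.0, 90.0, 180.0, 270.0)

# 10% Intralipid reduced scattering at 970 nm (mm^-1) and its spectral
# power-law slope across the SWIR band; configurable literature-lineage
# values (the emulsion's Mie scattering falls with wavelength).
INTRALIPID_10PCT_MUS970 = 1.2
INTRALIPID_SCATTER_POWER = 1.62
INTRALIPID_REFERENCE_WAVELENGTH = 970.0


@dataclass
class Scene:
    """Ground-truth composition and scattering of a planar sample."""

    pixel_pitch: float
    C_water_map: np.ndarray
    C_lipid_map: np.ndarray
    scatter_amplitude_map: np.ndarray  # mu_s' at reference_wavelength (mm^-1)
    scatter_power: float = 1.3
    reference_wavelength: float = INTRALIPID_REFERENCE_WAVELENGTH
    regions: dict = field(default_factory=dict)  # name -> boolean mask

    def __post_init__(self) -> None:
        self.C_water_map = np.asarray(self.C_water_map, dtype=float)
        self.C_lipid_map = np.asarray(self.C_lipid_map, dtype=float)
        self.scatter_amplitude_map = np.asarray(
            self.scatter_amplitude_map, dtype=float
        )
        shapes = {
            self.C_water_map.shape,
            self.C_lipid_map.shape,
            self.scatter_amplitude_map.shape,
        }
        if len(shapes) != 1:
            raise ValueError("scene maps must share one shape")
        for name, arr in (("C_water", self.C_water_map), ("C_lipid", self.C_lipid_map)):
            if np.any(arr < 0) or np.any(arr > 1.05):
                raise ValueError(f"{name} outside [0, 1.05]")
        if np.any(self.scatter_amplitude_map <= 0):
            raise ValueError("scatter amplitude must be positive")
        for name, mask in self.regions.items():
            if np.asarray(mask).shape != self.shape:
                raise ValueError(f"region {name!r} mask shape mismatch")

    @property
    def shape(self) -> tuple:
        return self.C_water_map.shape

    def mu_s_prime(self, wavelength: float) -> np.ndarray:
        return self.scatter_amplitude_map * (
            wavelength / self.reference_wavelength
        ) ** (-self.scatter_power)


@dataclass
class AcquisitionModel:
    """Camera/illumination model mapping reflectance to raw counts.

    Noise is Gaussian read noise (``read_sigma`` counts) plus a
    shot-noise-like term with variance ``shot_scale`` x expected counts.
    ``bit_depth=None`` models an ideal (unquantized) sensor.
    """

    gain: float = 30000.0  # counts per unit reflectance
    illumination_profile: np.ndarray | float = 1.0
    ambient_offset: float = 200.0
    read_sigma: float = 10.0
    shot_scale: float = 1.0
    bit_depth: int | None = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.read_sigma < 0 or self.shot_scale < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class TimeSeriesSpec:
    """Schedule of scene edits for a time series.

    Water loss couples to scattering through k: a relative water change
    d(C_w)/C_w multiplies mu_s' by (1 + k * d(C_w)/C_w). k is a modeling
    stand-in for the hydration-scattering mechanism, default 2.

    ``convention`` selects whether ``water_loss_per_step`` is a relative
    fraction of the current water content or absolute percentage points of
    volume fraction.
    """

    n_timepoints: int = 4
    water_loss_per_step: float = 0.00667  # ~2% relative over three steps
    convention: str = "relative"
    coupling_k: float = 2.0
    phantom_region: str | None = None
    # Exercise-specific schedule: baseline frames, step drop, recovery.
    n_baseline: int = 5
    exercise_drop: float = 0.05  # relative water drop at the exercise boundary
    recovery_tau: float = 8.0  # timepoints (minutes) of exponential recovery

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("a time series needs at least 2 timepoints")
        if self.convention not in ("relative", "absolute"):
            raise ValueError("convention must be 'relative' or 'absolute'")
        if not np.isfinite(self.coupling_k):
            raise ValueError("coupling k must be finite")


def scene_optical_properties(
    scene: Scene, table: ExtinctionTable, wavelength: float
) -> OpticalPropertyMap:
    """Ground-truth optical properties of a scene at one wavelength.

    mu_a is the linear water/lipid combination of the extinction table;
    mu_s' follows the scene's power law.
    """
    eps_w, eps_l = table.eps_at(wavelength)
    mu_a = scene.C_water_map * eps_w + scene.C_lipid_map * eps_l
    mu_s = scene.mu_s_prime(wavelength)
    shape = scene.shape
    return OpticalPropertyMap(
        wavelength=wavelength,
        mu_a=mu_a,
        mu_s_prime=mu_s,
        valid_mask=np.ones(shape, dtype=bool),
        reason=np.full(shape, REASON_OK, dtype=np.uint8),
        residual=np.zeros(shape),
    )


def _check_gamut(name, mu_a, mu_s, lut: ReflectanceLUT) -> None:
    bad = (
        (mu_a < lut.mu_a_grid[0])
        | (mu_a > lut.mu_a_grid[-1])
        | (mu_s < lut.mu_s_prime_grid[0])
        | (mu_s > lut.mu_s_prime_grid[-1])
    )
    if np.any(bad):
        idx = np.argwhere(bad)
        raise ValueError(
            f"{name}: {idx.shape[0]} pixels outside the LUT gamut, "
            f"first offenders (row, col): {idx[:5].tolist()}"
        )


def _quantize(frames: np.ndarray, bit_depth: int | None) -> np.ndarray:
    if bit_depth is None:
        return np.maximum(frames, 0.0)
    top = 2**bit_depth - 1
    return np.clip(np.rint(frames), 0, top)


def _render_condition(
    r_dc,
    r_ac,
    model: AcquisitionModel,
    fx: float,
    pixel_pitch: float,
    rng: np.random.Generator,
    wavelength: float,
    mode: str,
):
    """Raw frames for one {wavelength, fx} condition from per-pixel R."""
    illum = np.broadcast_to(
        np.asarray(model.illumination_profile, dtype=float), r_dc.shape
    )

    def add_noise(clean):
        noisy = clean + rng.normal(0.0, model.read_sigma, clean.shape)
        if model.shot_scale > 0:
            noisy = noisy + rng.normal(
                0.0, np.sqrt(model.shot_scale * np.maximum(clean, 0.0))
            )
        return _quantize(noisy, model.bit_depth)

    if mode == "dc":
        clean_on = illum * model.gain * r_dc + model.ambient_offset
        clean_off = np.full_like(clean_on, model.ambient_offset)
        frames = {"on": add_noise(clean_on), "off": add_noise(clean_off)}
    else:
        cols = np.arange(r_dc.shape[1]) * pixel_pitch
        frames = {}
        for phase in AC_PHASES_DEG:
            pattern = np.sin(2.0 * np.pi * fx * cols + np.deg2rad(phase))
            clean = (
                illum * model.gain * (r_dc + r_ac * pattern[None, :])
                + model.ambient_offset
            )
            frames[f"phase_{int(phase)}"] = add_noise(clean)
    return PhaseImageSet(
        wavelength=wavelength,
        fx=fx,
        pixel_pitch=pixel_pitch,
        mode=mode,
        frames=frames,
    )


def render_raw(
    scene: Scene,
    model: AcquisitionModel,
    lut: ReflectanceLUT,
    wavelengths,
    fx_list,
    phantom_spec: CalibrationPhantomSpec,
    table: ExtinctionTable | None = None,
    seed: int | None = None,
) -> dict:
    """Render raw image stacks for a scene and its calibration phantom.

    Returns ``{"sample": {(wavelength, fx): PhaseImageSet},
    "phantom": {...}}``. The phantom stack is rendered under the identical
    acquisition model (illumination, gain, noise statistics). Deterministic
    for a fixed seed; scene or phantom properties outside the LUT gamut are
    rejected listing the offending pixels.
    """
    table = table or ExtinctionTable.from_csv()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    fx_list = list(fx_list)
    if 0.0 not in [float(f) for f in fx_list]:
        raise ValueError("fx_list must include 0 (DC)")
    f_ac = [float(f) for f in fx_list if f != 0.0]

    out = {"sample": {}, "phantom": {}}
    for wl in wavelengths:
        props = scene_optical_properties(scene, table, wl)
        _check_gamut(f"scene at {wl} nm", props.mu_a, props.mu_s_prime, lut)
        p_mu_a, p_mu_s = phantom_spec.optical_properties(wl)
        _check_gamut(
            f"phantom at {wl} nm", np.atleast_1d(p_mu_a), np.atleast_1d(p_mu_s), lut
        )
        r = {}
        r["dc_sample"] = lut.forward(props.mu_a, props.mu_s_prime, 0.0)
        r["dc_phantom"] = np.full(scene.shape, lut.forward(p_mu_a, p_mu_s, 0.0))
        for role in ("sample", "phantom"):
            out[role][(wl, 0.0)] = _render_condition(
                r[f"dc_{role}"],
                None,
                model,
                0.0,
                scene.pixel_pitch,
                rng,
                wl,
                "dc",
            )
        for fx in f_ac:
            ac_sample = lut.forward(props.mu_a, props.mu_s_prime, fx)
            ac_phantom = np.full(scene.shape, lut.forward(p_mu_a, p_mu_s, fx))
            out["sample"][(wl, fx)] = _render_condition(
                r["dc_sample"], ac_sample, model, fx, scene.pixel_pitch, rng, wl, "ac"
            )
            out["phantom"][(wl, fx)] = _render_condition(
                r["dc_phantom"], ac_phantom, model, fx, scene.pixel_pitch, rng, wl, "ac"
            )
    return out


def intralipid_phantom_spec(
    wavelengths,
    table: ExtinctionTable | None = None,
    lipid_fraction: float = 0.10,
    mus970_10pct: float = INTRALIPID_10PCT_MUS970,
    scatter_power: float = INTRALIPID_SCATTER_POWER,
) -> CalibrationPhantomSpec:
    """Known optical properties of an Intralipid calibration phantom.

    Absorption follows the water/lipid extinction table at the dilution's
    volume fractions; reduced scattering scales proportionally with lipid
    fraction from the 10% reference and follows the emulsion's power law.
    """
    table = table or ExtinctionTable.from_csv()
    props = {}
    for wl in wavelengths:
        eps_w, eps_l = table.eps_at(wl)
        mu_a = (1.0 - lipid_fraction) * eps_w + lipid_fraction * eps_l
        mus = (
            mus970_10pct
            * (lipid_fraction / 0.10)
            * (wl / INTRALIPID_REFERENCE_WAVELENGTH) ** (-scatter_power)
        )
        props[float(wl)] = (mu_a, mus)
    return CalibrationPhantomSpec(
        properties=props, label=f"intralipid-{100 * lipid_fraction:g}pct"
    )


# ---------------------------------------------------------------------------
# Scenario generators


def make_dilution_series(
    lipid_fractions,
    shape=(32, 32),
    pixel_pitch: float = 0.5,
    mus970_10pct: float = INTRALIPID_10PCT_MUS970,
    scatter_power: float = INTRALIPID_SCATTER_POWER,
) -> list:
    """Homogeneous Intralipid dilution scenes.

    Each lipid fraction f gives a scene with C_lipid = f, C_water = 1 - f,
    and mu_s' scaled proportionally to f from the 10% Intralipid reference
    (a 20% emulsion scatters twice as much as a 10% one).
    """
    scenes = []
    for f in lipid_fractions:
        f = float(f)
        if not (0.0 < f < 1.0):
            raise ValueError(f"lipid fraction must be in (0, 1), got {f}")
        amp = mus970_10pct * (f / 0.10)
        scenes.append(
            Scene(
                pixel_pitch=pixel_pitch,
                C_water_map=np.full(shape, 1.0 - f),
                C_lipid_map=np.full(shape, f),
                scatter_amplitude_map=np.full(shape, amp),
                scatter_power=scatter_power,
                reference_wavelength=INTRALIPID_REFERENCE_WAVELENGTH,
            )
        )
    return scenes


def make_skin_scene(
    shape=(32, 32),
    pixel_pitch: float = 0.5,
    water: float = 0.70,
    lipid: float = 0.15,
    mus970: float = 1.5,
    scatter_power: float = 1.3,
    heterogeneity: float = 0.05,
    phantom_region: tuple | None = None,
    phantom_water: float = 0.90,
    phantom_lipid: float = 0.10,
    phantom_mus970: float = INTRALIPID_10PCT_MUS970,
    seed: int = 0,
) -> Scene:
    """Spatially heterogeneous skin-like scene, optionally with an in-frame
    static reference-phantom patch.

    ``heterogeneity`` is the relative amplitude of a smooth random field
    multiplying water content and scattering. ``phantom_region`` is a
    half-open pixel rectangle (r0, r1, c0, c1) labeled "phantom" in
    ``scene.regions``.
    """
    rng = np.random.default_rng(seed)

    def smooth_field():
        noise = rng.standard_normal(shape)
        f = gaussian_filter(noise, sigma=max(2.0, min(shape) / 8.0))
        f = f / max(f.std(), 1e-12)
        return 1.0 + heterogeneity * f

    C_w = np.clip(water * smooth_field(), 0.0, 1.0)
    C_l = np.full(shape, lipid)
    amp = mus970 * smooth_field()
    regions = {}
    if phantom_region is not None:
        r0, r1, c0, c1 = phantom_region
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        C_w[mask] = phantom_water
        C_l[mask] = phantom_lipid
        amp[mask] = phantom_mus970
        regions["phantom"] = mask
        regions["skin"] = ~mask
    return Scene(
        pixel_pitch=pixel_pitch,
        C_water_map=C_w,
        C_lipid_map=C_l,
        scatter_amplitude_map=amp,
        scatter_power=scatter_power,
        regions=regions,
    )


def _edited_scene(base: Scene, water_factor, mus_factor, frozen_mask=None) -> Scene:
    """Scene with water and scattering multiplied per pixel, except where
    frozen (the in-frame reference phantom never changes)."""
    wf = np.broadcast_to(np.asarray(water_factor, dtype=float), base.shape).copy()
    sf = np.broadcast_to(np.asarray(mus_factor, dtype=float), base.shape).copy()
    if frozen_mask is not None:
        wf[frozen_mask] = 1.0
        sf[frozen_mask] = 1.0
    C_w = base.C_water_map * wf
    if np.any(C_w < 0):
        raise ValueError("schedule drives water content below zero")
    return replace(
        base,
        C_water_map=C_w,
        C_lipid_map=base.C_lipid_map.copy(),
        scatter_amplitude_map=base.scatter_amplitude_map * sf,
        regions=dict(base.regions),
    )


def _frozen_mask(spec: TimeSeriesSpec, base: Scene):
    if spec.phantom_region is None:
        return None
    if spec.phantom_region not in base.regions:
        raise ValueError(
            f"scene has no region named {spec.phantom_region!r} to hold static"
        )
    return base.regions[spec.phantom_region]


def make_desiccation_series(spec: TimeSeriesSpec, base: Scene) -> list:
    """Monotone drying series: water decremented per step, scattering
    coupled multiplicatively through k."""
    frozen = _frozen_mask(spec, base)
    scenes = [base]
    water_factor = np.ones(base.shape)
    for _ in range(1, spec.n_timepoints):
        if spec.convention == "relative":
            rel_loss = np.full(base.shape, spec.water_loss_per_step)
        else:
            current = base.C_water_map * water_factor
            rel_loss = spec.water_loss_per_step / np.maximum(current, 1e-12)
        water_factor = water_factor * (1.0 - rel_loss)
        # cumulative relative water change sets the scattering factor
        total_rel = 1.0 - water_factor
        mus_factor = 1.0 - spec.coupling_k * total_rel
        if np.any(mus_factor <= 0):
            raise ValueError("coupling drives mu_s' to zero; reduce k or steps")
        scenes.append(_edited_scene(base, water_factor, mus_factor, frozen))
    return scenes


def make_exercise_series(spec: TimeSeriesSpec, base: Scene) -> list:
    """Pre/post-exercise series with a static in-frame reference phantom.

    Baseline timepoints repeat the base scene; at the exercise boundary
    dermal water steps down by ``exercise_drop`` (relative) with coupled
    scattering, then recovers exponentially toward baseline with time
    constant ``recovery_tau``. The phantom-labeled region never changes.
    """
    if spec.phantom_region is None:
        raise ValueError("exercise series requires a phantom region flag")
    frozen = _frozen_mask(spec, base)
    n_post = spec.n_timepoints - spec.n_baseline
    if n_post < 1:
        raise ValueError("n_timepoints must exceed n_baseline")
    scenes = [base] * spec.n_baseline
    for t in range(n_post):
        deficit = spec.exercise_drop * np.exp(-t / spec.recovery_tau)
        water_factor = 1.0 - deficit
        mus_factor = 1.0 - spec.coupling_k * deficit
        scenes.append(_edited_scene(base, water_factor, mus_factor, frozen))
    return scenes
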