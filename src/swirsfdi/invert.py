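"""Inversion of calibrated (R_DC, R_AC) pairs to optical properties.

Each pixel's pair of diffuse reflectance values is matched against the
bilinear-interpolated forward lookup table by least squares in reflectance.
The search is deterministic: a coarse scan over the table nodes seeds a
local 5x5 grid in (log mu_a, log mu_s') that contracts by half per
iteration; ties break toward smaller mu_a. Pixels whose best residual
exceeds the gamut tolerance are flagged rather than assigned values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .calibrate import ReflectanceImage
from .lut import ReflectanceLUT

logger = logging.getLogger(__name__)

DEFAULT_RESIDUAL_TOL = 1e-3  # reflectance units
RELATIVE_STEP_TOL = 1e-6  # descent terminates below this log-coordinate step

# Per-pixel reason codes for invalid entries.
REASON_OK = 0
REASON_MASKED_INPUT = 1
REASON_OUT_OF_GAMUT = 2


@dataclass
class InversionResult:
    """Single-pixel inversion outcome; values are NaN when out of gamut."""

    mu_a: float
    mu_s_prime: float
    residual: float
    in_gamut: bool


@dataclass
class OpticalPropertyMap:
    """Per-pixel absorption and reduced scattering at one wavelength."""

    wavelength: float
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    valid_mask: np.ndarray
    reason: np.ndarray
    residual: np.ndarray


def _check_lut_fx(lut: ReflectanceLUT) -> float:
    if lut.fx_list.size != 2 or not np.isclose(lut.fx_list[0], 0.0):
        raise ValueError("inversion requires a LUT with fx_list = [0, f_ac]")
    return float(lut.fx_list[1])


def _invert_arrays(r_dc, r_ac, lut: ReflectanceLUT, residual_tol: float):
    """Vectorized inversion of flat reflectance arrays.

    Returns (mu_a, mu_s_prime, residual, in_gamut) flat arrays.
    """
    fx_ac = _check_lut_fx(lut)
    r_dc = np.asarray(r_dc, dtype=float).ravel()
    r_ac = np.asarray(r_ac, dtype=float).ravel()
    if not (np.all(np.isfinite(r_dc)) and np.all(np.isfinite(r_ac))):
        raise ValueError("reflectance inputs must be finite")
    n = r_dc.size

    la_grid = np.log(lut.mu_a_grid)
    ls_grid = np.log(lut.mu_s_prime_grid)
    R0 = lut.R[:, :, lut.fx_index(0.0)]
    R1 = lut.R[:, :, lut.fx_index(fx_ac)]

    # Coarse seeding: squared mismatch against every table node.
    la = np.empty(n)
    ls = np.empty(n)
    chunk = 8192
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        err = (R0[None, :, :] - r_dc[sl, None, None]) ** 2 + (
            R1[None, :, :] - r_ac[sl, None, None]
        ) ** 2
        flat = err.reshape(err.shape[0], -1).argmin(axis=1)
        ia, js = np.unravel_index(flat, R0.shape)
        la[sl] = la_grid[ia]
        ls[sl] = ls_grid[js]

    # Local contracting 5x5 grid in log coordinates. Candidate order is
    # ascending mu_a then ascending mu_s', and argmin takes the first
    # minimum, so ties break toward smaller mu_a.
    ha = np.full(n, 2.0 * float(np.max(np.diff(la_grid))))
    hs = np.full(n, 2.0 * float(np.max(np.diff(ls_grid))))
    offsets = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    interp0 = lut._interp(lut.fx_index(0.0))
    interp1 = lut._interp(lut.fx_index(fx_ac))
    best_err = None
    rows = np.arange(n)
    # Windows contract only while the minimum is interior; a minimum on the
    # window edge keeps the width so the search can walk out of a poor seed.
    for _ in range(200):
        if max(ha.max(), hs.max()) <= RELATIVE_STEP_TOL:
            break
        ca = np.clip(
            la[:, None, None] + offsets[None, :, None] * ha[:, None, None],
            la_grid[0],
            la_grid[-1],
        )
        cs = np.clip(
            ls[:, None, None] + offsets[None, None, :] * hs[:, None, None],
            ls_grid[0],
            ls_grid[-1],
        )
        ca, cs = np.broadcast_arrays(ca, cs)
        pts = np.stack([ca.reshape(n, 25), cs.reshape(n, 25)], axis=-1)
        v0 = interp0(pts)
        v1 = interp1(pts)
        err = (v0 - r_dc[:, None]) ** 2 + (v1 - r_ac[:, None]) ** 2
        pick = err.argmin(axis=1)
        la_new = ca.reshape(n, 25)[rows, pick]
        ls_new = cs.reshape(n, 25)[rows, pick]
        best_err = err[rows, pick]
        ia_off, is_off = np.unravel_index(pick, (5, 5))
        at_edge_a = (ia_off == 0) | (ia_off == 4)
        at_edge_s = (is_off == 0) | (is_off == 4)
        ha = np.where(at_edge_a, ha, 0.5 * ha)
        hs = np.where(at_edge_s, hs, 0.5 * hs)
        la = la_new
        ls = ls_new

    residual = np.sqrt(best_err)
    in_gamut = residual <= residual_tol
    mu_a = np.where(in_gamut, np.exp(la), np.nan)
    mu_s_prime = np.where(in_gamut, np.exp(ls), np.nan)
    return mu_a, mu_s_prime, residual, in_gamut


def invert_pixel(
    r_dc: float,
    r_ac: float,
    lut: ReflectanceLUT,
    residual_tol: float = DEFAULT_RESIDUAL_TOL,
) -> InversionResult:
    """Invert one (R_DC, R_AC) pair to (mu_a, mu_s_prime)."""
    mu_a, mu_s, res, ok = _invert_arrays([r_dc], [r_ac], lut, residual_tol)
    return InversionResult(float(mu_a[0]), float(mu_s[0]), float(res[0]), bool(ok[0]))


def invert_map(
    r_dc_img: ReflectanceImage,
    r_ac_img: ReflectanceImage,
    lut: ReflectanceLUT,
    residual_tol: float = DEFAULT_RESIDUAL_TOL,
) -> OpticalPropertyMap:
    """Per-pixel inversion of a DC/AC reflectance image pair.

    Only pixels valid in both inputs are inverted; others carry reason
    codes. The invalid fraction is logged.
    """
    if not np.isclose(r_dc_img.wavelength, r_ac_img.wavelength):
        raise ValueError(
            f"wavelength mismatch: {r_dc_img.wavelength} vs {r_ac_img.wavelength} nm"
        )
    if r_dc_img.R.shape != r_ac_img.R.shape:
        raise ValueError("DC and AC images have different shapes")

    shape = r_dc_img.R.shape
    valid_in = r_dc_img.valid_mask & r_ac_img.valid_mask
    mu_a = np.full(shape, np.nan)
    mu_s = np.full(shape, np.nan)
    residual = np.full(shape, np.nan)
    reason = np.full(shape, REASON_MASKED_INPUT, dtype=np.uint8)
    if valid_in.any():
        a, s, res, ok = _invert_arrays(
            r_dc_img.R[valid_in], r_ac_img.R[valid_in], lut, residual_tol
        )
        mu_a[valid_in] = a
        mu_s[valid_in] = s
        residual[valid_in] = res
        rcodes = np.where(ok, REASON_OK, REASON_OUT_OF_GAMUT).astype(np.uint8)
        reason[valid_in] = rcodes
    valid = reason == REASON_OK
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > 0:
        logger.info(
            "invert_map: %.1f%% of pixels invalid at %g nm",
            100 * frac_invalid,
            r_dc_img.wavelength,
        )
    return OpticalPropertyMap(
        wavelength=r_dc_img.wavelength,
        mu_a=mu_a,
        mu_s_prime=mu_s,
        valid_mask=valid,
        reason=reason,
        residual=residual,
    )
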