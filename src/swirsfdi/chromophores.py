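"""Water/lipid unmixing of multi-wavelength absorption maps.

At each pixel the measured absorption coefficients are modeled as a linear
combination of pure-chromophore basis spectra,

    mu_a(lambda) = eps_water(lambda) * C_water + eps_lipid(lambda) * C_lipid,

and solved by ordinary (unconstrained) least squares over the available
wavelengths. With the packaged three-wavelength table (970, 1050, 1200 nm)
the system is overdetermined by one equation. Extinction coefficients are
standardized to pure-substance absorption (mm^-1 at 100% volume fraction),
so the recovered weights are volume fractions; the conventional molar
equivalents are 55.6 M for 100% water and 0.9 g/mL for 100% lipid.

The packaged coefficients are digitized from the standard pure-water and
soybean-oil absorption spectra; they are replaceable data with recorded
provenance, not ground truth.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .invert import OpticalPropertyMap

#: Molarity of pure water (mol/L) used when converting molar extinction
#: inputs to the pure-substance (volume-fraction) convention.
WATER_MOLARITY_100PCT = 55.6
#: Density of pure lipid (g/mL) for the same conversion.
LIPID_DENSITY_100PCT = 0.9


@dataclass
class ExtinctionTable:
    """Pure-substance absorption spectra for water and lipid.

    ``eps_water``/``eps_lipid`` are absorption coefficients (mm^-1) of the
    pure substance at each wavelength (nm).
    """

    wavelengths: np.ndarray
    eps_water: np.ndarray
    eps_lipid: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.eps_water = np.asarray(self.eps_water, dtype=float)
        self.eps_lipid = np.asarray(self.eps_lipid, dtype=float)
        if np.unique(self.wavelengths).size != self.wavelengths.size:
            raise ValueError("wavelengths must be unique")
        if np.any(self.eps_water <= 0) or np.any(self.eps_lipid <= 0):
            raise ValueError("extinction coefficients must be strictly positive")

    @classmethod
    def from_csv(cls, path=None) -> "ExtinctionTable":
        """Load a table from CSV; with no path, the packaged SWIR table."""
        if path is None:
            path = importlib.resources.files("swirsfdi.data") / "extinction_swir.csv"
        df = pd.read_csv(path)
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(),
            eps_water=df["eps_water_mm-1"].to_numpy(),
            eps_lipid=df["eps_lipid_mm-1"].to_numpy(),
            provenance=list(df.get("source", [])),
        )

    def design_matrix(self, wavelengths) -> np.ndarray:
        """(n_wavelengths, 2) matrix of [eps_water, eps_lipid] rows."""
        rows = []
        for wl in wavelengths:
            idx = np.nonzero(np.isclose(self.wavelengths, wl))[0]
            if idx.size == 0:
                raise KeyError(f"no extinction data at {wl} nm")
            rows.append([self.eps_water[idx[0]], self.eps_lipid[idx[0]]])
        return np.asarray(rows)

    def condition_number(self, wavelengths=None) -> float:
        E = self.design_matrix(
            self.wavelengths if wavelengths is None else wavelengths
        )
        return float(np.linalg.cond(E))

    def eps_at(self, wavelength: float) -> tuple:
        E = self.design_matrix([wavelength])
        return float(E[0, 0]), float(E[0, 1])


@dataclass
class ChromophoreMap:
    """Per-pixel water and lipid volume fractions with fit diagnostics."""

    C_water: np.ndarray
    C_lipid: np.ndarray
    residual: np.ndarray
    valid_mask: np.ndarray
    negativity_mask: np.ndarray


def unmix(mu_a_maps: dict, table: ExtinctionTable) -> ChromophoreMap:
    """Least-squares water/lipid concentrations from absorption maps.

    ``mu_a_maps`` maps wavelength (nm) to an :class:`OpticalPropertyMap`.
    Solutions are unconstrained; negative concentrations are retained but
    flagged in ``negativity_mask``. Pixels invalid at any wavelength are
    excluded via ``valid_mask``.
    """
    if len(mu_a_maps) < 2:
        raise ValueError("unmixing needs at least two wavelengths")
    wavelengths = sorted(mu_a_maps)
    E = table.design_matrix(wavelengths)
    if np.linalg.matrix_rank(E) < 2:
        raise ValueError("singular design matrix (collinear extinction rows)")

    maps = [mu_a_maps[wl] for wl in wavelengths]
    shape = maps[0].mu_a.shape
    for m in maps:
        if m.mu_a.shape != shape:
            raise ValueError("absorption maps must share one shape")
    valid = np.logical_and.reduce([m.valid_mask for m in maps])
    stack = np.stack([np.where(valid, m.mu_a, 0.0) for m in maps])  # (n_wl, ...)
    flat = stack.reshape(len(wavelengths), -1)

    coeff = np.linalg.pinv(E) @ flat  # (2, n_pix)
    fitted = E @ coeff
    resid = np.sqrt(((fitted - flat) ** 2).sum(axis=0))

    C_w = coeff[0].reshape(shape)
    C_l = coeff[1].reshape(shape)
    residual = resid.reshape(shape)
    C_w = np.where(valid, C_w, np.nan)
    C_l = np.where(valid, C_l, np.nan)
    residual = np.where(valid, residual, np.nan)
    negativity = valid & ((C_w < 0) | (C_l < 0))
    return ChromophoreMap(
        C_water=C_w,
        C_lipid=C_l,
        residual=residual,
        valid_mask=valid,
        negativity_mask=negativity,
    )


def to_percent(cmap: ChromophoreMap) -> tuple:
    """Express volume fractions as percent of the pure substance.

    100% corresponds to pure water (55.6 M) and pure lipid (0.9 g/mL)
    respectively; the conversion is simply 100 x volume fraction because
    the extinction inputs are already per unit volume fraction.
    """
    return 100.0 * cmap.C_water, 100.0 * cmap.C_lipid


def molar_to_volume_fraction_eps(eps_molar_water=None, eps_molar_lipid=None):
    """Convert molar extinction (mm^-1 M^-1, natural log base) to the
    pure-substance convention used here.

    Water: multiply by 55.6 M; lipid: multiply by 0.9 g/mL expressed in the
    caller's molar units. Returns the converted value(s) in the same order.
    """
    out = []
    if eps_molar_water is not None:
        out.append(np.asarray(eps_molar_water) * WATER_MOLARITY_100PCT)
    if eps_molar_lipid is not None:
        out.append(np.asarray(eps_molar_lipid) * LIPID_DENSITY_100PCT)
    return out[0] if len(out) == 1 else tuple(out)
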