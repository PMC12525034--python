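"""Bidirectional Monte Carlo lookup table (mu_a, mu_s') <-> (R_DC, R_AC).

The table is built by White Monte Carlo: one zero-absorption transport run
per reduced-scattering grid value (all runs share the same seed, so the
per-mean-free-path photon ensemble is common and the table is monotone in
mu_s' by construction), rescaled to every absorption grid value with
exp(-mu_a * L) per photon, then Hankel-transformed to each spatial
frequency.

Forward evaluation interpolates bilinearly in (log mu_a, log mu_s')
coordinates, where the reflectance surface is closest to linear.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from scipy.special import j0

from .media import MediumSpec
from .mc import (
    DEFAULT_N_BINS,
    DEFAULT_R_MAX_MM,
    STATUS_CENSORED,
    STATUS_ESCAPED,
    run_transport,
)

LUT_FORMAT_VERSION = "1"


class LUTInvariantError(AssertionError):
    """A built lookup table violated a physical monotonicity invariant."""


@dataclass
class MCConfig:
    """Monte Carlo settings for building a lookup table.

    ``l_max`` caps photon pathlengths (mm); the induced underestimate of
    reflectance is bounded by ``censored_fraction * exp(-mu_a * l_max)`` and
    recorded in the table metadata.
    """

    n_photons: int = 100_000
    g: float = 0.9
    n_medium: float = 1.33
    n_ambient: float = 1.0
    r_max: float = DEFAULT_R_MAX_MM
    n_bins: int = DEFAULT_N_BINS
    l_max: float = 1000.0


@dataclass
class ReflectanceLUT:
    """Grid of diffuse reflectance R[i_mu_a, i_mu_s_prime, i_fx]."""

    mu_a_grid: np.ndarray
    mu_s_prime_grid: np.ndarray
    fx_list: np.ndarray
    R: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu_a_grid = np.asarray(self.mu_a_grid, dtype=float)
        self.mu_s_prime_grid = np.asarray(self.mu_s_prime_grid, dtype=float)
        self.fx_list = np.asarray(self.fx_list, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self._interps: dict[int, RegularGridInterpolator] = {}

    # -- lookup ----------------------------------------------------------

    def fx_index(self, fx: float) -> int:
        idx = np.nonzero(np.isclose(self.fx_list, fx))[0]
        if idx.size == 0:
            raise ValueError(f"fx={fx} not in table fx_list {self.fx_list}")
        return int(idx[0])

    def _interp(self, k: int) -> RegularGridInterpolator:
        if k not in self._interps:
            self._interps[k] = RegularGridInterpolator(
                (np.log(self.mu_a_grid), np.log(self.mu_s_prime_grid)),
                self.R[:, :, k],
                method="linear",
                bounds_error=True,
            )
        return self._interps[k]

    def forward(self, mu_a, mu_s_prime, fx: float):
        """Interpolated reflectance at (mu_a, mu_s_prime) for one fx.

        Bilinear in (log mu_a, log mu_s'). Accepts scalars or arrays;
        raises for queries outside the grid, naming the offending axis.
        """
        mu_a = np.asarray(mu_a, dtype=float)
        mu_s_prime = np.asarray(mu_s_prime, dtype=float)
        for name, vals, grid in (
            ("mu_a", mu_a, self.mu_a_grid),
            ("mu_s_prime", mu_s_prime, self.mu_s_prime_grid),
        ):
            if np.any(vals < grid[0]) or np.any(vals > grid[-1]):
                raise ValueError(
                    f"{name} outside LUT grid [{grid[0]}, {grid[-1]}]"
                )
        pts = np.stack(
            np.broadcast_arrays(np.log(mu_a), np.log(mu_s_prime)), axis=-1
        )
        scalar = pts.ndim == 1
        out = self._interp(self.fx_index(fx))(pts)
        return float(out.reshape(-1)[0]) if scalar else out

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        """Assert the physical invariants of a diffuse-reflectance table."""
        if np.any(self.R < 0.0) or np.any(self.R > 1.0):
            raise LUTInvariantError("R outside [0, 1]")
        if not np.all(np.diff(self.R, axis=0) < 0.0):
            raise LUTInvariantError("R not strictly decreasing in mu_a")
        if np.any(np.diff(self.R, axis=1) < 0.0):
            raise LUTInvariantError("R not increasing in mu_s_prime")
        for k, fx in enumerate(self.fx_list):
            if fx > 0 and np.any(self.R[:, :, k] > self.R[:, :, self.fx_index(0.0)]):
                raise LUTInvariantError("R(fx>0) exceeds R(fx=0) somewhere")

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mu_a_grid", data=self.mu_a_grid)
            f.create_dataset("mu_s_prime_grid", data=self.mu_s_prime_grid)
            f.create_dataset("fx_list", data=self.fx_list)
            f.create_dataset("R", data=self.R)
            for key, val in self.meta.items():
                f.attrs[key] = val
            f.attrs["version"] = LUT_FORMAT_VERSION

    @classmethod
    def load(cls, path) -> "ReflectanceLUT":
        with h5py.File(path, "r") as f:
            lut = cls(
                mu_a_grid=f["mu_a_grid"][:],
                mu_s_prime_grid=f["mu_s_prime_grid"][:],
                fx_list=f["fx_list"][:],
                R=f["R"][:],
                meta={k: v for k, v in f.attrs.items()},
            )
        return lut

    def to_csv(self, path) -> None:
        """Long-format CSV export for inspection."""
        import pandas as pd

        ia, js, kf = np.meshgrid(
            np.arange(self.mu_a_grid.size),
            np.arange(self.mu_s_prime_grid.size),
            np.arange(self.fx_list.size),
            indexing="ij",
        )
        pd.DataFrame(
            {
                "mu_a_mm-1": self.mu_a_grid[ia.ravel()],
                "mu_s_prime_mm-1": self.mu_s_prime_grid[js.ravel()],
                "fx_mm-1": self.fx_list[kf.ravel()],
                "R": self.R.ravel(),
            }
        ).to_csv(path, index=False)


def default_grids() -> tuple[np.ndarray, np.ndarray]:
    """Default LUT axes: mu_a log-spaced 0.001-0.5, mu_s' 0.3-5 (48 pts).

    The mu_s' floor keeps the table in the diffusive domain at the default
    AC frequency (0.1 mm^-1): for transport mean free paths approaching the
    pattern period the AC reflectance loses its monotone dependence on
    absorption (the diffusion closed form shows the same sign change), so a
    bidirectional table there would be ill-posed.
    """
    return np.geomspace(1e-3, 0.5, 48), np.geomspace(0.3, 5.0, 48)


def build_lut(
    mu_a_grid,
    mu_s_prime_grid,
    fx_list=(0.0, 0.1),
    mc_config: MCConfig | None = None,
    seed: int = 0,
) -> ReflectanceLUT:
    """Build a reflectance lookup table by White Monte Carlo.

    One zero-absorption transport run per mu_s' grid value (shared seed);
    absorption filled in by per-photon exp(-mu_a * L) rescaling; the
    zero-order Hankel transform of the radial profile gives R at each
    spatial frequency. Deterministic for a fixed seed. Invariants are
    asserted before the table is returned.
    """
    cfg = mc_config or MCConfig()
    mu_a_grid = np.asarray(mu_a_grid, dtype=float)
    mu_s_prime_grid = np.asarray(mu_s_prime_grid, dtype=float)
    fx_list = np.asarray(fx_list, dtype=float)
    for name, grid in (("mu_a_grid", mu_a_grid), ("mu_s_prime_grid", mu_s_prime_grid)):
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be strictly ascending with >= 2 points")
    if not np.any(np.isclose(fx_list, 0.0)):
        raise ValueError("fx_list must contain 0 (DC)")

    warnings_list = []
    if mu_s_prime_grid[0] < 10.0 * mu_a_grid[-1]:
        warnings_list.append(
            "grid corner mu_s' < 10*mu_a is outside the validated MC regime"
        )

    R = np.zeros((mu_a_grid.size, mu_s_prime_grid.size, fx_list.size))
    max_censored = 0.0
    for j, mus in enumerate(mu_s_prime_grid):
        medium = MediumSpec(
            mu_a=0.0,
            mu_s_prime=float(mus),
            g=cfg.g,
            n_medium=cfg.n_medium,
            n_ambient=cfg.n_ambient,
        )
        # Same seed for every mu_s' run: at mu_a = 0 the walk is scale-free,
        # so the shared ensemble makes R monotone in mu_s' by construction.
        records = run_transport(medium, cfg.n_photons, seed=seed, l_max=cfg.l_max)
        esc = records.status == STATUS_ESCAPED
        cen = records.status == STATUS_CENSORED
        w_esc = records.weight[esc]
        l_esc = records.pathlength[esc]
        r_esc = records.r[esc]
        w_cen = records.weight[cen]
        l_cen = records.pathlength[cen]
        max_censored = max(max_censored, float(w_cen.sum()) / cfg.n_photons)
        # Exact Monte Carlo Hankel quadrature: R(fx) = E[w e^{-mu_a L} J0(2 pi fx r)].
        # Censored photons (final radius unknown) enter only the DC channel,
        # where their almost-sure eventual escape bounds the contribution.
        j0_esc = {k: j0(2.0 * np.pi * float(fx) * r_esc) for k, fx in enumerate(fx_list)}
        for i, mua in enumerate(mu_a_grid):
            scale_esc = w_esc * np.exp(-float(mua) * l_esc)
            scale_cen = w_cen * np.exp(-float(mua) * l_cen)
            for k, fx in enumerate(fx_list):
                val = float(np.dot(scale_esc, j0_esc[k]))
                if fx == 0.0:
                    val += float(scale_cen.sum())
                R[i, j, k] = val / cfg.n_photons

    meta = {
        "g": cfg.g,
        "n_medium": cfg.n_medium,
        "n_ambient": cfg.n_ambient,
        "n_photons": cfg.n_photons,
        "seed": int(seed),
        "r_max_mm": cfg.r_max,
        "n_bins": cfg.n_bins,
        "l_max_mm": cfg.l_max,
        "censoring_bias_bound": max_censored * float(np.exp(-mu_a_grid[0] * cfg.l_max)),
        "build_timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "warnings": "; ".join(warnings_list),
    }
    lut = ReflectanceLUT(
        mu_a_grid=mu_a_grid,
        mu_s_prime_grid=mu_s_prime_grid,
        fx_list=fx_list,
        R=R,
        meta=meta,
    )
    lut.validate()
    return lut
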