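"""Optical description of a semi-infinite homogeneous turbid medium."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MediumSpec:
    """Optical properties of a semi-infinite homogeneous medium.

    Parameters
    ----------
    mu_a:
        Absorption coefficient (mm^-1), >= 0.
    mu_s_prime:
        Reduced scattering coefficient mu_s * (1 - g) (mm^-1), > 0.
    g:
        Scattering anisotropy of the Henyey-Greenstein phase function,
        -1 < g < 1. Soft tissue convention is 0.9.
    n_medium:
        Refractive index inside the medium (>= 1).
    n_ambient:
        Refractive index of the ambient half-space (>= 1).
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.9
    n_medium: float = 1.4
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0.0):
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if not (self.mu_s_prime > 0.0):
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if not (self.n_medium >= 1.0):
            raise ValueError(f"n_medium must be >= 1, got {self.n_medium}")
        if not (self.n_ambient >= 1.0):
            raise ValueError(f"n_ambient must be >= 1, got {self.n_ambient}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s' / (1 - g) (mm^-1)."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def n_rel(self) -> float:
        """Relative refractive index n_medium / n_ambient."""
        return self.n_medium / self.n_ambient

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path 1 / (mu_a + mu_s') (mm)."""
        return 1.0 / (self.mu_a + self.mu_s_prime)
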