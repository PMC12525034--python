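"""Diffusion-approximation oracle for frequency-domain diffuse reflectance.

Standard semi-infinite diffusion solution for sinusoidally structured
illumination with an extrapolated (partial-current) boundary condition.
Used as an independent closed-form cross-check of the Monte Carlo model in
the diffusive regime (mu_s' >> mu_a, low spatial frequency); it is never
used to build lookup tables.
"""

from __future__ import annotations

import warnings

import numpy as np

from .media import MediumSpec


def effective_reflection_coefficient(n_rel: float) -> float:
    """Internal diffuse reflection parameter R_eff for a refractive mismatch.

    Polynomial fit in the relative index n = n_medium / n_ambient
    (Groenhuis-style), valid for n in [1, 1.6]. Matched boundaries give
    R_eff ~ 0.
    """
    n = n_rel
    if n == 1.0:
        return 0.0
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffusion_rd(medium: MediumSpec, fx: float) -> float:
    """Closed-form diffuse reflectance at spatial frequency ``fx`` (mm^-1).

    Scalar attenuation mu_eff' = sqrt(3*mu_a*mu_tr + (2*pi*fx)^2) with
    mu_tr = mu_a + mu_s'; the boundary enters through
    A = (1 - R_eff) / (2 * (1 + R_eff)).

    Deterministic, no RNG. Emits a warning when mu_s'/mu_a < 10 where the
    diffusion approximation is unreliable.
    """
    if fx < 0:
        raise ValueError("fx must be >= 0")
    if medium.mu_a > 0 and medium.mu_s_prime / medium.mu_a < 10.0:
        warnings.warn(
            "diffusion approximation is unreliable for mu_s'/mu_a < 10",
            stacklevel=2,
        )
    mu_tr = medium.mu_a + medium.mu_s_prime
    a_prime = medium.mu_s_prime / mu_tr
    mu_eff_prime = np.sqrt(3.0 * medium.mu_a * mu_tr + (2.0 * np.pi * fx) ** 2)
    r_eff = effective_reflection_coefficient(medium.n_rel)
    A = (1.0 - r_eff) / (2.0 * (1.0 + r_eff))
    x = mu_eff_prime / mu_tr
    return float(3.0 * A * a_prime / ((x + 1.0) * (x + 3.0 * A)))
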