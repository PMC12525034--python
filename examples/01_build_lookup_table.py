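"""Build a Monte Carlo reflectance lookup table and sanity-check it.

The table maps (absorption, reduced scattering) to diffuse reflectance
under planar (DC, fx = 0) and structured (AC, fx = 0.1 mm^-1)
illumination. A closed-form diffusion value provides an independent check
in the diffusive regime.
"""

from swirsfdi import MediumSpec, diffusion_rd

from _common import example_lut

lut = example_lut()
print(f"grid: {lut.mu_a_grid.size} mu_a x {lut.mu_s_prime_grid.size} mu_s' nodes")
print(f"photons per scattering value: {lut.meta['n_photons']}")

mu_a, mu_s = 0.01, 1.0  # mm^-1, a dilute-Intralipid-like medium
r_dc = lut.forward(mu_a, mu_s, 0.0)
r_ac = lut.forward(mu_a, mu_s, 0.1)
medium = MediumSpec(mu_a, mu_s, g=0.9, n_medium=1.33)
print(f"\nat mu_a={mu_a}, mu_s'={mu_s} mm^-1:")
print(f"  R_DC = {r_dc:.4f}  (diffusion closed form: {diffusion_rd(medium, 0.0):.4f})")
print(f"  R_AC = {r_ac:.4f}  (diffusion closed form: {diffusion_rd(medium, 0.1):.4f})")
print(
    "\nR_AC < R_DC because the structured pattern blurs out over long"
    "\nphoton paths; absorption lowers both. Agreement with diffusion to a"
    "\nfew percent confirms the transport physics."
)
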