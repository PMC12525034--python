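"""Shared helper: build (once) and cache a small Monte Carlo lookup table.

The examples use a compact grid spanning liquid-phantom and skin-like
optical properties so they run in about a minute on a laptop core.
"""

import pathlib

import numpy as np

from swirsfdi import MCConfig, ReflectanceLUT, build_lut

CACHE = pathlib.Path(__file__).parent / "example_lut.h5"


def example_lut(seed: int = 7) -> ReflectanceLUT:
    if CACHE.exists():
        return ReflectanceLUT.load(CACHE)
    print("building a small lookup table (one-off, ~1 minute) ...")
    lut = build_lut(
        np.geomspace(0.002, 0.3, 12),
        np.geomspace(0.3, 4.0, 10),
        (0.0, 0.1),
        MCConfig(n_photons=30_000, l_max=800.0),
        seed=seed,
    )
    lut.save(CACHE)
    return lut
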