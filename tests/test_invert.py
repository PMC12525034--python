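"""LUT inversion mechanics on the analytic synthetic table."""

import numpy as np
import pytest

from swirsfdi import ReflectanceImage, invert_map, invert_pixel
from swirsfdi.invert import (
    REASON_MASKED_INPUT,
    REASON_OK,
    REASON_OUT_OF_GAMUT,
    _invert_arrays,
)


def interior_points(lut, n, seed=0, margin=0.1):
    """Random off-grid points inside the central (1 - 2*margin) of the gamut."""
    rng = np.random.default_rng(seed)
    lo_a, hi_a = np.log(lut.mu_a_grid[[0, -1]])
    lo_s, hi_s = np.log(lut.mu_s_prime_grid[[0, -1]])
    la = rng.uniform(lo_a + margin * (hi_a - lo_a), hi_a - margin * (hi_a - lo_a), n)
    ls = rng.uniform(lo_s + margin * (hi_s - lo_s), hi_s - margin * (hi_s - lo_s), n)
    return np.exp(la), np.exp(ls)


def refl_image(R, wavelength=970.0, fx=0.0, mask=None):
    R = np.asarray(R, float)
    return ReflectanceImage(
        wavelength=wavelength,
        fx=fx,
        R=R,
        valid_mask=np.ones(R.shape, bool) if mask is None else mask,
    )


class TestInvertPixel:
    def test_node_recovered_exactly(self, synthetic_lut):
        i, j = 12, 25
        res = invert_pixel(
            synthetic_lut.R[i, j, 0], synthetic_lut.R[i, j, 1], synthetic_lut
        )
        assert res.in_gamut
        assert res.mu_a == pytest.approx(synthetic_lut.mu_a_grid[i], rel=1e-9)
        assert res.mu_s_prime == pytest.approx(
            synthetic_lut.mu_s_prime_grid[j], rel=1e-9
        )

    def test_forward_round_trip_within_half_percent(self, synthetic_lut):
        mua, mus = interior_points(synthetic_lut, 50, seed=1)
        rdc = synthetic_lut.forward(mua, mus, 0.0)
        rac = synthetic_lut.forward(mua, mus, 0.1)
        a, s, _, ok = _invert_arrays(rdc, rac, synthetic_lut, 1e-3)
        assert ok.all()
        assert np.abs(a / mua - 1).max() < 5e-3
        assert np.abs(s / mus - 1).max() < 5e-3

    def test_out_of_gamut_flagged_without_value(self, synthetic_lut):
        res = invert_pixel(0.9, 0.89, synthetic_lut)
        assert not res.in_gamut
        assert np.isnan(res.mu_a) and np.isnan(res.mu_s_prime)
        assert res.residual > 1e-3

    def test_nonfinite_input_rejected(self, synthetic_lut):
        with pytest.raises(ValueError):
            invert_pixel(np.nan, 0.3, synthetic_lut)

    def test_single_frequency_lut_rejected(self, synthetic_lut):
        from dataclasses import replace

        one_fx = replace(
            synthetic_lut,
            fx_list=np.array([0.0]),
            R=synthetic_lut.R[:, :, :1],
        )
        with pytest.raises(ValueError):
            invert_pixel(0.5, 0.4, one_fx)

    def test_objective_minimum_unique_in_gamut(self, synthetic_lut):
        """Exhaustive fine-grid scan: for in-gamut targets every near-optimal
        point lies in one localized basin around the argmin (no competing
        minimum elsewhere in the gamut), on 20 seeded cases."""
        mua, mus = interior_points(synthetic_lut, 20, seed=3)
        n_scan = 200
        la = np.linspace(*np.log(synthetic_lut.mu_a_grid[[0, -1]]), n_scan)
        ls = np.linspace(*np.log(synthetic_lut.mu_s_prime_grid[[0, -1]]), n_scan)
        LA, LS = np.meshgrid(la, ls, indexing="ij")
        pts = np.stack([LA.ravel(), LS.ravel()], axis=-1)
        v0 = synthetic_lut._interp(0)(pts).reshape(n_scan, n_scan)
        v1 = synthetic_lut._interp(1)(pts).reshape(n_scan, n_scan)
        for k in range(20):
            rdc = synthetic_lut.forward(mua[k], mus[k], 0.0)
            rac = synthetic_lut.forward(mua[k], mus[k], 0.1)
            err = (v0 - rdc) ** 2 + (v1 - rac) ** 2
            i0, j0 = np.unravel_index(err.argmin(), err.shape)
            near = err <= 10.0 * err.min()
            ii, jj = np.nonzero(near)
            dist = np.hypot(LA[ii, jj] - LA[i0, j0], LS[ii, jj] - LS[i0, j0])
            assert dist.max() < 0.15  # log-coordinate units


class TestInvertMap:
    def test_uniform_node_images_give_uniform_map(self, synthetic_lut):
        i, j = 15, 18
        shape = (5, 7)
        m = invert_map(
            refl_image(np.full(shape, synthetic_lut.R[i, j, 0]), fx=0.0),
            refl_image(np.full(shape, synthetic_lut.R[i, j, 1]), fx=0.1),
            synthetic_lut,
        )
        assert m.valid_mask.all()
        np.testing.assert_allclose(m.mu_a, synthetic_lut.mu_a_grid[i], rtol=1e-9)
        np.testing.assert_allclose(
            m.mu_s_prime, synthetic_lut.mu_s_prime_grid[j], rtol=1e-9
        )

    def test_checkerboard_recovered(self, synthetic_lut):
        pairs = [(0.01, 1.0), (0.05, 2.0)]
        shape = (6, 6)
        board = np.indices(shape).sum(axis=0) % 2
        mua = np.where(board == 0, pairs[0][0], pairs[1][0])
        mus = np.where(board == 0, pairs[0][1], pairs[1][1])
        rdc = synthetic_lut.forward(mua, mus, 0.0)
        rac = synthetic_lut.forward(mua, mus, 0.1)
        m = invert_map(
            refl_image(rdc, fx=0.0), refl_image(rac, fx=0.1), synthetic_lut
        )
        assert m.valid_mask.all()
        np.testing.assert_allclose(m.mu_a, mua, rtol=5e-3)
        np.testing.assert_allclose(m.mu_s_prime, mus, rtol=5e-3)

    def test_input_masks_propagate_with_reason_codes(self, synthetic_lut):
        shape = (4, 8)
        mask = np.zeros(shape, bool)
        mask[:, :4] = True  # half the pixels valid
        rdc = np.full(shape, synthetic_lut.R[10, 10, 0])
        rac = np.full(shape, synthetic_lut.R[10, 10, 1])
        m = invert_map(
            refl_image(rdc, fx=0.0, mask=mask),
            refl_image(rac, fx=0.1, mask=np.ones(shape, bool)),
            synthetic_lut,
        )
        assert m.valid_mask.mean() <= 0.5
        assert np.all(m.reason[~mask] == REASON_MASKED_INPUT)
        assert np.all(m.reason[mask] == REASON_OK)

    def test_gamut_failures_reason_coded(self, synthetic_lut):
        shape = (2, 2)
        m = invert_map(
            refl_image(np.full(shape, 0.95), fx=0.0),
            refl_image(np.full(shape, 0.94), fx=0.1),
            synthetic_lut,
        )
        assert not m.valid_mask.any()
        assert np.all(m.reason == REASON_OUT_OF_GAMUT)

    def test_wavelength_mismatch_rejected(self, synthetic_lut):
        r = np.full((2, 2), 0.3)
        with pytest.raises(ValueError):
            invert_map(
                refl_image(r, wavelength=970.0, fx=0.0),
                refl_image(r, wavelength=1050.0, fx=0.1),
                synthetic_lut,
            )
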