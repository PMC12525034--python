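"""Water/lipid least-squares unmixing against brute-force oracles."""

import numpy as np
import pytest

from swirsfdi import ExtinctionTable, to_percent, unmix
from swirsfdi.invert import REASON_OK, OpticalPropertyMap


def property_maps(mu_a_by_wl, valid=None):
    maps = {}
    for wl, mu_a in mu_a_by_wl.items():
        mu_a = np.atleast_2d(np.asarray(mu_a, float))
        mask = np.ones(mu_a.shape, bool) if valid is None else valid
        maps[wl] = OpticalPropertyMap(
            wavelength=wl,
            mu_a=mu_a,
            mu_s_prime=np.ones_like(mu_a),
            valid_mask=mask,
            reason=np.full(mu_a.shape, REASON_OK, np.uint8),
            residual=np.zeros_like(mu_a),
        )
    return maps


def synthesize(table, C_w, C_l):
    return {
        wl: C_w * table.eps_at(wl)[0] + C_l * table.eps_at(wl)[1]
        for wl in table.wavelengths
    }


def grid_search_oracle(E, y, step=1e-4, lo=-0.2, hi=1.3):
    """Brute-force scan of the least-squares objective on a (C_w, C_l) grid."""
    cw = np.arange(lo, hi, step)
    cl = np.arange(lo, hi, step)
    best = (np.inf, None, None)
    # coarse-to-exhaustive in two passes to keep the scan tractable
    for cwv in cw[::50]:
        r = y[:, None] - np.outer(E[:, 0], np.full(cl.size, cwv)) - np.outer(E[:, 1], cl)
        sse = (r**2).sum(axis=0)
        k = sse.argmin()
        if sse[k] < best[0]:
            best = (sse[k], cwv, cl[k])
    cw_fine = np.arange(best[1] - 0.006, best[1] + 0.006, step)
    for cwv in cw_fine:
        r = y[:, None] - np.outer(E[:, 0], np.full(cl.size, cwv)) - np.outer(E[:, 1], cl)
        sse = (r**2).sum(axis=0)
        k = sse.argmin()
        if sse[k] < best[0]:
            best = (sse[k], cwv, cl[k])
    return best[1], best[2]


class TestUnmix:
    def test_exact_linear_combination_recovered_to_machine_precision(
        self, extinction
    ):
        maps = property_maps(synthesize(extinction, 0.70, 0.10))
        cm = unmix(maps, extinction)
        assert cm.C_water[0, 0] == pytest.approx(0.70, abs=1e-12)
        assert cm.C_lipid[0, 0] == pytest.approx(0.10, abs=1e-12)
        assert cm.residual[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_water_column(self, extinction):
        maps = property_maps(
            {wl: extinction.eps_at(wl)[0] for wl in extinction.wavelengths}
        )
        cm = unmix(maps, extinction)
        assert cm.C_water[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert cm.C_lipid[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_matches_grid_search_oracle(self, extinction):
        rng = np.random.default_rng(7)
        E = extinction.design_matrix(extinction.wavelengths)
        truth = np.array([0.85, 0.15])
        y = E @ truth + 0.002 * rng.standard_normal(3)
        maps = property_maps(dict(zip(extinction.wavelengths, y)))
        cm = unmix(maps, extinction)
        cw_o, cl_o = grid_search_oracle(E, y)
        assert cm.C_water[0, 0] == pytest.approx(cw_o, abs=1e-4)
        assert cm.C_lipid[0, 0] == pytest.approx(cl_o, abs=1e-4)

    def test_linearity_in_absorption(self, extinction):
        base = synthesize(extinction, 0.6, 0.2)
        cm1 = unmix(property_maps(base), extinction)
        cm2 = unmix(
            property_maps({wl: 2.5 * v for wl, v in base.items()}), extinction
        )
        assert cm2.C_water[0, 0] == pytest.approx(2.5 * cm1.C_water[0, 0])
        assert cm2.C_lipid[0, 0] == pytest.approx(2.5 * cm1.C_lipid[0, 0])

    def test_water_lipid_only_scenes_sum_to_one(self, extinction):
        rng = np.random.default_rng(8)
        C_w = rng.uniform(0.3, 0.95, (4, 4))
        C_l = 1.0 - C_w
        mu_a = {
            wl: C_w * extinction.eps_at(wl)[0] + C_l * extinction.eps_at(wl)[1]
            for wl in extinction.wavelengths
        }
        cm = unmix(property_maps(mu_a), extinction)
        total = cm.C_water + cm.C_lipid
        assert np.all((total > 0.98) & (total < 1.02))

    def test_negative_solutions_flagged_not_clipped(self, extinction):
        # an in-span combination with a negative lipid weight stays negative
        maps = property_maps(synthesize(extinction, 1.0, -0.5))
        cm = unmix(maps, extinction)
        assert cm.negativity_mask[0, 0]
        assert cm.C_lipid[0, 0] == pytest.approx(-0.5, abs=1e-10)

    def test_invalid_inputs_propagate_to_mask(self, extinction):
        mu_a = synthesize(extinction, 0.7, 0.1)
        shape = (1, 3)
        valid = np.array([[True, False, True]])
        maps = property_maps(
            {wl: np.full(shape, v) for wl, v in mu_a.items()}, valid=valid
        )
        cm = unmix(maps, extinction)
        assert not cm.valid_mask[0, 1]
        assert np.isnan(cm.C_water[0, 1])
        assert cm.valid_mask[0, 0] and cm.valid_mask[0, 2]

    def test_fewer_than_two_wavelengths_rejected(self, extinction):
        maps = property_maps({970.0: 0.05})
        with pytest.raises(ValueError):
            unmix(maps, extinction)


class TestPercent:
    def test_volume_fractions_scale_to_percent(self, extinction):
        maps = property_maps(synthesize(extinction, 0.90, 0.10))
        w, l = to_percent(unmix(maps, extinction))
        assert w[0, 0] == pytest.approx(90.0)
        assert l[0, 0] == pytest.approx(10.0)

    def test_dilution_ground_truth_series(self, extinction):
        for C_l, expected in zip(
            (0.05, 0.10, 0.15, 0.20), (95.0, 90.0, 85.0, 80.0)
        ):
            maps = property_maps(synthesize(extinction, 1.0 - C_l, C_l))
            w, _ = to_percent(unmix(maps, extinction))
            assert w[0, 0] == pytest.approx(expected, abs=1e-9)


class TestExtinctionTable:
    def test_packaged_table_well_conditioned(self, extinction):
        assert np.isfinite(extinction.condition_number())
        assert set(extinction.wavelengths) >= {970.0, 1050.0, 1200.0}

    def test_duplicate_wavelengths_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionTable(
                wavelengths=[970.0, 970.0],
                eps_water=[0.05, 0.05],
                eps_lipid=[0.005, 0.005],
            )

    def test_nonpositive_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionTable(
                wavelengths=[970.0, 1050.0],
                eps_water=[0.05, -0.01],
                eps_lipid=[0.005, 0.004],
            )
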