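"""Synthetic scenes, forward renderer, and scenario generators."""

import numpy as np
import pytest

from swirsfdi import (
    AcquisitionModel,
    Scene,
    TimeSeriesSpec,
    calibrate_reflectance,
    demodulate_ac,
    demodulate_dc,
    intralipid_phantom_spec,
    make_desiccation_series,
    make_dilution_series,
    make_exercise_series,
    make_skin_scene,
    predict_phantom_reflectance,
    render_raw,
    scene_optical_properties,
)

WAVELENGTHS = [970.0, 1050.0, 1200.0]


def flat_scene(C_w=0.9, C_l=0.1, mus=1.2, shape=(8, 8), b=1.3):
    return Scene(
        pixel_pitch=0.5,
        C_water_map=np.full(shape, C_w),
        C_lipid_map=np.full(shape, C_l),
        scatter_amplitude_map=np.full(shape, mus),
        scatter_power=b,
        reference_wavelength=970.0,
    )


class TestSceneOpticalProperties:
    def test_pure_water_pixel_reproduces_water_extinction(self, extinction):
        scene = flat_scene(C_w=1.0, C_l=0.0)
        for wl in WAVELENGTHS:
            props = scene_optical_properties(scene, extinction, wl)
            assert props.mu_a[0, 0] == pytest.approx(extinction.eps_at(wl)[0])

    def test_linear_combination_exact(self, extinction):
        scene = flat_scene(C_w=0.9, C_l=0.1)
        eps_w, eps_l = extinction.eps_at(1200.0)
        props = scene_optical_properties(scene, extinction, 1200.0)
        assert props.mu_a[0, 0] == pytest.approx(0.9 * eps_w + 0.1 * eps_l)

    def test_zero_scatter_power_is_flat_across_wavelengths(self, extinction):
        scene = flat_scene(b=0.0)
        mus = [
            scene_optical_properties(scene, extinction, wl).mu_s_prime[0, 0]
            for wl in WAVELENGTHS
        ]
        assert mus[0] == mus[1] == mus[2]

    def test_missing_wavelength_rejected(self, extinction):
        with pytest.raises(KeyError):
            scene_optical_properties(flat_scene(), extinction, 1310.0)


class TestSceneValidation:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            flat_scene(C_w=1.2)

    def test_map_shapes_must_agree(self):
        with pytest.raises(ValueError):
            Scene(
                pixel_pitch=0.5,
                C_water_map=np.full((4, 4), 0.9),
                C_lipid_map=np.full((4, 5), 0.1),
                scatter_amplitude_map=np.full((4, 4), 1.0),
            )


class TestRenderer:
    def test_same_seed_renders_identical_frames(self, synthetic_lut, phantom):
        scene = flat_scene()
        model = AcquisitionModel(seed=3)
        kwargs = dict(
            lut=synthetic_lut,
            wavelengths=[970.0],
            fx_list=(0.0, 0.1),
            phantom_spec=phantom,
        )
        a = render_raw(scene, model, seed=3, **kwargs)
        b = render_raw(scene, model, seed=3, **kwargs)
        for key in a["sample"]:
            for tag in a["sample"][key].frames:
                assert np.array_equal(
                    a["sample"][key].frames[tag], b["sample"][key].frames[tag]
                )

    def test_illumination_nonuniformity_cancels_in_calibration(
        self, synthetic_lut, phantom
    ):
        """±30% illumination ripple leaves noiseless calibrated R flat."""
        shape = (8, 16)
        cols = np.linspace(0.7, 1.3, shape[1])
        model = AcquisitionModel(
            illumination_profile=np.tile(cols, (shape[0], 1)),
            read_sigma=0.0,
            shot_scale=0.0,
            ambient_offset=100.0,
            bit_depth=None,  # ideal sensor: no quantization ripple
            seed=1,
        )
        scene = flat_scene(shape=shape)
        raw = render_raw(
            scene, model, synthetic_lut, [970.0], (0.0, 0.1), phantom, seed=1
        )
        for fx, dm in ((0.0, demodulate_dc), (0.1, demodulate_ac)):
            r_pred = predict_phantom_reflectance(phantom, synthetic_lut, 970.0, fx)
            out = calibrate_reflectance(
                dm(raw["sample"][(970.0, fx)]),
                dm(raw["phantom"][(970.0, fx)]),
                r_pred,
            )
            vals = out.R[out.valid_mask]
            assert vals.max() - vals.min() < 1e-6 * vals.mean()

    def test_gamut_violation_rejected_with_pixel_list(
        self, synthetic_lut, phantom, extinction
    ):
        scene = flat_scene(mus=50.0)  # far outside the mu_s' grid
        with pytest.raises(ValueError, match="gamut"):
            render_raw(
                scene,
                AcquisitionModel(seed=0),
                synthetic_lut,
                [970.0],
                (0.0, 0.1),
                phantom,
                extinction,
            )

    def test_frames_are_quantized_within_bit_depth(self, synthetic_lut, phantom):
        raw = render_raw(
            flat_scene(),
            AcquisitionModel(seed=2),
            synthetic_lut,
            [970.0],
            (0.0, 0.1),
            phantom,
        )
        for stack in raw["sample"].values():
            for frame in stack.frames.values():
                assert frame.min() >= 0
                assert frame.max() <= 65535
                np.testing.assert_array_equal(frame, np.rint(frame))


class TestDilutionSeries:
    def test_paper_fractions_give_expected_water_contents(self):
        scenes = make_dilution_series([0.05, 0.10, 0.15, 0.20])
        waters = [s.C_water_map[0, 0] for s in scenes]
        np.testing.assert_allclose(waters, [0.95, 0.90, 0.85, 0.80])

    def test_single_fraction_gives_one_homogeneous_scene(self):
        (scene,) = make_dilution_series([0.10])
        assert np.unique(scene.C_water_map).size == 1

    def test_scatter_scales_proportionally_with_lipid(self):
        s10, s20 = make_dilution_series([0.10, 0.20])
        ratio = s20.scatter_amplitude_map[0, 0] / s10.scatter_amplitude_map[0, 0]
        assert ratio == pytest.approx(2.0)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_dilution_series([1.5])


class TestDesiccationSeries:
    def test_decoupled_limit_keeps_scattering_constant(self):
        spec = TimeSeriesSpec(n_timepoints=4, coupling_k=0.0)
        series = make_desiccation_series(spec, flat_scene())
        mus = [s.scatter_amplitude_map[0, 0] for s in series]
        water = [s.C_water_map[0, 0] for s in series]
        assert np.unique(mus).size == 1
        assert np.all(np.diff(water) < 0)

    def test_coupling_definition(self):
        """2% relative water loss with k = 2 gives a 4% mu_s' decrease."""
        spec = TimeSeriesSpec(
            n_timepoints=2, water_loss_per_step=0.02, coupling_k=2.0
        )
        base = flat_scene()
        series = make_desiccation_series(spec, base)
        rel_mus = series[1].scatter_amplitude_map[0, 0] / base.scatter_amplitude_map[0, 0]
        assert rel_mus == pytest.approx(0.96)

    def test_scattering_series_monotone_for_positive_coupling(self):
        spec = TimeSeriesSpec(n_timepoints=5, coupling_k=2.0)
        series = make_desiccation_series(spec, flat_scene())
        mus = [s.scatter_amplitude_map[0, 0] for s in series]
        assert np.all(np.diff(mus) < 0)

    def test_absolute_convention(self):
        spec = TimeSeriesSpec(
            n_timepoints=2,
            water_loss_per_step=0.05,
            convention="absolute",
            coupling_k=0.0,
        )
        base = flat_scene(C_w=0.80)
        series = make_desiccation_series(spec, base)
        assert series[1].C_water_map[0, 0] == pytest.approx(0.75)

    def test_schedule_below_zero_rejected(self):
        spec = TimeSeriesSpec(
            n_timepoints=3, water_loss_per_step=0.6, convention="absolute"
        )
        with pytest.raises(ValueError):
            make_desiccation_series(spec, flat_scene(C_w=0.8))


class TestExerciseSeries:
    def make_base(self):
        return make_skin_scene(
            shape=(16, 16), phantom_region=(0, 4, 0, 4), seed=5
        )

    def test_missing_phantom_region_rejected(self):
        spec = TimeSeriesSpec(n_timepoints=8, phantom_region="phantom")
        with pytest.raises(ValueError):
            make_exercise_series(spec, flat_scene())

    def test_phantom_region_never_changes(self):
        base = self.make_base()
        spec = TimeSeriesSpec(
            n_timepoints=10, n_baseline=4, phantom_region="phantom"
        )
        series = make_exercise_series(spec, base)
        mask = base.regions["phantom"]
        for s in series:
            np.testing.assert_array_equal(
                s.C_water_map[mask], base.C_water_map[mask]
            )
            np.testing.assert_array_equal(
                s.scatter_amplitude_map[mask], base.scatter_amplitude_map[mask]
            )

    def test_skin_scattering_steps_down_then_recovers(self):
        base = self.make_base()
        spec = TimeSeriesSpec(
            n_timepoints=12,
            n_baseline=4,
            phantom_region="phantom",
            exercise_drop=0.05,
            coupling_k=2.0,
            recovery_tau=4.0,
        )
        series = make_exercise_series(spec, base)
        skin = base.regions["skin"]
        mus = np.array([s.scatter_amplitude_map[skin].mean() for s in series])
        assert np.all(mus[4:] < mus[:4].mean())  # stepped down post-exercise
        assert np.all(np.diff(mus[4:]) > 0)  # exponential recovery toward baseline

    def test_zero_magnitude_step_is_null_scenario(self):
        base = self.make_base()
        spec = TimeSeriesSpec(
            n_timepoints=8, n_baseline=3, phantom_region="phantom", exercise_drop=0.0
        )
        series = make_exercise_series(spec, base)
        for s in series[1:]:
            np.testing.assert_array_equal(s.C_water_map, base.C_water_map)
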