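import dataclasses

import numpy as np
import pytest

import twodes as td
from twodes.core import C_CM_PER_FS
from twodes.exceptions import DomainError
from twodes.simulate import (
    BEAT_MODES_CM1,
    BeatMode,
    Gaussian2DFeature,
    KineticComponent,
    NoiseSpec,
    Preset,
    get_preset,
)


class TestMakeGrid:
    def test_experimental_time_span_gives_134_points(self):
        _, _, t = td.make_grid(13_800, 17_600, 96, 1000, 7.5)
        assert len(t) == 134
        assert t.values[0] == 0.0
        assert t.values[-1] == pytest.approx(997.5)

    def test_default_grid_step(self):
        exc, emi, _ = td.make_grid(13_800, 17_600, 96, 1000, 7.5)
        assert exc.step == pytest.approx(40.0)
        np.testing.assert_array_equal(exc.values, emi.values)

    def test_short_scan_collapses_to_t_zero(self):
        _, _, t = td.make_grid(13_800, 17_600, 8, 5.0, 7.5)
        np.testing.assert_array_equal(t.values, [0.0])


class TestRenderFeature:
    def test_peak_value_and_one_sigma_point(self, axes_96):
        exc, emi, _ = axes_96
        f = Gaussian2DFeature((15_400.0, 15_000.0), 200.0, 200.0, 0.0, 2.0)
        m = td.render_feature(f, exc, emi)
        i = exc.nearest_index(15_400.0)
        j = emi.nearest_index(15_000.0)
        assert m.amplitude[i, j] == pytest.approx(2.0, rel=1e-10)
        j_sig = emi.nearest_index(15_200.0)  # center + sigma on emission
        assert m.amplitude[i, j_sig] == pytest.approx(2.0 * np.exp(-0.5), rel=1e-10)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_grid_integral_matches_gaussian_normalization(self, axes_96, rho):
        exc, emi, _ = axes_96
        f = Gaussian2DFeature((15_700.0, 15_700.0), 250.0, 180.0, rho, 1.3)
        m = td.render_feature(f, exc, emi)
        integral = m.amplitude.sum() * exc.step * emi.step
        expected = 2 * np.pi * 250.0 * 180.0 * np.sqrt(1 - rho**2) * 1.3
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_positive_rho_elongates_along_diagonal(self, axes_96):
        exc, emi, _ = axes_96
        f = Gaussian2DFeature((15_700.0, 15_700.0), 200.0, 200.0, 0.9, 1.0)
        m = td.render_feature(f, exc, emi).amplitude
        i = exc.nearest_index(15_700.0)
        d = 5  # 200 cm^-1 displacement
        assert m[i + d, i + d] > 5 * m[i + d, i - d]


class TestKineticGeneration:
    def test_flat_das_gives_pure_exponential_everywhere(self):
        comp = KineticComponent(
            tau=100.0,
            features=(Gaussian2DFeature((15_000.0, 15_000.0), 1e7, 1e7, 0.0, 1.0),),
        )
        p = Preset("flat", (14_000, 16_000, 8, 300, 30), "kinetic",
                   components=(comp,), noise=NoiseSpec(0.0))
        ds = td.generate_kinetic(p)
        t = ds.time.values
        expected = np.broadcast_to(np.exp(-t / 100.0), ds.cube.shape)
        np.testing.assert_allclose(ds.cube, expected, rtol=1e-6)

    def test_reconstruction_identity_noiseless(self):
        p = get_preset("rt_kinetic", sigma_rel=0.0)
        p = dataclasses.replace(p, beats=())
        ds = td.generate_kinetic(p)
        exc, emi, t = ds.excitation, ds.emission, ds.time.values
        total = np.zeros_like(ds.cube)
        for comp in p.components:
            das = np.zeros((len(exc), len(emi)))
            for f in comp.features:
                das += td.render_feature(f, exc, emi).amplitude
            total += das[:, :, None] * np.exp(-t / comp.tau)[None, None, :]
        np.testing.assert_allclose(ds.cube, total, atol=1e-12)

    def test_generator_linearity_in_feature_amplitudes(self):
        def build(scale):
            comp = KineticComponent(
                tau=120.0,
                features=(
                    Gaussian2DFeature((15_000.0, 15_000.0), 200.0, 200.0, 0.4, 1.0 * scale),
                    Gaussian2DFeature((15_400.0, 14_800.0), 150.0, 150.0, 0.0, -0.5 * scale),
                ),
            )
            p = Preset("lin", (14_000, 16_000, 16, 300, 15), "kinetic",
                       components=(comp,), noise=NoiseSpec(0.0))
            return td.generate_kinetic(p)

        np.testing.assert_allclose(build(3.0).cube, 3.0 * build(1.0).cube, rtol=1e-12)


class TestLineshapeGeneration:
    def test_slice_correlation_follows_rho_of_t2(self):
        p = get_preset("rt_lineshape", sigma_rel=0.0)
        ds = td.generate_lineshape(p)
        ls = p.lineshape
        exc = ds.excitation.values - ls.center[0]
        emi = ds.emission.values - ls.center[1]
        for k in [0, 10, 20, 60, 133]:
            w = ds.cube[:, :, k]
            wsum = w.sum()
            m1 = (w * exc[:, None]).sum() / wsum
            m3 = (w * emi[None, :]).sum() / wsum
            c11 = (w * (exc[:, None] - m1) ** 2).sum() / wsum
            c33 = (w * (emi[None, :] - m3) ** 2).sum() / wsum
            c13 = (w * (exc[:, None] - m1) * (emi[None, :] - m3)).sum() / wsum
            rho_obs = c13 / np.sqrt(c11 * c33)
            assert rho_obs == pytest.approx(ls.rho(ds.time.values[k]), abs=0.01)

    def test_frozen_rho_keeps_shape_constant(self):
        ds = td.generate_lineshape(get_preset("k77_lineshape", sigma_rel=0.0))
        first = ds.cube[:, :, 0] / np.max(ds.cube[:, :, 0])
        last = ds.cube[:, :, -1] / np.max(ds.cube[:, :, -1])
        np.testing.assert_allclose(first, last, atol=1e-9)

    def test_amplitude_decays_with_tau_amp(self):
        # frozen-rho preset: the slice shape is constant, so the grid maximum
        # tracks exp(-t2/tau_amp) exactly
        p = get_preset("k77_lineshape", sigma_rel=0.0)
        ds = td.generate_lineshape(p)
        peaks = ds.cube.max(axis=(0, 1))
        t = ds.time.values
        np.testing.assert_allclose(
            peaks / peaks[0], np.exp(-t / p.lineshape.tau_amp), rtol=1e-9
        )


class TestBeats:
    def _base(self):
        comp = KineticComponent(
            tau=500.0,
            features=(Gaussian2DFeature((15_000.0, 15_000.0), 300.0, 300.0, 0.0, 1.0),),
        )
        p = Preset("b", (14_000, 16_000, 16, 990, 7.5), "kinetic",
                   components=(comp,), noise=NoiseSpec(0.0))
        return td.generate_kinetic(p)

    def test_zero_amplitude_is_identity(self):
        ds = self._base()
        mode = BeatMode(nu=770.0, amplitude=0.0, damping=600.0)
        np.testing.assert_array_equal(td.add_beats(ds, [mode]).cube, ds.cube)

    def test_oscillation_period_of_770_mode(self):
        ds = self._base()
        mode = BeatMode(nu=770.0, amplitude=0.1, damping=1e9)
        beat = td.add_beats(ds, [mode]).cube[0, 0, :] - ds.cube[0, 0, :]
        # first return to a maximum after one period 1/(c*770) ~ 43.3 fs
        period = 1.0 / (C_CM_PER_FS * 770.0)
        assert period == pytest.approx(43.3, abs=0.05)
        t = ds.time.values
        ref = np.cos(2 * np.pi * t / period)
        assert np.corrcoef(beat, ref)[0, 1] > 0.999

    def test_beat_only_residues_transform_to_single_peak(self):
        ds = self._base()
        mode = BeatMode(nu=770.0, amplitude=0.05, damping=600.0)
        noisy = td.add_beats(ds, [mode])
        beat_part = noisy.cube - ds.cube  # exact non-oscillating subtraction
        spec = np.abs(np.fft.rfft(beat_part[8, 8, :], n=4 * len(ds.time)))
        freqs = np.fft.rfftfreq(4 * len(ds.time), 7.5) / C_CM_PER_FS
        assert freqs[np.argmax(spec)] == pytest.approx(770.0, abs=freqs[1] / 2 + 5)

    def test_mode_above_nyquist_rejected(self):
        ds = self._base()
        with pytest.raises(DomainError):
            td.add_beats(ds, [BeatMode(nu=3000.0, amplitude=0.1, damping=600.0)])


class TestNoise:
    def test_zero_sigma_is_identity(self):
        ds = td.generate(get_preset("rt_lineshape", sigma_rel=0.0))
        out = td.add_noise(ds, NoiseSpec(0.0, 7))
        np.testing.assert_array_equal(out.cube, ds.cube)

    def test_same_seed_bit_identical(self):
        a = td.generate(get_preset("rt_kinetic", seed=99))
        b = td.generate(get_preset("rt_kinetic", seed=99))
        np.testing.assert_array_equal(a.cube, b.cube)

    def test_different_seed_differs(self):
        a = td.generate(get_preset("rt_kinetic", seed=99))
        b = td.generate(get_preset("rt_kinetic", seed=100))
        assert not np.array_equal(a.cube, b.cube)

    def test_noise_sd_matches_spec_level(self):
        clean = td.generate(get_preset("rt_kinetic", sigma_rel=0.0))
        noisy = td.add_noise(clean, NoiseSpec(0.01, 5))
        sd = np.std(noisy.cube - clean.cube)
        assert sd == pytest.approx(0.01 * clean.max_abs, rel=0.02)


class TestPresets:
    def test_preset_time_constants(self):
        assert get_preset("rt_kinetic").components[0].tau == 150.0
        assert get_preset("k77_kinetic").components[0].tau == 60.0
        assert get_preset("rt_lineshape").lineshape.tau_sd == 150.0

    def test_cold_lineshape_correlation_is_frozen(self):
        ls = get_preset("k77_lineshape").lineshape
        assert ls.rho0 == ls.rho_inf

    def test_cold_low_frequency_beats_quenched(self):
        p = get_preset("k77_kinetic")
        rt = get_preset("rt_kinetic")
        for b77, brt in zip(p.beats, rt.beats):
            if b77.nu < 700:
                assert b77.amplitude == pytest.approx(0.2 * brt.amplitude)
            else:
                assert b77.amplitude == brt.amplitude

    def test_unknown_name_lists_valid_presets(self):
        with pytest.raises(DomainError, match="rt_kinetic"):
            get_preset("nope")

    def test_nine_beat_modes(self):
        assert BEAT_MODES_CM1 == (200, 296, 380, 450, 530, 770, 926, 1120, 1260)

    def test_preset_dict_roundtrip(self):
        for name in ("rt_kinetic", "k77_lineshape"):
            p = get_preset(name)
            assert Preset.from_dict(p.to_dict()) == p
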