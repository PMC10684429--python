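import math

import numpy as np
import pytest

from goodph import synthetic as syn
from goodph.exceptions import ValidationError
from goodph.hard_model import eval_component, eval_mixture, fit_mixture
from goodph.ph_probe import (
    MOPSH,
    MOPS_MINUS,
    PENICILLIN_G,
    WATER,
    calibrate,
    pka_mops,
    ph_from_ratio,
    predict_ph,
    ratio_from_ph,
    zeta_ratio_of,
)
from goodph.spectra_io import RamanSpectrum

T35 = 308.15


class TestSpeciate:
    def test_equivalence_point(self):
        st = syn.speciate(0.05, pka_mops(T35), T35)
        assert st.c_mopsh == pytest.approx(0.025, abs=1e-12)
        assert st.c_mops_minus == pytest.approx(0.025, abs=1e-12)

    def test_decade_above_pka(self):
        st = syn.speciate(0.05, pka_mops(T35) + 1.0, T35)
        assert st.c_mops_minus == pytest.approx(0.05 * 10 / 11, rel=1e-10)
        assert st.c_mopsh == pytest.approx(0.05 / 11, rel=1e-10)

    def test_zero_total(self):
        st = syn.speciate(0.0, 7.0, T35)
        assert st.c_mopsh == 0.0 and st.c_mops_minus == 0.0

    def test_mass_conservation_invariant(self):
        for ph in np.linspace(5.5, 8.5, 13):
            st = syn.speciate(0.05, float(ph), T35)
            assert st.c_mopsh + st.c_mops_minus == pytest.approx(0.05, abs=1e-12)

    def test_negative_total(self):
        with pytest.raises(ValidationError):
            syn.speciate(-0.01, 7.0, T35)


class TestTitrate:
    def test_add_nothing(self):
        st = syn.speciate(0.05, 7.0, T35)
        out = syn.titrate(st, 0.0)
        assert out.true_ph == pytest.approx(st.true_ph, abs=1e-12)
        assert out.c_mopsh == pytest.approx(st.c_mopsh, abs=1e-15)

    def test_stoichiometric_hand_computation(self):
        # 30 mL of 25/25 mM; 1.5e-4 mol NaOH -> 30/20 mM, dpH = log10(1.5)
        st = syn.speciate(0.05, pka_mops(T35), T35)
        assert st.volume == pytest.approx(0.030)
        out = syn.titrate(st, 1.5e-4)
        assert out.c_mops_minus == pytest.approx(0.030, abs=1e-12)
        assert out.c_mopsh == pytest.approx(0.020, abs=1e-12)
        assert out.true_ph - st.true_ph == pytest.approx(
            math.log10(30 / 20), abs=1e-10
        )

    def test_dilution(self):
        st = syn.speciate(0.05, 7.0, T35)
        out = syn.titrate(st, 0.0, added_volume=0.030)
        assert out.total_mops == pytest.approx(0.025, abs=1e-12)
        assert out.true_ph == pytest.approx(st.true_ph, abs=1e-12)

    def test_over_titration(self):
        st = syn.speciate(0.05, 7.0, T35)
        with pytest.raises(ValidationError):
            syn.titrate(st, st.c_mopsh * st.volume * 1.01)
        with pytest.raises(ValidationError):
            syn.titrate(st, -st.c_mops_minus * st.volume * 1.01)

    def test_agrees_with_charge_balance(self):
        st = syn.speciate(0.05, 6.0, T35)
        for target in np.linspace(6.1, 8.0, 20):
            r = ratio_from_ph(float(target), T35)
            mol = (st.total_mops * r / (1 + r) - st.c_mops_minus) * st.volume
            st = syn.titrate(st, mol)
            oracle = syn.charge_balance_ph(st.total_mops, st.c_na, st.c_cl, T35)
            assert abs(st.true_ph - oracle) <= 0.002


class TestChargeBalance:
    def test_pure_water(self):
        assert syn.charge_balance_ph(0, 0, 0, T35) == pytest.approx(7.00, abs=1e-5)

    def test_half_neutralized_buffer(self):
        got = syn.charge_balance_ph(0.05, 0.025, 0, T35)
        assert got == pytest.approx(pka_mops(T35), abs=0.01)

    def test_strong_base_only(self):
        got = syn.charge_balance_ph(0, 0.05, 0, T35)
        assert got == pytest.approx(14 + math.log10(0.05), abs=1e-4)  # 12.70

    def test_negative_concentration(self):
        with pytest.raises(ValidationError):
            syn.charge_balance_ph(-0.01, 0, 0, T35)


class TestAddSalt:
    def test_add_nothing(self):
        st = syn.speciate(0.05, 7.0, T35)
        out = syn.add_salt(st, 0.0)
        assert out.ionic_strength == pytest.approx(st.ionic_strength, abs=1e-15)

    def test_hand_sum(self):
        # 25/25 mM MOPS + 100 mM NaCl -> I = 0.125 M
        st = syn.speciate(0.05, pka_mops(T35), T35)
        out = syn.add_salt(st, 0.100 * st.volume)
        assert out.ionic_strength == pytest.approx(0.125, abs=1e-4)

    def test_ph_unchanged(self):
        st = syn.speciate(0.05, 7.0, T35)
        out = syn.add_salt(st, 0.5 * st.volume)
        assert out.true_ph == st.true_ph

    def test_paper_design_reaches_1100_mM(self):
        # 12 small + 19 five-fold additions -> ionic strength ~1.1 mol/L
        res = syn.simulate_salt_series(7.0, syn.NoiseConfig(0.0, 0.0, 0.0, seed=0))
        assert len(res.series) == 32  # initial point + 31 additions
        final_i = res.truth.ionic_strength.iloc[-1]
        assert 0.9 <= final_i <= 1.3


class TestSynthesizeSpectrum:
    def test_forward_identity_zero_noise(self, tables, composite, quiet_noise):
        st = syn.speciate(0.05, 7.0, T35)
        spec = syn.synthesize_spectrum(st, tables, noise=quiet_noise)
        sigma = syn.DEFAULT_CROSS_SECTIONS
        weights = {
            WATER: sigma[WATER] * syn.WATER_CONCENTRATION,
            MOPSH: sigma[MOPSH] * st.c_mopsh,
            MOPS_MINUS: sigma[MOPS_MINUS] * st.c_mops_minus,
        }
        # water perturbation at 35 degC: position shift 0, width ~ I-dependent
        wscale = 1.0 + syn.WATER_WIDTH_PER_MOLAR * st.ionic_strength
        adjustments = {
            (WATER, i, "fwhm"): tables[WATER].peaks[i].fwhm * wscale
            for i in range(len(tables[WATER].peaks))
        }
        expected = eval_mixture(
            composite, weights, syn.DEFAULT_BASELINE, adjustments, spec.wavenumber
        )
        np.testing.assert_allclose(spec.intensity, expected, rtol=1e-12)

    def test_determinism(self, tables):
        st = syn.speciate(0.05, 7.0, T35)
        noise = syn.NoiseConfig(seed=11)
        a = syn.synthesize_spectrum(st, tables, noise=noise)
        b = syn.synthesize_spectrum(st, tables, noise=noise)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_missing_table(self, tables, quiet_noise):
        st = syn.speciate(0.05, 7.0, T35)
        partial = {k: v for k, v in tables.items() if k != MOPSH}
        with pytest.raises(ValidationError):
            syn.synthesize_spectrum(st, partial, noise=quiet_noise)

    def test_band_trends_match_titration(self, tables, quiet_noise):
        """Rising pH: 2765-2938 integral strictly up, 2990-3030 strictly down."""
        up, down = [], []
        for ph in np.linspace(6.0, 8.0, 9):
            st = syn.speciate(0.05, float(ph), T35)
            spec = syn.synthesize_spectrum(st, tables, noise=quiet_noise)
            nu, y = spec.wavenumber, spec.intensity
            up.append(y[(nu >= 2765) & (nu <= 2938)].sum())
            down.append(y[(nu >= 2990) & (nu <= 3030)].sum())
        assert all(a < b for a, b in zip(up, up[1:]))
        assert all(a > b for a, b in zip(down, down[1:]))

    def test_increase_band_2718_2738(self, tables, quiet_noise):
        vals = []
        for ph in (6.0, 7.0, 8.0):
            st = syn.speciate(0.05, ph, T35)
            spec = syn.synthesize_spectrum(st, tables, noise=quiet_noise)
            nu, y = spec.wavenumber, spec.intensity
            vals.append(y[(nu >= 2718) & (nu <= 2738)].sum())
        assert vals[0] < vals[1] < vals[2]


class TestFixtureModels:
    def test_band_membership(self):
        tables = syn.make_fixture_models(3)
        minus_pos = [p.position for p in tables[MOPS_MINUS].peaks]
        assert any(2718 <= p <= 2738 for p in minus_pos)
        assert any(2950 <= p <= 2965 for p in minus_pos)
        h_pos = [p.position for p in tables[MOPSH].peaks]
        assert any(2990 <= p <= 3030 for p in h_pos)

    def test_deterministic_under_seed(self):
        a = syn.make_fixture_models(5)
        b = syn.make_fixture_models(5)
        for name in a:
            assert a[name].peaks == b[name].peaks

    def test_different_seeds_differ(self):
        a = syn.make_fixture_models(1)
        b = syn.make_fixture_models(2)
        assert a[MOPSH].peaks != b[MOPSH].peaks

    def test_water_free_parameters(self):
        tables = syn.make_fixture_models(0)
        free = {(fp.peak, fp.parameter) for fp in tables[WATER].free_parameters}
        assert free == {(0, "position"), (0, "fwhm"), (1, "position"), (1, "fwhm")}

    def test_water_tails_reach_fit_window(self):
        tables = syn.make_fixture_models(0)
        nu = np.arange(2700.0, 3101.0, 1.0)
        assert eval_component(tables[WATER], nu).max() > 0.01


class TestSimulateTitrationSeries:
    def test_default_plan_60_points(self, quiet_noise):
        res = syn.simulate_titration_series(syn.TitrationPlan(), quiet_noise)
        assert len(res.series) == 60
        assert len(res.truth) == 60
        assert set(res.truth.run.unique()) == {0, 1, 2}

    def test_reference_noise_applied(self):
        noise = syn.NoiseConfig(0.0, 0.05, 0.0, seed=3)
        res = syn.simulate_titration_series(syn.TitrationPlan(runs=1), noise)
        diff = res.truth.reference_ph - res.truth.true_ph
        assert diff.abs().max() > 0
        assert diff.abs().max() < 0.5

    def test_zero_noise_end_to_end_recovery(self, tables, composite, quiet_noise):
        plan = syn.TitrationPlan(runs=1, points_per_run=6)
        res = syn.simulate_titration_series(plan, quiet_noise, peak_tables=tables)
        fits = [fit_mixture(composite, s) for s in res.series]
        pts = [
            (f, r.reference_ph, r.temperature)
            for f, (_, r) in zip(fits, res.truth.iterrows())
        ]
        cal = calibrate(pts, composite=composite)
        assert cal.k == pytest.approx(1.0, abs=1e-6)
        for f, true_ph in zip(fits, res.truth.true_ph):
            got = ph_from_ratio(cal.k * zeta_ratio_of(f), T35)
            assert got == pytest.approx(true_ph, abs=1e-3)

    def test_laser_power_invariance(self, tables, composite):
        """Any laser-power CV leaves predictions untouched at zero spectral noise."""
        from goodph.ph_probe import CalibrationModel

        cal = CalibrationModel(k=1.0, composite=composite)
        noise = syn.NoiseConfig(0.0, 0.0, 0.9, seed=21)
        st = syn.speciate(0.05, 7.2, T35)
        rng = np.random.default_rng(noise.seed)
        preds = []
        for _ in range(4):
            spec = syn.synthesize_spectrum(st, tables, noise=noise, rng=rng)
            preds.append(predict_ph(spec, cal, T35).ph)
        assert max(preds) - min(preds) <= 1e-6


class TestEnzymeReaction:
    KIN = syn.KineticsConfig(vmax=1e-5, km=1e-3, s0=0.02, duration=4000.0, dt=1.0)

    @pytest.fixture()
    def initial(self):
        return syn.speciate(0.05, 8.2, 298.15)

    def test_monotone_ph_and_substrate(self, initial, quiet_noise):
        res = syn.simulate_enzyme_reaction(self.KIN, initial, quiet_noise, n_spectra=10)
        ph = res.truth.true_ph.to_numpy()
        s = res.truth.substrate.to_numpy()
        assert np.all(np.diff(ph) <= 1e-12)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all(s >= 0)
        assert not res.truncated

    def test_closed_form_endpoint(self, initial, quiet_noise):
        # after full conversion, x(inf) = s0 protons have converted MOPS- to MOPSH
        res = syn.simulate_enzyme_reaction(self.KIN, initial, quiet_noise, n_spectra=5)
        expected = pka_mops(298.15) + math.log10(
            (initial.c_mops_minus - self.KIN.s0) / (initial.c_mopsh + self.KIN.s0)
        )
        assert res.truth.true_ph.iloc[-1] == pytest.approx(expected, abs=1e-6)

    def test_near_zero_rate_constant_ph(self, initial, quiet_noise):
        kin = syn.KineticsConfig(vmax=1e-15, km=1e-3, s0=0.02, duration=100.0, dt=1.0)
        res = syn.simulate_enzyme_reaction(kin, initial, quiet_noise, n_spectra=5)
        ph = res.truth.true_ph.to_numpy()
        assert ph.max() - ph.min() < 1e-9

    def test_buffer_exhaustion_truncates(self, quiet_noise):
        initial = syn.speciate(0.05, 6.5, 298.15)  # little MOPS- available
        kin = syn.KineticsConfig(vmax=1e-4, km=1e-3, s0=0.04, duration=2000.0, dt=1.0)
        res = syn.simulate_enzyme_reaction(kin, initial, quiet_noise, n_spectra=5)
        assert res.truncated
        assert res.truth.c_mops_minus.min() > 0

    def test_mass_conservation_along_trajectory(self, initial, quiet_noise):
        res = syn.simulate_enzyme_reaction(self.KIN, initial, quiet_noise, n_spectra=8)
        total = res.truth.c_mopsh + res.truth.c_mops_minus
        np.testing.assert_allclose(total, initial.total_mops, atol=1e-12)

    def test_penicillin_component_scales_with_substrate(self, initial, tables):
        res = syn.simulate_enzyme_reaction(
            self.KIN, initial, syn.NoiseConfig(0.0, 0.0, 0.0, seed=0),
            n_spectra=6, peak_tables=tables,
        )
        comp = syn.make_composite(tables, include_penicillin=True)
        weights = []
        for spec in res.series:
            fit = fit_mixture(comp, spec)
            weights.append(fit.weights[PENICILLIN_G])
        expected = syn.DEFAULT_CROSS_SECTIONS[PENICILLIN_G] * res.truth.substrate
        np.testing.assert_allclose(weights, expected, atol=1e-4)
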