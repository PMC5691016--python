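"""Ratio curves, shift sensitivity, and the four calibration recoveries."""
import numpy as np
import pytest

from protondosim import Profile, ReadoutModel
from protondosim.compare import (
    agreement_table,
    decay_fit,
    dose_rate_uniformity,
    linearity_fit,
    orientation_difference,
    ratio_curve,
    shift_sensitivity,
    simulate_decay_experiment,
    simulate_dose_rate_experiment,
    simulate_linearity_experiment,
    simulate_orientation_experiment,
)
from protondosim.detectors import scan_profile
from protondosim.errors import ProtonDosimError
from protondosim.metrics import _distal_crossing


class TestRatioCurve:
    def test_identity_is_unity(self, sobp127_mod30):
        _, prof = sobp127_mod30
        res = ratio_curve(prof, prof)
        np.testing.assert_allclose(res.ratio, 1.0, atol=1e-12)
        assert res.distal_ratio_90 == pytest.approx(1.0, abs=1e-9)
        assert res.distal_ratio_95 == pytest.approx(1.0, abs=1e-9)
        assert res.d50_difference == 0.0

    def test_clip_at_25_percent_distal(self, sobp127_mod30):
        _, prof = sobp127_mod30
        res = ratio_curve(prof, prof)
        dense = Profile(
            np.arange(0.0, 130.0, 0.001),
            np.interp(np.arange(0.0, 130.0, 0.001), prof.positions, prof.dose),
            axis="depth",
        )
        assert res.clip_depth == pytest.approx(_distal_crossing(dense, 0.25), abs=0.01)
        assert res.depth.max() <= res.clip_depth + 1e-9

    def test_misalignment_raises_distal_ratio(self, sobp127_mod30):
        """A deeper-ranging diode curve produces the distal ratio rise."""
        _, ref = sobp127_mod30
        shifted = Profile(ref.positions + 0.9, ref.dose, axis="depth")
        res = ratio_curve(shifted, ref)
        assert res.distal_ratio_90 > 1.04
        assert res.distal_ratio_95 > 1.01
        assert res.d50_difference == pytest.approx(0.9, abs=1e-6)

    def test_nonoverlapping_supports_rejected(self):
        a = Profile(np.linspace(0, 10, 11), np.linspace(1, 0.5, 11))
        b = Profile(np.linspace(20, 30, 11), np.linspace(1, 0.5, 11))
        with pytest.raises(ProtonDosimError):
            ratio_curve(a, b)


class TestShiftSensitivity:
    def test_zero_shift_zero_change(self, pristine127):
        assert shift_sensitivity(pristine127, 0.0) == 0.0

    def test_study_shifts_land_in_10_30_band(self, pristine127):
        """0.4 and 0.9 mm misalignments move the mid-falloff ratio 10-30%."""
        for s in (0.4, 0.9):
            change = shift_sensitivity(pristine127, s)
            assert 10.0 <= change <= 30.0

    def test_small_shift_linearity(self, pristine127):
        for s in (0.025, 0.05, 0.1):
            c1 = shift_sensitivity(pristine127, s)
            c2 = shift_sensitivity(pristine127, 2 * s)
            assert c2 == pytest.approx(2 * c1, rel=0.05)

    def test_degenerate_falloff_rejected(self):
        z = np.linspace(0, 100, 1001)
        d = np.where(z <= 50, 1.0, 0.0)
        with pytest.raises(ProtonDosimError):
            shift_sensitivity(Profile(z, d, axis="depth"), 0.5)


class TestLinearity:
    def test_exact_affine_recovery(self):
        doses = np.array([1.0, 5.0, 12.0, 20.0])
        fit = linearity_fit(doses, 100.0 + 2500.0 * doses)
        assert fit.slope == pytest.approx(2500.0)
        assert fit.intercept == pytest.approx(100.0)
        assert fit.r_value == pytest.approx(1.0)

    def test_intercept_recovery_single_run(self, diode):
        model = ReadoutModel(offset=100.0, noise_sd=0.005, decay_rate=0.0)
        rng = np.random.default_rng(17)
        d, q = simulate_linearity_experiment(diode, model, rng)
        fit = linearity_fit(d, q)
        assert fit.intercept == pytest.approx(100.0, abs=3 * fit.intercept_stderr)

    def test_intercept_unbiased_over_seeds(self, diode):
        model = ReadoutModel(offset=100.0, noise_sd=0.005, decay_rate=0.0)
        ests = []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            d, q = simulate_linearity_experiment(diode, model, rng)
            ests.append(linearity_fit(d, q).intercept)
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(100.0, abs=2 * sem)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ProtonDosimError):
            linearity_fit(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_unit_rescaling_equivariance(self):
        doses = np.linspace(0.6, 23.0, 9)
        q_pc = 100.0 + 2500.0 * doses
        fit_pc = linearity_fit(doses, q_pc)
        fit_nc = linearity_fit(doses, q_pc / 1000.0)
        assert fit_nc.slope == pytest.approx(fit_pc.slope / 1000.0)
        assert fit_nc.r_value == pytest.approx(fit_pc.r_value)


class TestDecay:
    def test_no_decay_gives_zero_rate(self, diode):
        model = ReadoutModel(decay_rate=0.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        acc, resp = simulate_decay_experiment(diode, model, rng)
        rate, _ = decay_fit(acc, resp)
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_damage_protocol_recovers_1pct_per_100gy(self, diode):
        model = ReadoutModel(decay_rate=1e-4, noise_sd=0.005)
        rates = []
        for s in range(100):
            rng = np.random.default_rng(5000 + s)
            acc, resp = simulate_decay_experiment(diode, model, rng)
            rates.append(decay_fit(acc, resp)[0])
        assert np.mean(rates) == pytest.approx(1.0, abs=0.3)

    @pytest.mark.parametrize("rate_pct", [0.5, 1.0, 2.0])
    def test_recovery_across_injected_rates(self, diode, rate_pct):
        model = ReadoutModel(decay_rate=rate_pct * 1e-4, noise_sd=0.005)
        ests = []
        for s in range(60):
            rng = np.random.default_rng(999 + s)
            acc, resp = simulate_decay_experiment(diode, model, rng)
            ests.append(decay_fit(acc, resp)[0])
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(rate_pct, abs=2 * sem + 0.02)

    def test_non_monotone_accumulation_rejected(self):
        with pytest.raises(ProtonDosimError):
            decay_fit(np.array([0.0, 56.0, 28.0]), np.array([1.0, 0.99, 0.98]))


class TestOrientation:
    def test_identical_samples_zero_difference(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        est, _ = orientation_difference(x, x)
        assert est == 0.0

    def test_recovers_sub_percent_difference(self, diode, diode_edge):
        model = ReadoutModel(orientation_factor=0.994, noise_sd=0.002)
        ests, covered = [], 0
        truth = 0.6
        for s in range(100):
            rng = np.random.default_rng(300 + s)
            ax, eo = simulate_orientation_experiment(diode, diode_edge, model, rng)
            est, ci = orientation_difference(ax, eo)
            ests.append(est)
            if ci[0] <= truth <= ci[1]:
                covered += 1
        assert np.mean(ests) <= 1.0
        assert covered >= 90  # 95% CI covers the injected truth

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ProtonDosimError):
            orientation_difference(np.array([1.0]), np.array([1.0, 1.0]))


class TestDoseRate:
    def test_constant_response_zero_slope(self):
        rates = np.linspace(0.7, 2.3, 14)
        fit, verdict = dose_rate_uniformity(rates, np.ones(14), seed=0)
        assert fit.slope == pytest.approx(0.0)
        assert verdict == "uniform"

    def test_uniform_verdict_rate(self, diode):
        model = ReadoutModel(noise_sd=0.005)
        uniform = 0
        n = 60
        for s in range(n):
            rng = np.random.default_rng(700 + s)
            rates, resp = simulate_dose_rate_experiment(diode, model, rng)
            _, verdict = dose_rate_uniformity(rates, resp, seed=s)
            uniform += verdict == "uniform"
        assert uniform / n >= 0.90

    def test_injected_trend_detected(self, diode):
        model = ReadoutModel(noise_sd=0.005)
        detected = 0
        n = 40
        for s in range(n):
            rng = np.random.default_rng(900 + s)
            rates, resp = simulate_dose_rate_experiment(diode, model, rng)
            resp = resp * (1.0 + 0.02 * (rates - rates.mean()))  # 2% per cGy/s
            _, verdict = dose_rate_uniformity(rates, resp, seed=s)
            detected += verdict == "trend"
        assert detected / n >= 0.95


class TestAgreementTable:
    def test_identical_sets_all_zero(self, pristine127):
        sets = {"b1": {"diode": pristine127, "markus": pristine127}}
        tab = agreement_table(sets, pairs=[("diode", "markus")])
        assert tab["diode-markus_mm"].abs().max() == pytest.approx(0.0)

    def test_window_wet_offset_appears(self, spec127, diode, markus):
        kw = dict(axis="depth", start=40.0, stop=120.0, step=0.25,
                  window_correction=False)
        sets = {
            "127-Mod0": {
                "diode": scan_profile(spec127, diode, **kw),
                "markus": scan_profile(spec127, markus, **kw),
            }
        }
        tab = agreement_table(sets, pairs=[("diode", "markus")])
        assert tab["diode-markus_mm"][0] == pytest.approx(-(1.33 - 1.06), abs=0.25)

    def test_full_preset_list_yields_nine_records(self):
        from protondosim.beam import pristine_bragg, sobp_synthesize
        from protondosim.presets import BEAM_PRESETS

        sets = {}
        for name, spec in BEAM_PRESETS.items():
            z = np.arange(0.0, spec.pristine_d50 + 6 * spec.falloff_8020, 0.25)
            if spec.modulation > 0:
                _, p = sobp_synthesize(spec, z_grid=z)
            else:
                p = pristine_bragg(spec, z)
            sets[name] = {"diode": p, "simulation": p}
        tab = agreement_table(sets, pairs=[("diode", "simulation")])
        assert len(tab) == 9
        assert set(tab.beam) == set(BEAM_PRESETS)

    def test_orphan_modalities_listed(self, pristine127):
        sets = {
            "b1": {"diode": pristine127, "markus": pristine127},
            "b2": {"diode": pristine127},
        }
        with pytest.raises(ProtonDosimError, match="b2"):
            agreement_table(sets)
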