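"""Phantom bench math: mixtures, conductivity, QC, noise, trends."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from earval.core import Recording
from earval.phantom import (
    conductivity,
    impedance_qc,
    integrity_trend,
    mixture_agar,
    mixture_bg,
    mixture_cf,
    noise_floor,
    simulated_signal_snr,
)
from earval.synthetic import generate_phantom_recording, square_wave


class TestMixtures:
    def test_agar_700g_water_rounds_up_to_30_and_4(self):
        recipe = mixture_agar(700.0)
        assert recipe.component_masses["agar"] == 30.0
        assert recipe.component_masses["salt"] == 4.0

    def test_agar_exact_fractions_at_191g(self):
        recipe = mixture_agar(191.0, rounding="none")
        assert recipe.component_masses["agar"] == pytest.approx(8.0)
        assert recipe.component_masses["salt"] == pytest.approx(1.0)

    def test_agar_zero_water(self):
        recipe = mixture_agar(0.0)
        assert recipe.component_masses == {"agar": 0.0, "salt": 0.0}

    def test_bg_closed_form(self):
        recipe = mixture_bg(770.0)
        assert recipe.component_masses["gelatin"] == pytest.approx(150.0)
        assert recipe.component_masses["salt"] == pytest.approx(80.0)
        recipe = mixture_bg(700.0)
        assert recipe.component_masses["gelatin"] == pytest.approx(
            136.36, abs=0.01)
        assert recipe.component_masses["salt"] == pytest.approx(72.73,
                                                                abs=0.01)

    def test_cf_700ml_at_1pct_gives_8g(self):
        recipe = mixture_cf(700.0)
        assert recipe.component_masses["carbon_fiber"] == 8.0
        assert recipe.component_masses["silicone"] == pytest.approx(777.0)

    def test_cf_half_percent_closed_form(self):
        # CF = S/199 at 0.5%
        recipe = mixture_cf(199.0 / 1.11, cf_pct=0.5, rounding="none")
        assert recipe.component_masses["carbon_fiber"] == pytest.approx(1.0)

    def test_cf_zero_percent(self):
        recipe = mixture_cf(700.0, cf_pct=0.0)
        assert recipe.component_masses["carbon_fiber"] == 0.0

    def test_cf_above_one_percent_warns(self):
        with pytest.warns(UserWarning, match="too dense"):
            mixture_cf(700.0, cf_pct=1.5)

    def test_infeasible_percentages_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            mixture_agar(700.0, agar_pct=60.0, salt_pct=50.0)
        with pytest.raises(ValueError):
            mixture_agar(-1.0)

    @given(w=st.floats(1.0, 5000.0),
           p1=st.floats(0.5, 40.0), p2=st.floats(0.1, 20.0))
    def test_unrounded_recipes_reproduce_target_fractions(self, w, p1, p2):
        recipe = mixture_agar(w, agar_pct=p1, salt_pct=p2, rounding="none")
        masses = recipe.component_masses
        total = w + sum(masses.values())
        assert masses["agar"] / total == pytest.approx(p1 / 100.0, rel=1e-9)
        assert masses["salt"] / total == pytest.approx(p2 / 100.0, rel=1e-9)


class TestConductivity:
    def test_strip_geometry_value(self):
        m = conductivity(5000.0)
        assert m.conductivity == pytest.approx(0.3)
        assert m.resistivity == pytest.approx(1.0 / 0.3)

    def test_doubling_resistance_halves_conductivity(self):
        assert conductivity(10000.0).conductivity == pytest.approx(
            conductivity(5000.0).conductivity / 2.0)

    def test_inversion_round_trip(self):
        # sigma = 0.309 S/m on the strip implies R ~ 4854 Ohm
        sigma = 0.309
        r = 0.03 / (sigma * 2e-5)
        assert r == pytest.approx(4854.4, abs=0.1)
        assert conductivity(r).conductivity == pytest.approx(sigma, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            conductivity(0.0)
        with pytest.raises(ValueError):
            conductivity(100.0, length_m=-1.0)


class TestImpedanceQc:
    def test_class_anchors(self):
        table = impedance_qc({"a": 5.0, "b": 15.0, "c": 30.0, "d": 80.0})
        classes = dict(zip(table.electrode, table.qc_class))
        assert classes == {"a": "good", "b": "acceptable", "c": "poor",
                           "d": "no_contact"}

    def test_boundaries_assigned_upward(self):
        table = impedance_qc({"x": 10.0, "y": 20.0, "z": 50.0})
        classes = dict(zip(table.electrode, table.qc_class))
        assert classes == {"x": "acceptable", "y": "poor", "z": "no_contact"}

    def test_saturated_is_no_contact(self):
        table = impedance_qc({"e": "saturated"})
        assert table.qc_class.iloc[0] == "no_contact"
        assert bool(table.saturated.iloc[0])

    @given(st.floats(0.0, 500.0))
    def test_classes_partition_nonnegative_reals(self, kohm):
        table = impedance_qc({"e": kohm})
        assert table.qc_class.iloc[0] in {"good", "acceptable", "poor",
                                          "no_contact"}

    def test_negative_impedance_rejected(self):
        with pytest.raises(ValueError):
            impedance_qc({"e": -1.0})


class TestNoiseFloor:
    def test_zero_signal_zero_rms(self):
        rec = Recording(np.zeros((2, 1000)), 250.0, ["a", "b"])
        assert (noise_floor(rec) == 0).all()

    def test_in_band_sinusoid_rms(self):
        fs, a = 250.0, 4.0
        t = np.arange(int(20 * fs)) / fs
        rec = Recording((a * np.sin(2 * np.pi * 10.0 * t))[None, :], fs,
                        ["c"])
        assert noise_floor(rec).iloc[0] == pytest.approx(a / np.sqrt(2),
                                                         rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            noise_floor(Recording(np.zeros((1, 100)), 250.0, ["c"]))

    def test_separates_good_from_bad_contacts(self):
        rec, gt = generate_phantom_recording(
            square_amp_mv=0.0,   # noise floor: acquisition with no signal
            contact_quality={"ER1": "good", "ER2": "bad"}, seed=3)
        floors = noise_floor(rec)
        assert floors["ER2"] > 10.0 * floors["ER1"]
        assert floors["ER2"] > 100.0   # hundreds of µVrms for bad contact


class TestSimulatedSignalSnr:
    def test_square_wave_significant_at_f0(self):
        rec, _ = generate_phantom_recording(
            contact_quality={"ER8": "good"}, seed=1)
        res = simulated_signal_snr(rec)["ER8"]
        assert res.snr_db > 10.0
        assert res.p_value < 0.01

    def test_pure_noise_not_significant(self):
        rec, _ = generate_phantom_recording(
            square_amp_mv=0.0, contact_quality={"ER8": "good"}, seed=2)
        res = simulated_signal_snr(rec)["ER8"]
        # single-bin estimate from 4 Welch segments: wide spread
        # around 0 dB under pure noise
        assert abs(res.snr_db) < 8.0
        assert res.p_value >= 0.01

    def test_halving_amplitude_drops_snr_six_db(self):
        quality = {"ER8": "good"}
        full, _ = generate_phantom_recording(
            square_amp_mv=100.0, contact_quality=quality,
            noise_floor_uvrms={"good": 0.5}, seed=4)
        half, _ = generate_phantom_recording(
            square_amp_mv=50.0, contact_quality=quality,
            noise_floor_uvrms={"good": 0.5}, seed=4)
        drop = simulated_signal_snr(full)["ER8"].snr_db \
            - simulated_signal_snr(half)["ER8"].snr_db
        assert drop == pytest.approx(6.0, abs=1.0)

    def test_phantom_harmonics_at_10_and_30(self):
        from earval.spectral import find_spectral_peaks, welch_psd
        rec, _ = generate_phantom_recording(
            contact_quality={"ER8": "good"},
            noise_floor_uvrms={"good": 0.1}, seed=5)
        psd = welch_psd(rec, window_s=8.0)
        peaks = find_spectral_peaks(psd, "ER8", rel_height=1e-3)
        assert 10.0 in np.round(peaks, 3)
        assert 30.0 in np.round(peaks, 3)


class TestIntegrityTrend:
    def test_halving_amplitude_series_pct_change(self):
        table = integrity_trend([(1, 80.0), (2, 52.0), (3, 52.0), (4, 40.0)])
        assert table.pct_change_from_day1.iloc[-1] == pytest.approx(-50.0)

    def test_constant_series_zero_deltas(self):
        table = integrity_trend([(1, 5.0), (2, 5.0), (3, 5.0)])
        assert (table.delta.iloc[1:] == 0).all()

    def test_mass_series_total_loss(self):
        table = integrity_trend([(1, 855.0), (2, 851.0), (3, 850.0),
                                 (4, 845.0)], value_name="mass_g")
        assert table.mass_g.iloc[-1] - table.mass_g.iloc[0] == -10.0

    def test_duplicate_days_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            integrity_trend([(1, 1.0), (1, 2.0)])
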