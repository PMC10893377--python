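"""Filter chain, re-referencing, epoching and baseline correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from earval.core import MarkerStream, Recording
from earval.preprocess import (
    Epochs,
    FilterSpec,
    ReferenceScheme,
    apply_filter_chain,
    baseline_correct,
    extract_epochs,
    rereference,
)

FS = 500.0


def _sine(freq, seconds=10.0, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilterChain:
    def test_notch_removes_50hz(self):
        rec = Recording(_sine(50.0)[None, :], FS, ["c"])
        out = apply_filter_chain(rec, FilterSpec(1.0, 100.0, 50.0))
        rms_in = np.sqrt((rec.data ** 2).mean())
        rms_out = np.sqrt((out.data[:, 500:-500] ** 2).mean())
        assert rms_out < 0.05 * rms_in

    def test_passband_preserves_10hz(self):
        rec = Recording(_sine(10.0, amp=7.0)[None, :], FS, ["c"])
        out = apply_filter_chain(rec, FilterSpec(1.0, 100.0, 50.0))
        mid = out.data[0, 1000:-1000]
        assert np.abs(mid).max() == pytest.approx(7.0, rel=0.05)

    def test_zero_in_zero_out_and_dc_removed(self):
        rec = Recording(np.zeros((2, 2000)), FS, ["a", "b"])
        out = apply_filter_chain(rec, FilterSpec(1.0, 20.0, None))
        assert np.all(out.data == 0)
        dc = Recording(np.full((1, 5000), 42.0), FS, ["a"])
        out = apply_filter_chain(dc, FilterSpec(1.0, 20.0, None))
        # DC gain below -40 dB
        assert np.abs(out.data[0, 1000:-1000]).max() < 42.0 * 1e-2

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 3000))
        y = rng.normal(size=(1, 3000))
        spec = FilterSpec(1.0, 40.0, None)
        fa = apply_filter_chain(Recording(x, FS, ["c"]), spec).data
        fb = apply_filter_chain(Recording(y, FS, ["c"]), spec).data
        fab = apply_filter_chain(
            Recording(2.0 * x - 3.0 * y, FS, ["c"]), spec).data
        np.testing.assert_allclose(fab, 2.0 * fa - 3.0 * fb, atol=1e-8)

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_filter_chain(Recording(np.zeros((1, 100)), FS, ["c"]),
                               FilterSpec(1.0, 300.0, None))
        with pytest.raises(ValueError, match="notch"):
            FilterSpec(1.0, 20.0, 50.0).validate(FS)
        with pytest.raises(ValueError, match="highpass"):
            FilterSpec(30.0, 20.0, None).validate(FS)


class TestRereference:
    @pytest.fixture
    def rec(self, rng):
        return Recording(rng.normal(size=(4, 100)), FS,
                         ["Cz", "T8", "EL8", "ER3"])

    def test_reference_channel_becomes_zero(self, rec):
        out = rereference(rec, ReferenceScheme("channel", "Cz"))
        assert np.all(out.data[0] == 0)
        assert out.reference_label == "Cz"

    def test_pairwise_differences_preserved(self, rec):
        out = rereference(rec, ReferenceScheme("channel", "T8"))
        np.testing.assert_allclose(out.data[2] - out.data[3],
                                   rec.data[2] - rec.data[3], atol=1e-12)

    def test_rereference_composition_identity(self, rec):
        # (re-ref to T8 then to Cz) == (re-ref to Cz directly)
        via = rereference(rereference(rec, ReferenceScheme("channel", "T8")),
                          ReferenceScheme("channel", "Cz"))
        direct = rereference(rec, ReferenceScheme("channel", "Cz"))
        np.testing.assert_allclose(via.data, direct.data, atol=1e-12)

    def test_between_ear_reference(self, rec):
        out = rereference(rec, ReferenceScheme("channel", "ER3"))
        np.testing.assert_allclose(out.data[2],
                                   rec.data[2] - rec.data[3], atol=1e-12)

    def test_missing_channel_is_lookup_error(self, rec):
        with pytest.raises(KeyError, match="Pz"):
            rereference(rec, ReferenceScheme("channel", "Pz"))


class TestExtractEpochs:
    def test_window_index_arithmetic(self):
        data = np.arange(2000, dtype=float)[None, :]
        rec = Recording(data, FS, ["c"])
        markers = MarkerStream([(1000 / FS, "s")])
        ep = extract_epochs(rec, markers, {"s"}, (-0.1, 0.5))
        assert ep.data.shape == (1, 1, 301)
        # samples 950..1250 inclusive
        assert ep.data[0, 0, 0] == 950
        assert ep.data[0, 0, -1] == 1250

    def test_latency_correction_rounds_ties_up(self):
        data = np.arange(2000, dtype=float)[None, :]
        rec = Recording(data, FS, ["c"])
        markers = MarkerStream([(1000 / FS, "s")])
        # 21 ms at 500 Hz = 10.5 samples -> rounds up to 11
        ep = extract_epochs(rec, markers, {"s"}, (-0.1, 0.5),
                            latency_correction=0.021)
        assert ep.data[0, 0, 0] == 950 + 11

    def test_trial_count_matches_markers(self, aep_session):
        rec, markers, gt = aep_session
        ep = extract_epochs(rec, markers, {"tone"}, (-0.1, 0.5))
        assert ep.n_trials == 200
        assert ep.n_trials + ep.n_dropped == len(markers)

    def test_edge_trials_dropped_and_counted(self):
        rec = Recording(np.zeros((1, 1000)), FS, ["c"])
        markers = MarkerStream([(0.01, "s"), (1.0, "s"), (1.99, "s")])
        ep = extract_epochs(rec, markers, {"s"}, (-0.1, 0.5))
        assert ep.n_trials == 1
        assert ep.n_dropped == 2

    def test_no_matching_markers_is_selection_error(self):
        rec = Recording(np.zeros((1, 1000)), FS, ["c"])
        markers = MarkerStream([(1.0, "other")])
        with pytest.raises(ValueError, match="no markers"):
            extract_epochs(rec, markers, {"s"}, (-0.1, 0.5))


class TestBaseline:
    def _epochs(self, data):
        return Epochs(data, FS, (-0.1, 0.5), ["c"], ["s"] * data.shape[0])

    def test_constant_trials_go_to_zero(self):
        data = np.full((3, 1, 301), 5.0)
        out = baseline_correct(self._epochs(data), (-0.1, 0.0))
        assert np.all(out.data == 0)
        assert out.baseline_window == (-0.1, 0.0)

    def test_post_baseline_interval_mean_is_zero(self, rng):
        data = rng.normal(3.0, 1.0, size=(10, 1, 301))
        out = baseline_correct(self._epochs(data), (-0.1, 0.0))
        mask = (out.times >= -0.1) & (out.times <= 0.0)
        np.testing.assert_allclose(out.data[:, :, mask].mean(axis=2), 0.0,
                                   atol=1e-12)

    def test_template_recovered_despite_per_trial_offsets(self, rng):
        times = -0.1 + np.arange(301) / FS
        template = 4.0 * np.exp(-0.5 * ((times - 0.2) / 0.03) ** 2)
        offsets = rng.normal(0, 20.0, size=200)
        noise = rng.normal(0, 1.0, size=(200, 1, 301))
        data = template[None, None, :] + offsets[:, None, None] + noise
        out = baseline_correct(self._epochs(data), (-0.1, 0.0))
        recovered = out.data.mean(axis=0)[0]
        assert np.abs(recovered - template).max() < 3.0 * 1.2 / np.sqrt(200)

    def test_invalid_baseline_span_rejected(self):
        ep = self._epochs(np.zeros((2, 1, 301)))
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(ep, (-0.5, -0.2))
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(ep, (0.2, 0.1))


@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_rereference_preserves_differences_property(seed):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(5, 40))
    rec = Recording(data, FS, list("abcde"))
    out = rereference(rec, ReferenceScheme("channel", "c"))
    for i in range(5):
        for j in range(5):
            np.testing.assert_allclose(
                out.data[i] - out.data[j], data[i] - data[j], atol=1e-10)
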