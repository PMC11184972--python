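"""Filter design contract, epoch indexing, baseline, and aRMS rejection."""

import numpy as np
import pytest

from phosdec.preprocessing import (
    ChannelStats,
    EpochSet,
    apply_filter,
    baseline_correct,
    compute_arms,
    design_bandpass,
    epoch_n_samples,
    extract_epochs,
    preprocess_sessions,
    reject_high_impedance,
    reject_outlier_channels,
    transition_bandwidths,
)
from phosdec.stimulus_design import ScheduledEvent
from phosdec.synthetic_data import ChannelLayout, ContinuousRecording


def _recording(data, fs=1000.0, impedances=None):
    n = data.shape[0]
    lay = ChannelLayout(
        names=[f"ch{i}" for i in range(n)],
        positions=np.zeros((n, 2)),
        impedances=impedances,
    )
    return ContinuousRecording(data=data, fs=fs, layout=lay)


class TestImpedanceRejection:
    def test_threshold(self):
        rec = _recording(np.zeros((4, 100)), impedances=np.array([50.0, 150.0, 99.0, 101.0]))
        out, removed = reject_high_impedance(rec)
        assert removed == ["ch1", "ch3"]
        assert out.layout.n_channels == 2

    def test_none_removed(self):
        rec = _recording(np.zeros((3, 10)), impedances=np.full(3, 10.0))
        out, removed = reject_high_impedance(rec)
        assert removed == [] and out.layout.n_channels == 3

    def test_all_removed_raises(self):
        rec = _recording(np.zeros((2, 10)), impedances=np.full(2, 500.0))
        with pytest.raises(ValueError, match="every channel"):
            reject_high_impedance(rec)


class TestFilterDesign:
    def test_half_amplitude_cutoffs(self):
        spec = design_bandpass(0.5, 30.0, 1000.0)
        assert spec.half_amplitude_cutoffs == (0.25, 33.75)

    def test_transition_bandwidth_rule(self):
        assert transition_bandwidths(0.5, 30.0, 1000.0) == (0.5, 7.5)
        # rule branches: max(0.25*l, 2) capped at l; upper capped at fs/2 - h
        assert transition_bandwidths(10.0, 40.0, 100.0) == (2.5, 10.0)
        assert transition_bandwidths(1.0, 4.0, 1000.0) == (1.0, 2.0)

    def test_measured_minus6db_points(self):
        spec = design_bandpass()
        lo, hi = spec.measured_half_amplitude_cutoffs()
        assert lo == pytest.approx(0.25, abs=0.02)
        assert hi == pytest.approx(33.75, abs=0.02)

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            design_bandpass(30.0, 0.5, 1000.0)
        with pytest.raises(ValueError):
            design_bandpass(1.0, 600.0, 1000.0)


@pytest.fixture(scope="module")
def spec():
    return design_bandpass()


class TestFilterApplication:

    def test_passband_sinusoid_preserved(self, spec):
        fs, t = 1000.0, np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        out = apply_filter(_recording(x), spec).data[0]
        mid = slice(8000, 12000)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.02)
        # zero phase: aligned with input
        assert np.corrcoef(out[mid], x[0, mid])[0, 1] > 0.999

    def test_dc_rejected(self, spec):
        x = np.full((1, 20000), 5.0)
        out = apply_filter(_recording(x), spec).data[0]
        assert np.abs(out[8000:12000]).max() < 0.05

    def test_stopband_attenuation_at_45hz(self, spec):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 45 * t)[None, :]
        out = apply_filter(_recording(x), spec).data[0]
        assert np.abs(out[8000:12000]).max() < 0.05

    def test_short_recording_raises(self, spec):
        with pytest.raises(ValueError, match="shorter"):
            apply_filter(_recording(np.zeros((1, 100))), spec)


class TestEpoching:
    def test_index_formula(self):
        rec = _recording(np.arange(8000, dtype=float)[None, :])
        ep = extract_epochs(rec, [ScheduledEvent(5.0, "s", 0, 0)])
        assert ep.data.shape == (1, 1, 1050)
        assert ep.data[0, 0, 0] == 4700
        assert ep.data[0, 0, -1] == 5749

    def test_samples_scale_with_fs(self):
        assert epoch_n_samples(500.0) == 525
        rec = _recording(np.zeros((1, 5000)), fs=500.0)
        ep = extract_epochs(rec, [ScheduledEvent(2.0, "s", 0, 0)])
        assert ep.n_samples == 525

    def test_truncated_trials_dropped_with_warning(self):
        rec = _recording(np.zeros((1, 2000)))
        events = [ScheduledEvent(0.1, "early", 0, 0), ScheduledEvent(1.0, "ok", 0, 0)]
        with pytest.warns(UserWarning, match="truncated"):
            ep = extract_epochs(rec, events)
        assert ep.n_trials == 1
        assert ep.stimulus_ids[0] == "ok"

    def test_all_events_kept_when_windows_fit(self):
        rec = _recording(np.zeros((2, 10000)))
        events = [ScheduledEvent(1.0 + 2 * k, f"s{k}", 0, 0) for k in range(4)]
        ep = extract_epochs(rec, events)
        assert ep.n_trials == 4


class TestBaseline:
    def _epochs(self, data, fs=1000.0):
        return EpochSet(
            data=data, fs=fs, ch_names=[f"c{i}" for i in range(data.shape[1])],
            stimulus_ids=np.array([f"s{i}" for i in range(data.shape[0])]),
        )

    def test_constant_epoch_zeroed(self):
        ep = self._epochs(np.full((1, 1, 1050), 7.0))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0)

    def test_baseline_window_mean_zero(self, rng):
        ep = self._epochs(rng.standard_normal((5, 3, 1050)))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data[:, :, :200].mean(axis=2), 0.0, atol=1e-12)

    def test_per_channel_independence(self):
        data = np.zeros((1, 2, 1050))
        data[0, 0] = 1.0
        data[0, 1] = 2.0
        out = baseline_correct(self._epochs(data))
        np.testing.assert_allclose(out.data, 0.0)


class TestArms:
    def _epochs(self, data):
        return EpochSet(
            data=data, fs=1000.0, ch_names=[f"c{i}" for i in range(data.shape[1])],
            stimulus_ids=np.array([f"s{i}" for i in range(data.shape[0])]),
        )

    def test_constant_single_trial(self):
        stats = compute_arms(self._epochs(np.full((1, 1, 10), 2.0)))
        assert stats.arms[0] == pytest.approx(2.0)

    def test_mean_of_rms_not_rms_of_pooled(self):
        data = np.zeros((2, 1, 10))
        data[1] = 2.0
        stats = compute_arms(self._epochs(data))
        assert stats.arms[0] == pytest.approx(1.0)  # (0 + 2) / 2

    def test_matches_nested_loop_oracle(self, rng):
        data = rng.standard_normal((7, 5, 20))
        stats = compute_arms(self._epochs(data))
        for j in range(5):
            acc = 0.0
            for n in range(7):
                acc += np.sqrt(np.mean([data[n, j, t] ** 2 for t in range(20)]))
            assert stats.arms[j] == pytest.approx(acc / 7, abs=1e-12)


class TestOutlierRejection:
    def _stats(self, arms):
        arms = np.asarray(arms, dtype=float)
        q1, q3 = np.quantile(arms, [0.25, 0.75])
        return ChannelStats(
            ch_names=[f"c{i}" for i in range(len(arms))], arms=arms,
            q1=float(q1), q3=float(q3),
        )

    def test_single_high_outlier(self):
        keep, removed = reject_outlier_channels(self._stats([10, 11, 12, 13, 12, 40]))
        assert removed == ["c5"]

    def test_all_equal_nothing_removed(self):
        keep, removed = reject_outlier_channels(self._stats([5.0] * 6))
        assert removed == []

    def test_symmetric_contamination(self):
        keep, removed = reject_outlier_channels(
            self._stats([0.01, 10, 11, 12, 13, 12, 11, 100])
        )
        assert set(removed) == {"c0", "c7"}

    def test_never_removes_inside_fences(self, rng):
        for _ in range(50):
            arms = rng.gamma(5.0, 2.0, size=rng.integers(4, 30))
            stats = self._stats(arms)
            keep, removed = reject_outlier_channels(stats)
            low, high = stats.fences
            for name, a in zip(stats.ch_names, arms):
                if low < a < high:
                    assert name not in removed

    def test_too_few_channels_raises(self):
        with pytest.raises(ValueError, match="4 channels"):
            reject_outlier_channels(self._stats([1, 2, 3]))


class TestFullChain:
    def test_noiseless_template_recovery(self, registry, layout8):
        """Filtering then epoching recovers the band-limited evoked template."""
        from phosdec.pipeline import make_custom_schedule
        from phosdec.synthetic_data import (
            NoiseParams, make_erp_template, synthesize_recording,
        )

        fs = 250.0
        sch = make_custom_schedule({"a": ["block9_center"]}, n_trials=4, seed=0,
                                   lead_in=30.0)
        rec = synthesize_recording(sch, registry, layout8,
                                   noise=NoiseParams(std_uv=0.0), seed=0, fs=fs)
        epochs, report = preprocess_sessions({0: rec}, sch)
        tpl = make_erp_template(registry["block9_center"], layout8, fs=fs)
        tpl = tpl[[layout8.names.index(n) for n in epochs.ch_names]]
        onset_sample = int(0.3 * fs)
        rec_tpl = epochs.data[0, :, onset_sample : onset_sample + tpl.shape[1]]
        corr = np.corrcoef(rec_tpl.ravel(), tpl.ravel())[0, 1]
        assert corr > 0.99
        assert report.n_epochs == 4

    def test_channel_bookkeeping_consistent(self, registry, layout32):
        from phosdec.pipeline import ScaledStudyConfig, simulate_task_epochs
        from phosdec.stimulus_design import build_task_registry

        task = {t.name: t for t in build_task_registry(registry)}["left_vs_right"]
        cfg = ScaledStudyConfig(n_trials=40, n_bad_channels=3)
        epochs, report = simulate_task_epochs(task, registry, cfg, seed=5)
        assert len(report.removed_impedance) == 3
        survivors = set(layout32.names) - set(report.removed_impedance) - set(report.removed_arms)
        assert set(epochs.ch_names) == survivors
        # order preserved relative to the original layout
        original_order = [n for n in layout32.names if n in survivors]
        assert epochs.ch_names == original_order
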