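"""RMS envelope, epoching, baseline correction, normalization, pooling, measures."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import auriclab as al
from auriclab.exogenous import (
    ConditionAverages,
    Epoch,
    baseline_correct,
    estimate_onset_latency,
    exogenous_epochs,
    mean_amplitude,
    normalize_by_stimulus_type,
    phasic_trial_measures,
    pool_laterality,
    rms_envelope,
    segment_epochs,
)
from auriclab.io_core import DataError, DesignError
from auriclab.preprocess import preprocess_recording

from conftest import make_events


def brute_force_rms(x, window, step, align):
    """Independent per-window sqrt-mean-square with edge clipping."""
    n = x.size
    out = []
    for p in range(0, n, step):
        if align == "causal":
            lo, hi = max(p + 1 - window, 0), p + 1
        else:
            left = window // 2
            lo, hi = max(p - left, 0), min(p - left + window, n)
        out.append(np.sqrt(np.mean(x[lo:hi] ** 2)))
    return np.array(out)


class TestRmsEnvelope:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(10, 10_000),
        window=st.integers(1, 300),
        step=st.integers(1, 7),
        align=st.sampled_from(["causal", "center"]),
        seed=st.integers(0, 2**16),
    )
    def test_matches_brute_force_oracle(self, n, window, step, align, seed):
        if window > n:
            window = n
        x = np.random.default_rng(seed).normal(size=n)
        env = rms_envelope(x, window, step, align=align)
        np.testing.assert_allclose(
            env.values, brute_force_rms(x, window, step, align), atol=1e-12
        )

    def test_constant_signal(self):
        env = rms_envelope(np.full(1000, -3.0), 150)
        np.testing.assert_allclose(env.values, 3.0)

    def test_zeros(self):
        assert np.all(rms_envelope(np.zeros(500), 50).values == 0)

    def test_sinusoid_interior_is_inv_sqrt2(self):
        fs = 2400.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * 160.0 * t)  # window of 150 samples spans 10 periods
        env = rms_envelope(x, 150, fs=fs)
        interior = env.values[300:-300]
        np.testing.assert_allclose(interior, 1 / np.sqrt(2), rtol=0.01)

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(DataError):
            rms_envelope(np.zeros(100), 101)

    def test_nonnegative(self, rng):
        env = rms_envelope(rng.normal(size=4000), 150)
        assert np.all(env.values >= 0)


def _flat_envelope(n, fs, channel, value=0.0):
    return al.Envelope(np.full(n, value), fs, channel)


class TestEpoching:
    FS = 480.0

    def test_one_epoch_per_event(self, exo_events, pam_pair, small_cfg):
        env = _flat_envelope(int(60 * self.FS), self.FS, pam_pair[0])
        es = segment_epochs(env, exo_events, small_cfg)
        assert len(es) == 4 and es.n_dropped == 0

    def test_epoch_length_tracks_stimulus_duration(self, pam_pair):
        cfg = al.AnalysisConfig()  # epoch_pre = epoch_post = 3 s
        fs = 2400.0
        env = _flat_envelope(int(30 * fs), fs, pam_pair[0])
        ev = make_events(
            [dict(onset=10.0, duration=1.7, speaker_azimuth=30,
                  stimulus_type="a", experiment="exogenous")]
        )
        es = segment_epochs(env, ev, cfg)
        assert es.epochs[0].values.size == int((3 + 1.7 + 3) * fs) == 18480
        assert es.epochs[0].onset_index == int(3 * fs)

    def test_out_of_bounds_event_dropped_with_count(self, pam_pair, small_cfg):
        env = _flat_envelope(int(20 * self.FS), self.FS, pam_pair[0])
        ev = make_events(
            [dict(onset=1.0, duration=2.0, speaker_azimuth=30,
                  stimulus_type="a", experiment="exogenous")]
        )  # needs 3 s of pre-stimulus context
        es = segment_epochs(env, ev, small_cfg)
        assert len(es) == 0 and es.n_dropped == 1


class TestBaselineCorrection:
    def _epoch(self, values, onset_index, channel):
        return Epoch(np.asarray(values, float), 480.0, onset_index, "a", 30.0, channel)

    def test_constant_epoch_goes_to_zero(self, pam_pair):
        ep = baseline_correct(self._epoch(np.full(100, 5.0), 40, pam_pair[0]))
        assert np.all(ep.values == 0) and ep.baseline_mean == 5.0

    def test_post_values_shift_by_pre_mean(self, pam_pair):
        vals = np.concatenate([np.full(50, 2.0), np.full(50, 5.0)])
        ep = baseline_correct(self._epoch(vals, 50, pam_pair[0]))
        np.testing.assert_allclose(ep.values[50:], 3.0)

    def test_pre_interval_mean_is_zero(self, rng, pam_pair):
        ep = baseline_correct(self._epoch(rng.random(200), 80, pam_pair[0]))
        assert abs(ep.values[:80].mean()) < 1e-12

    def test_empty_pre_interval_errors(self, pam_pair):
        with pytest.raises(DataError):
            baseline_correct(self._epoch(np.ones(10), 0, pam_pair[0]))


class TestNormalization:
    def _group(self, peaks, channel):
        eps = []
        for i, pk in enumerate(peaks):
            v = np.zeros(100)
            v[60] = pk
            eps.append(Epoch(v, 480.0, 40, "a", [-30, 30, -120, 120][i], channel))
        return al.EpochSet(eps)

    def test_shared_reference_is_group_max(self, pam_pair):
        es = normalize_by_stimulus_type(self._group([2, 4, 1, 3], pam_pair[0]))
        peaks = sorted(ep.values.max() for ep in es)
        np.testing.assert_allclose(peaks, [0.25, 0.5, 0.75, 1.0])
        assert all(ep.norm_factor == 4.0 for ep in es)

    def test_all_equal_epochs_peak_at_one(self, pam_pair):
        es = normalize_by_stimulus_type(self._group([2, 2, 2, 2], pam_pair[0]))
        assert all(ep.values.max() == 1.0 for ep in es)

    def test_group_size_enforced(self, pam_pair):
        es = self._group([2, 4, 1, 3], pam_pair[0])
        es.epochs.pop()
        with pytest.raises(DesignError):
            normalize_by_stimulus_type(es)

    def test_nonpositive_reference_rejected(self, pam_pair):
        es = self._group([-1, -2, -1, -3], pam_pair[0])
        with pytest.raises(DesignError):
            normalize_by_stimulus_type(es)

    def test_synthetic_session_group_maxima_all_one(self, small_sim, small_cfg):
        rec, ev, _ = al.simulate_exogenous_session(small_sim, "s01", 5)
        proc = preprocess_recording(rec, small_cfg)
        epochs = exogenous_epochs(proc, ev, small_cfg)
        groups = {}
        for ep in epochs:
            groups.setdefault((ep.channel.label, ep.stim_type), []).append(ep)
        for eps in groups.values():
            assert len(eps) == 4
            assert max(e.values.max() for e in eps) == pytest.approx(1.0)
            assert all(e.values.max() <= 1.0 + 1e-12 for e in eps)


class TestPooling:
    def test_full_design_gives_18_trials_per_cell(self, small_cfg):
        sim = al.reduced_sim(
            fs=480.0, carrier_band=(20.0, 90.0), n_stimulus_types=9,
            muscles=("PAM", "TAM"),
        )
        rec, ev, _ = al.simulate_exogenous_session(sim, "s01", 2)
        proc = preprocess_recording(rec, small_cfg)
        avg = pool_laterality(exogenous_epochs(proc, ev, small_cfg))
        assert len(avg.waveforms) == 8  # 2 muscles x 2 x 2
        assert all(n == 18 for n in avg.n_trials.values())
        # conservation: every event contributes one ipsi and one contra epoch
        # per muscle pair, so the four cells hold 2 x 36 epochs in total
        for m in (al.Muscle.PAM, al.Muscle.TAM):
            assert sum(avg.n_trials[(m, c, a)] for c in ("ipsi", "contra")
                       for a in ("front", "back")) == 72

    @pytest.mark.parametrize(
        "side, azimuth, corr, ant",
        [
            (al.Side.LEFT, -30, "ipsi", "front"),
            (al.Side.LEFT, 120, "contra", "back"),
            (al.Side.RIGHT, 30, "ipsi", "front"),
            (al.Side.RIGHT, -120, "contra", "back"),
        ],
    )
    def test_cell_assignment(self, side, azimuth, corr, ant):
        ep = Epoch(np.zeros(4), 480.0, 2, "a", azimuth, al.ChannelInfo(al.Muscle.PAM, side))
        assert (ep.correspondence, ep.anteriority) == (corr, ant)

    def test_constant_epochs_average_to_constant(self, pam_pair):
        eps = []
        for ch in pam_pair:
            for az in (-30, 30, -120, 120):
                eps.append(Epoch(np.ones(50), 480.0, 10, "a", az, ch))
        avg = pool_laterality(al.EpochSet(eps))
        for wf in avg.waveforms.values():
            np.testing.assert_array_equal(wf, 1.0)

    def test_mirror_symmetry(self, small_sim, small_cfg):
        """Swapping all azimuth signs and muscle sides leaves cells unchanged."""
        rec, ev, _ = al.simulate_exogenous_session(small_sim, "s01", 11)
        proc = preprocess_recording(rec, small_cfg)
        epochs = exogenous_epochs(proc, ev, small_cfg)
        avg = pool_laterality(epochs)
        flip_side = {al.Side.LEFT: al.Side.RIGHT, al.Side.RIGHT: al.Side.LEFT}
        mirrored = al.EpochSet(
            [
                Epoch(ep.values, ep.fs, ep.onset_index, ep.stim_type,
                      -ep.speaker_azimuth,
                      al.ChannelInfo(ep.channel.muscle, flip_side[ep.channel.side]))
                for ep in epochs
            ]
        )
        avg2 = pool_laterality(mirrored)
        for key in avg.waveforms:
            np.testing.assert_allclose(avg.waveforms[key], avg2.waveforms[key])

    def test_truncation_to_shortest_epoch(self, pam_pair):
        eps = []
        for ch in pam_pair:
            for az, n in zip((-30, 30, -120, 120), (50, 60, 70, 80)):
                eps.append(Epoch(np.ones(n), 480.0, 10, "a", az, ch))
        avg = pool_laterality(al.EpochSet(eps))
        # each cell pools one left- and one right-channel epoch and truncates
        # to the shorter: front cells -> min(50, 60), back cells -> min(70, 80)
        assert {wf.size for wf in avg.waveforms.values()} == {50, 70}


class TestMeasures:
    def _ramp_avg(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs  # value = t in seconds, onset at 0
        wf = {(al.Muscle.PAM, "ipsi", "front"): t}
        return ConditionAverages(wf, {(al.Muscle.PAM, "ipsi", "front"): 1}, fs, 0)

    def test_ramp_measure_window(self):
        amp = mean_amplitude(self._ramp_avg(), (100.0, 1500.0))
        assert amp[(al.Muscle.PAM, "ipsi", "front")] == pytest.approx(0.8, rel=1e-2)

    def test_ramp_phasic_window(self):
        amp = mean_amplitude(self._ramp_avg(), (50.0, 300.0))
        assert amp[(al.Muscle.PAM, "ipsi", "front")] == pytest.approx(0.175, rel=1e-2)

    def test_constant_waveform(self):
        avg = self._ramp_avg()
        key = next(iter(avg.waveforms))
        avg.waveforms[key] = np.full_like(avg.waveforms[key], 0.3)
        assert mean_amplitude(avg, (100.0, 1500.0))[key] == pytest.approx(0.3)

    def test_window_outside_waveform_errors(self):
        with pytest.raises(DataError):
            mean_amplitude(self._ramp_avg(), (100.0, 5000.0))


class TestOnsetLatency:
    FS = 1200.0

    def _waveform(self, step_at_ms, height, noise_sd, seed=0):
        rng = np.random.default_rng(seed)
        onset = int(1.0 * self.FS)
        n = onset + int(1.0 * self.FS)
        wf = rng.normal(0, noise_sd, n)
        wf[onset + int(step_at_ms / 1000 * self.FS):] += height
        return wf, onset

    def test_step_recovered_within_window_width(self):
        wf, onset = self._waveform(70.0, 10.0, 1.0)
        est = estimate_onset_latency(wf, self.FS, onset)
        assert est == pytest.approx(70.0, abs=62.5)

    def test_pure_noise_gives_none(self):
        wf, onset = self._waveform(0.0, 0.0, 1.0, seed=3)
        assert estimate_onset_latency(wf, self.FS, onset) is None

    def test_flat_baseline_errors(self):
        wf = np.zeros(4800)
        with pytest.raises(DataError):
            estimate_onset_latency(wf, self.FS, 2400)

    def test_short_baseline_errors(self):
        with pytest.raises(DataError):
            estimate_onset_latency(np.zeros(1000), self.FS, 100)


class TestSubjectMeasures:
    def test_tidy_table_shape_and_trial_counts(self, small_sim, small_cfg):
        rec, ev, _ = al.simulate_exogenous_session(small_sim, "s07", 4)
        proc = preprocess_recording(rec, small_cfg)
        df = al.subject_condition_measures(proc, ev, small_cfg)
        assert set(df.columns) >= {
            "subject", "muscle", "correspondence", "anteriority",
            "mean_amp", "phasic_mean", "phasic_sd", "n_trials",
        }
        assert len(df) == 4  # one muscle x 2 x 2
        assert (df["subject"] == "s07").all()
        # one stimulus type x 4 speakers -> 2 epochs per cell (both channels)
        assert (df["n_trials"] == 2).all()

    def test_ipsi_gain_shows_up_in_measures(self, small_sim, small_cfg):
        rec, ev, _ = al.simulate_exogenous_session(small_sim, "s01", 21)
        proc = preprocess_recording(rec, small_cfg)
        df = al.subject_condition_measures(proc, ev, small_cfg)
        piv = df.pivot_table(index="correspondence", values="mean_amp", aggfunc="mean")
        assert piv.loc["ipsi", "mean_amp"] > piv.loc["contra", "mean_amp"]
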