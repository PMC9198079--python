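"""Onset detection, curation rules and window extraction."""

import numpy as np
import pytest

from hammersound.audio_io import (
    STATUS_DELETED,
    STATUS_EXCLUDED,
    STATUS_KEPT,
    Annotation,
    Recording,
)
from hammersound.signal_extraction import (
    WINDOW_LEN,
    StrikeEvent,
    StrikeWindow,
    curate,
    detect_onsets,
    detect_strikes,
    extract_window,
    onset_strength,
)

SR = 44100


def _rec(x, op="op1"):
    return Recording(operation_id=op, samples=x, sample_rate=SR)


def _impulse_rec(times, dur=3.0, amp=0.8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise, int(dur * SR)) if noise else np.zeros(int(dur * SR))
    for t in times:
        x[int(t * SR)] += amp
    return _rec(x)


class TestOnsetStrength:
    def test_silence_gives_all_zero_envelope(self):
        env = onset_strength(_rec(np.zeros(SR)))
        assert np.all(env.values == 0)
        assert len(env.values) == -(-SR // 256)  # ceil(n/hop)

    def test_envelope_maximum_within_one_hop_of_impulse(self):
        t0 = 1.2345
        env = onset_strength(_impulse_rec([t0]))
        t_peak = env.times()[np.argmax(env.values)]
        assert abs(t_peak - t0) <= env.hop / SR

    def test_two_impulses_give_two_local_maxima_at_those_times(self):
        t1, t2 = 1.0, 1.5
        env = onset_strength(_impulse_rec([t1, t2]))
        onsets = detect_onsets(env)
        assert len(onsets) == 2
        assert abs(onsets[0] - t1) <= env.hop / SR
        assert abs(onsets[1] - t2) <= env.hop / SR

    def test_recording_shorter_than_one_frame_rejected(self):
        with pytest.raises(ValueError, match="shorter than one frame"):
            onset_strength(_rec(np.zeros(512)))


class TestDetectOnsets:
    def test_all_zero_envelope_yields_no_onsets(self):
        env = onset_strength(_rec(np.zeros(SR)))
        assert detect_onsets(env) == []

    def test_close_peaks_pruned_keeping_the_larger(self):
        # two impulses 50 ms apart, second one larger; min separation 150 ms
        rec = _impulse_rec([1.0], amp=0.4)
        rec.samples[int(1.05 * SR)] += 0.9
        env = onset_strength(rec)
        onsets = detect_onsets(env, min_separation=0.150)
        assert len(onsets) == 1
        assert abs(onsets[0] - 1.05) <= 2 * env.hop / SR

    def test_synthetic_strikes_recovered_without_spurious_detections(self):
        """20 strikes at known times in 20 dB noise: >= 19 hits, 0 spurious."""
        from hammersound.synthetic_data import OperationParams, synth_strike_wave

        rng = np.random.default_rng(5)
        times = 0.6 + 0.4 * np.arange(20)
        op = OperationParams(base_freq_hz=2000.0, beta=0.0)
        x = np.zeros(int((times[-1] + 1.0) * SR))
        for t in times:
            w = synth_strike_wave(0.5, op, rng) * 0.6
            i = int(t * SR)
            x[i : i + len(w)] += w
        strike_rms = 0.6 * np.sqrt(np.mean(synth_strike_wave(0.5, op, rng) ** 2))
        x += rng.normal(0, strike_rms / 10, len(x))  # 20 dB SNR
        det = np.asarray(detect_strikes(_rec(x)))
        hits = sum(1 for t in times if np.min(np.abs(det - t)) <= 0.005)
        assert hits >= 19
        spurious = sum(1 for d in det if np.min(np.abs(times - d)) > 0.005)
        assert spurious == 0


def _ann(kept, deleted=(), noise=(), op="op1"):
    return Annotation(
        operation_id=op,
        stem_type="Optimys",
        rasp_sequence=[0, 2, 3, 4],
        final_size=4,
        kept_onsets=list(kept),
        deleted_onsets=list(deleted),
        noise_intervals=list(noise),
    )


class TestCurate:
    def test_exact_detections_all_kept_with_labels(self):
        kept = [(1.0, 0), (2.0, 2), (3.0, 4)]
        events = curate([1.0, 2.0, 3.0], _ann(kept), SR)
        assert [e.status for e in events] == [STATUS_KEPT] * 3
        assert [e.size_index for e in events] == [0, 2, 4]
        assert [e.onset_time for e in events] == [1.0, 2.0, 3.0]

    def test_detection_within_tolerance_inherits_label_and_time(self):
        events = curate([1.004], _ann([(1.0, 4)]), SR)
        assert events[0].status == STATUS_KEPT
        assert events[0].onset_time == pytest.approx(1.004)

    def test_kept_onset_window_overlapping_noise_interval_excluded(self):
        window_s = WINDOW_LEN / SR
        events = curate(
            [1.0, 2.0],
            _ann([(1.0, 0), (2.0, 4)], noise=[(2.0 + window_s / 2, 2.5)]),
            SR,
        )
        assert events[0].status == STATUS_KEPT
        assert events[1].status == STATUS_EXCLUDED

    def test_unmatched_detection_and_deleted_onset_are_deleted(self):
        events = curate([1.0, 5.0], _ann([(1.0, 4)], deleted=[7.0]), SR)
        statuses = {round(e.onset_time, 3): e.status for e in events}
        assert statuses[1.0] == STATUS_KEPT
        assert statuses[5.0] == STATUS_DELETED  # spurious detection
        assert statuses[7.0] == STATUS_DELETED  # annotated non-strike

    def test_missed_annotation_onset_synthesized_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="hammersound.signal_extraction"):
            events = curate([], _ann([(1.0, 4)]), SR)
        assert len(events) == 1
        assert events[0].status == STATUS_KEPT
        assert events[0].onset_time == 1.0
        assert any("no detection" in r.message for r in caplog.records)


class TestExtractWindow:
    def _event(self, t, status=STATUS_KEPT):
        return StrikeEvent.at("op1", t, SR, 4, status)

    def test_onset_at_zero_of_4096_recording_returns_it_all(self):
        x = np.linspace(-1, 1, WINDOW_LEN)
        w = extract_window(_rec(x), self._event(0.0))
        assert np.array_equal(w.samples, x)

    def test_window_near_end_zero_padded(self):
        n = 10000
        x = np.ones(n) * 0.5
        ev = self._event((n - 1000) / SR)
        w = extract_window(_rec(x), ev)
        assert len(w.samples) == WINDOW_LEN
        assert np.all(w.samples[:1000] == 0.5)
        assert np.all(w.samples[1000:] == 0.0)

    def test_window_is_exact_slice_of_known_ramp(self):
        x = np.arange(20000) / 20000.0
        ev = self._event(100 / SR)
        w = extract_window(_rec(x), ev)
        assert np.array_equal(w.samples, x[100 : 100 + WINDOW_LEN])

    def test_non_kept_event_rejected(self):
        with pytest.raises(ValueError, match="status"):
            extract_window(_rec(np.zeros(SR)), self._event(0.5, STATUS_DELETED))

    def test_onset_beyond_recording_end_rejected(self):
        with pytest.raises(ValueError, match="beyond end"):
            extract_window(_rec(np.zeros(1000)), self._event(1.0))

    @pytest.mark.parametrize("onset_frac", [0.0, 0.5, 0.97, 0.999])
    def test_every_window_has_length_4096(self, onset_frac):
        n = 50000
        rec = _rec(np.random.default_rng(0).normal(0, 0.1, n))
        ev = self._event(onset_frac * n / SR)
        assert len(extract_window(rec, ev).samples) == WINDOW_LEN
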