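"""Delta-modulation codec contracts, checked against an independent
step-through oracle that re-implements the encoding rule literally."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfosnn.adm import (
    AdmParams,
    PulseStream,
    TuningConfig,
    compression_ratio,
    decode,
    encode,
    read_pulses,
    tune_threshold,
    write_pulses,
)

FS = 1000.0


def oracle_encode(x, delta, refr_samples):
    """Literal step-through of the stated rule, independent of the
    compiled implementation: thresholds at baseline ± delta, inclusive
    crossings, re-anchor around the crossed threshold (the continuous-
    time crossing value), shared refractory."""
    if len(x) == 0:
        return []
    anchor = x[0]
    last = -math.inf
    out = []
    for i in range(1, len(x)):
        if i - last < refr_samples:
            continue
        if x[i] >= anchor + delta:
            out.append((i, +1))
            anchor, last = anchor + delta, i
        elif x[i] <= anchor - delta:
            out.append((i, -1))
            anchor, last = anchor - delta, i
    return out


def _pulse_list(stream: PulseStream):
    return [(int(round(t * stream.fs)), int(p)) for t, p in zip(stream.times, stream.polarities)]


class TestTuning:
    def test_constant_signal_returns_floor(self):
        cfg = TuningConfig(tuning_duration=1.0, window_len=0.1, percentile=50)
        with pytest.warns(UserWarning, match="constant"):
            delta = tune_threshold(np.full(1000, 5.0), cfg, FS)
        assert delta == cfg.delta_min

    def test_median_of_known_ranges(self):
        # five 100-sample windows with ranges 1..5 uV
        parts = [np.linspace(0, r, 100) for r in (1, 2, 3, 4, 5)]
        x = np.concatenate(parts)
        cfg = TuningConfig(tuning_duration=0.5, window_len=0.1, percentile=50)
        assert tune_threshold(x, cfg, FS) == pytest.approx(3.0)

    def test_percentile_40_linear_interpolation(self):
        parts = [np.linspace(0, r, 100) for r in (1, 2, 3, 4, 5)]
        x = np.concatenate(parts)
        cfg = TuningConfig(tuning_duration=0.5, window_len=0.1, percentile=40)
        # independent linear-interpolation percentile: idx = 0.4*(5-1) = 1.6
        expected = 2 + 0.6 * (3 - 2)
        assert tune_threshold(x, cfg, FS) == pytest.approx(expected)

    def test_signal_shorter_than_tuning_phase_rejected(self):
        cfg = TuningConfig(tuning_duration=5.0, window_len=0.05)
        with pytest.raises(ValueError, match="tuning needs"):
            tune_threshold(np.zeros(100), cfg, FS)

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            TuningConfig(percentile=0.0)


class TestEncode:
    def test_constant_signal_no_pulses(self):
        s = encode(np.array([5.0, 5, 5, 5]), AdmParams(delta=1.0), FS)
        assert len(s) == 0
        assert s.x0 == 5.0

    def test_ramp_matches_oracle(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        s = encode(x, AdmParams(delta=1.0), FS)
        assert _pulse_list(s) == [(2, 1), (4, 1)]
        assert _pulse_list(s) == oracle_encode(x, 1.0, 0)

    def test_ramp_with_refractory(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        s = encode(x, AdmParams(delta=1.0, refractory=3 / FS), FS)
        assert _pulse_list(s) == [(2, 1)]

    def test_multi_delta_step_emits_single_pulse(self):
        s = encode(np.array([0.0, -2.0]), AdmParams(delta=1.0), FS)
        assert _pulse_list(s) == [(1, -1)]

    def test_empty_signal_empty_stream(self):
        s = encode(np.array([]), AdmParams(delta=1.0), FS)
        assert len(s) == 0 and s.n_samples == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        delta=st.floats(0.2, 3.0),
        refr=st.integers(0, 5),
    )
    def test_matches_oracle_on_random_smooth_signals(self, seed, delta, refr):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(0, 0.5, size=200))
        s = encode(x, AdmParams(delta=delta, refractory=refr / FS), FS)
        assert _pulse_list(s) == oracle_encode(x, delta, refr)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_refractory_respected_and_monotone_in_delta(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(0, 1.0, size=300))
        refr = 4
        s = encode(x, AdmParams(delta=1.0, refractory=refr / FS), FS)
        if len(s) > 1:
            assert np.all(np.diff(s.times) >= refr / FS - 1e-12)
        counts = [len(encode(x, AdmParams(delta=d), FS)) for d in (0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestDecode:
    def test_empty_stream_constant(self):
        s = PulseStream(times=np.empty(0), polarities=np.empty(0, dtype=np.int8),
                        delta=1.0, x0=2.5, fs=FS, n_samples=4)
        assert np.allclose(decode(s), 2.5)

    def test_up_then_dn_staircase(self):
        # the reconstruction recursion applied directly
        s = PulseStream(times=np.array([1, 3]) / FS, polarities=np.array([1, -1], dtype=np.int8),
                        delta=1.0, x0=0.0, fs=FS, n_samples=5)
        assert np.allclose(decode(s), [0, 1, 1, 0, 0])

    def test_ramp_round_trip_error_bounded(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        s = encode(x, AdmParams(delta=1.0), FS)
        xhat = decode(s)
        assert np.allclose(xhat, [0, 0, 1, 1, 2])
        assert np.max(np.abs(x - xhat)) <= 1.0 + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), delta=st.floats(0.5, 2.0))
    def test_round_trip_bound_on_smooth_signals(self, seed, delta):
        """With tau=0 and per-sample increments < delta, |x - x_hat| <= delta."""
        rng = np.random.default_rng(seed)
        increments = rng.uniform(-0.9 * delta, 0.9 * delta, size=400)
        x = np.cumsum(increments)
        s = encode(x, AdmParams(delta=delta), FS)
        xhat = decode(s)
        assert np.max(np.abs(x - xhat)) <= delta + 1e-9

    def test_decode_steps_only_at_pulse_times(self, rng):
        x = np.cumsum(rng.normal(0, 1, 300))
        s = encode(x, AdmParams(delta=1.5), FS)
        xhat = decode(s)
        steps = np.flatnonzero(np.diff(xhat) != 0) + 1
        pulse_idx = np.round(s.times * FS).astype(int)
        assert set(steps) <= set(pulse_idx.tolist())
        assert np.allclose(np.abs(np.diff(xhat)[np.diff(xhat) != 0]), 1.5)


class TestCompression:
    def test_simple_ratio(self):
        assert compression_ratio(100, 5) == 20

    def test_empty_stream_flagged_infinite(self):
        with pytest.warns(UserWarning, match="no events"):
            assert math.isinf(compression_ratio(100, 0))

    def test_zero_length_signal_rejected(self):
        with pytest.raises(ValueError):
            compression_ratio(0, 5)


def test_pulse_file_round_trip(tmp_path, rng):
    x = np.cumsum(rng.normal(0, 1, 5000))
    s = encode(x, AdmParams(delta=1.0, refractory=0.002, band="EEG"), FS, channel="CH01")
    path = tmp_path / "pulses.csv"
    write_pulses([s], path)
    (back,) = read_pulses(path)
    assert np.array_equal(back.times, s.times)
    assert np.array_equal(back.polarities, s.polarities)
    assert (back.delta, back.x0, back.fs, back.n_samples) == (s.delta, s.x0, s.fs, s.n_samples)


def test_pulse_file_invalid_polarity_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text('#{"streams": []}\ntime_s,channel,band,polarity\n0.1,CH01,EEG,2\n')
    with pytest.raises(ValueError, match="polarity"):
        read_pulses(path)
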