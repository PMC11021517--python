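"""Spiking-core contracts: layout arithmetic, mismatch heterogeneity,
LIF integration against the closed-form single-pulse response, wiring
exclusivity and determinism."""

import numpy as np
import pytest

from hfosnn.adm import PulseStream
from hfosnn.snn import (
    CHIP_CAPACITY,
    CORE_CAPACITY,
    MismatchModel,
    NeuronParams,
    build_network,
    neuron_utilization,
    read_raster,
    simulate,
    write_raster,
)

FS = 2000.0


def _stream(times, pols, channel="CH01", band="HFO", duration=1.0):
    return PulseStream(
        times=np.asarray(times, dtype=float),
        polarities=np.asarray(pols, dtype=np.int8),
        delta=1.0, x0=0.0, fs=FS, n_samples=int(duration * FS),
        channel=channel, band=band,
    )


class TestLayout:
    def test_one_channel_is_forty_neurons(self):
        assert build_network(1).n_neurons == 40

    def test_eight_channels_fill_both_cores(self):
        net = build_network(8)
        assert net.n_neurons == 320
        for band in (0, 1):  # one core per band
            assert int(np.sum(net.band_idx == band)) == 160
            assert int(np.sum(net.band_idx == band)) <= CORE_CAPACITY

    def test_capacity_error_beyond_eight_channels(self):
        with pytest.raises(ValueError, match="capacity"):
            build_network(9)

    @pytest.mark.parametrize(
        ("n", "expected"), [(0, 0.0), (1, 40 / 1024), (8, 320 / 1024)]
    )
    def test_utilization_fraction(self, n, expected):
        assert neuron_utilization(n) == pytest.approx(expected)

    def test_utilization_matches_reported_percentages(self):
        assert round(100 * neuron_utilization(1), 1) == 3.9
        assert round(100 * neuron_utilization(8), 1) == 31.2
        assert CHIP_CAPACITY == 4 * CORE_CAPACITY


class TestMismatch:
    def test_cv_zero_identical_neurons(self):
        net = build_network(1, mismatch=MismatchModel(cv=0.0))
        for arr in net.params.values():
            hfo = arr[net.band_idx == 1]
            assert np.all(hfo == hfo[0])

    def test_jitter_deterministic_and_positive(self):
        a = build_network(2, mismatch=MismatchModel(cv=0.2, seed=5))
        b = build_network(2, mismatch=MismatchModel(cv=0.2, seed=5))
        c = build_network(2, mismatch=MismatchModel(cv=0.2, seed=6))
        for name in a.params:
            assert np.array_equal(a.params[name], b.params[name])
        assert not np.array_equal(a.params["input_weight"], c.params["input_weight"])
        assert np.all(a.params["membrane_tau"] > 0)
        assert np.all(a.params["synapse_tau"] > 0)

    def test_invalid_cv_rejected(self):
        with pytest.raises(ValueError):
            MismatchModel(cv=0.7)

    def test_heterogeneity_decorrelates_spike_trains(self):
        """Mean pairwise correlation within a population drops as cv grows."""
        rng = np.random.default_rng(0)
        # dense poisson-ish UP pulse train
        times = np.sort(rng.uniform(0.05, 0.95, size=400))
        times = np.unique(np.round(times, 4))
        stream = _stream(times, np.ones(len(times)))

        def mean_corr(cv):
            p = NeuronParams(membrane_tau=0.01, synapse_tau=0.004, refractory=0.005,
                             input_weight=0.4)
            net = build_network(1, hfo_params=p, mismatch=MismatchModel(cv=cv, seed=1))
            raster = simulate(net, [stream], dt=1e-4, duration=1.0)
            sub = raster.select(band="HFO", pop="ACC_UP")
            bins = np.arange(0, 1.0 + 0.01, 0.01)
            trains = [np.histogram(sub.times[sub.unit_idx == u], bins)[0] for u in range(10)]
            cors = []
            for i in range(10):
                for j in range(i + 1, 10):
                    si, sj = np.std(trains[i]), np.std(trains[j])
                    if si > 0 and sj > 0:
                        cors.append(np.corrcoef(trains[i], trains[j])[0, 1])
            return np.mean(cors)

        assert mean_corr(0.0) > mean_corr(0.2)


class TestSimulate:
    def test_no_input_no_spikes(self):
        net = build_network(1)
        raster = simulate(net, [], dt=1e-4, duration=0.5)
        assert len(raster) == 0

    def test_single_pulse_threshold_crossing_closed_form(self):
        """Peak membrane response to one pulse is
        A(e^{-t/tau_m} - e^{-t/tau_s}) with A = g·w·tau_s/(tau_m - tau_s);
        thresholds straddling that peak separate silence from firing."""
        tau_m, tau_s, w, g = 0.010, 0.004, 0.5, 1.0
        A = g * w * tau_s / (tau_m - tau_s)
        t_peak = np.log(tau_m / tau_s) * tau_m * tau_s / (tau_m - tau_s)
        v_peak = A * (np.exp(-t_peak / tau_m) - np.exp(-t_peak / tau_s))
        stream = _stream([0.1], [1])
        for thr, expect_spikes in ((10 * v_peak, False), (v_peak / 10, True)):
            p = NeuronParams(membrane_tau=tau_m, synapse_tau=tau_s, threshold=thr,
                             input_weight=w, gain=g)
            net = build_network(1, hfo_params=p, mismatch=MismatchModel(cv=0.0))
            raster = simulate(net, [stream], dt=1e-5, duration=0.3)
            n = len(raster.select(band="HFO", pop="ACC_UP"))
            assert (n >= 10) == expect_spikes  # all 10 identical neurons agree

    def test_mismatch_produces_distinct_spike_counts(self):
        rng = np.random.default_rng(2)
        times = np.unique(np.round(np.sort(rng.uniform(0.1, 0.3, 300)), 4))
        stream = _stream(times, np.ones(len(times)))
        p = NeuronParams(membrane_tau=0.01, synapse_tau=0.004, refractory=0.005,
                         input_weight=0.3)
        net = build_network(1, hfo_params=p, mismatch=MismatchModel(cv=0.2, seed=3))
        raster = simulate(net, [stream], dt=1e-4, duration=0.5)
        sub = raster.select(band="HFO", pop="ACC_UP")
        counts = [int(np.sum(sub.unit_idx == u)) for u in range(10)]
        assert len(set(counts)) >= 2

    def test_wiring_exclusivity(self):
        """ACC UP raster is unchanged when DN pulses are removed."""
        rng = np.random.default_rng(4)
        up_times = np.unique(np.round(np.sort(rng.uniform(0, 0.9, 150)), 4))
        dn_times = np.unique(np.round(np.sort(rng.uniform(0, 0.9, 150)), 4)) + 1e-4 / 3
        both = _stream(
            np.sort(np.concatenate([up_times, dn_times])),
            [1 if t in set(up_times) else -1 for t in np.sort(np.concatenate([up_times, dn_times]))],
        )
        up_only = _stream(up_times, np.ones(len(up_times)))
        p = NeuronParams(membrane_tau=0.01, synapse_tau=0.004, input_weight=0.4)
        net = build_network(1, hfo_params=p, mismatch=MismatchModel(cv=0.2, seed=0))
        r_both = simulate(net, [both], dt=1e-4, duration=1.0).select(band="HFO", pop="ACC_UP")
        r_up = simulate(net, [up_only], dt=1e-4, duration=1.0).select(band="HFO", pop="ACC_UP")
        assert np.array_equal(r_both.times, r_up.times)
        assert np.array_equal(r_both.unit_idx, r_up.unit_idx)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        times = np.unique(np.round(np.sort(rng.uniform(0, 0.5, 200)), 4))
        stream = _stream(times, np.ones(len(times)))
        net = build_network(1, mismatch=MismatchModel(cv=0.2, seed=9))
        a = simulate(net, [stream], dt=1e-4, duration=0.6)
        b = simulate(net, [stream], dt=1e-4, duration=0.6)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.unit_idx, b.unit_idx)

    def test_coarse_dt_rejected(self):
        net = build_network(1)
        with pytest.raises(ValueError, match="dt"):
            simulate(net, [_stream([0.1], [1])], dt=0.002, duration=0.5)

    def test_unknown_channel_rejected(self):
        net = build_network(1, channels=["CH01"])
        with pytest.raises(KeyError):
            simulate(net, [_stream([0.1], [1], channel="CH99")], dt=1e-4, duration=0.5)


def test_raster_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    times = np.unique(np.round(np.sort(rng.uniform(0, 0.4, 200)), 4))
    stream = _stream(times, rng.choice([1, -1], len(times)))
    net = build_network(1)
    raster = simulate(net, [stream], dt=1e-4, duration=0.5)
    assert len(raster) > 0
    path = tmp_path / "raster.csv"
    write_raster(raster, path)
    back = read_raster(path, duration=0.5)
    assert np.array_equal(back.times, raster.times)
    assert np.array_equal(back.pop_idx, raster.pop_idx)
    assert np.array_equal(back.unit_idx, raster.unit_idx)


def test_raster_negative_neuron_id_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("time_s,channel,band,population,neuron_id\n0.1,CH01,HFO,ACC_UP,-1\n")
    with pytest.raises(ValueError, match="negative neuron id"):
        read_raster(path)
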