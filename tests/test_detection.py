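"""Detection rules on hand-constructed spike rasters: smoothing,
segmentation, the four HFO rules in order, IED-HFO logic and rates."""

import numpy as np
import pytest

from hfosnn.detection import (
    DetectionRules,
    classify_hfo,
    classify_ied_hfo,
    detect_channel,
    event_rates,
    segment_eoi,
    smooth_activity,
    write_events,
)
from hfosnn.snn import BANDS, POPS, SpikeRaster

RULES = DetectionRules()


def make_raster(spikes, duration=2.0, channels=("CH01",)):
    """spikes: list of (time, channel, band, pop, unit)."""
    spikes = sorted(spikes)
    return SpikeRaster(
        times=np.array([s[0] for s in spikes], dtype=float),
        channel_idx=np.array([s[1] for s in spikes], dtype=np.int16),
        band_idx=np.array([BANDS.index(s[2]) for s in spikes], dtype=np.int8),
        pop_idx=np.array([POPS.index(s[3]) for s in spikes], dtype=np.int8),
        unit_idx=np.array([s[4] for s in spikes], dtype=np.int16),
        channels=list(channels),
        duration=duration,
    )


def hfo_burst(t0, n_up=4, n_dn=4, spread=0.010, channel=0):
    """A clean mixed burst: interleaved UP/DN spikes from distinct neurons."""
    out = []
    for i in range(n_up):
        out.append((t0 + spread * i / max(n_up, 1), channel, "HFO", "ACC_UP", i))
    for i in range(n_dn):
        out.append((t0 + spread * (i + 0.5) / max(n_dn, 1), channel, "HFO", "ACC_DN", i))
    return out


class TestSmoothing:
    def test_empty_raster_zero_trace(self):
        trace = smooth_activity(make_raster([]), 0, "HFO", RULES, duration=1.0)
        assert np.all(trace.total == 0)

    def test_single_spike_active_for_kernel_duration(self):
        raster = make_raster([(0.5, 0, "HFO", "ACC_UP", 0)])
        trace = smooth_activity(raster, 0, "HFO", RULES, duration=1.0)
        active = np.flatnonzero(trace.total > 0) * RULES.grid_dt
        assert active.min() == pytest.approx(0.5, abs=RULES.grid_dt)
        assert active.max() - active.min() == pytest.approx(RULES.kernel_duration,
                                                            abs=2 * RULES.grid_dt)

    def test_two_spikes_merge_into_one_interval(self):
        raster = make_raster([(0.5, 0, "HFO", "ACC_UP", 0), (0.55, 0, "HFO", "ACC_DN", 1)])
        trace = smooth_activity(raster, 0, "HFO", RULES, duration=1.0)
        segments = segment_eoi(trace)
        assert len(segments) == 1
        seg = segments[0]
        assert seg["end"] - seg["start"] == pytest.approx(0.150, abs=3 * RULES.grid_dt)
        assert seg["is_eoi"]


class TestSegmentation:
    def test_up_only_interval_not_eoi(self):
        raster = make_raster([(0.3, 0, "HFO", "ACC_UP", 0), (0.31, 0, "HFO", "ACC_UP", 1)])
        trace = smooth_activity(raster, 0, "HFO", RULES, duration=1.0)
        (seg,) = segment_eoi(trace)
        assert seg["has_up"] and not seg["has_dn"] and not seg["is_eoi"]

    def test_interleaved_up_dn_is_eoi(self):
        raster = make_raster(hfo_burst(0.4))
        (seg,) = segment_eoi(smooth_activity(raster, 0, "HFO", RULES, duration=1.0))
        assert seg["is_eoi"]

    def test_distant_bursts_stay_separate(self):
        raster = make_raster(hfo_burst(0.2) + hfo_burst(0.9))
        segments = segment_eoi(smooth_activity(raster, 0, "HFO", RULES, duration=1.5))
        assert len(segments) == 2


def _classify(spikes, duration=2.0):
    raster = make_raster(spikes, duration)
    trace = smooth_activity(raster, 0, "HFO", RULES, duration)
    eeg_trace = smooth_activity(raster, 0, "EEG", RULES, duration)
    (candidate,) = [s for s in segment_eoi(trace) if s["is_eoi"]]
    return classify_hfo(candidate, raster, 0, RULES, segment_eoi(eeg_trace))


class TestHfoRules:
    def test_clean_burst_accepted(self):
        ev = _classify(hfo_burst(0.5, n_up=3, n_dn=4, spread=0.020))
        assert ev.kind == "HFO"
        assert ev.rejection_reason is None

    def test_rule1_too_few_neurons(self):
        ev = _classify(hfo_burst(0.5, n_up=3, n_dn=2, spread=0.020))
        assert ev.rejection_reason == "rule1_insufficient_neurons"

    def test_rule1_missing_dn_activations(self):
        spikes = hfo_burst(0.5, n_up=7, n_dn=0) + [(0.505, 0, "HFO", "ACC_DN", 0)]
        ev = _classify(spikes)
        assert ev.rejection_reason == "rule1_insufficient_neurons"

    def test_rule2_separated_up_dn_rejected(self):
        """Filtering-artifact signature: UP burst then DN burst, 40 ms gap."""
        spikes = [(0.5 + 0.002 * i, 0, "HFO", "ACC_UP", i) for i in range(4)]
        spikes += [(0.548 + 0.002 * i, 0, "HFO", "ACC_DN", i) for i in range(4)]
        ev = _classify(spikes)
        assert ev.rejection_reason == "rule2_up_dn_separated"

    def test_rule3_span_too_long(self):
        ev = _classify(hfo_burst(0.5, n_up=5, n_dn=5, spread=0.045))
        assert ev.rejection_reason == "rule3_too_long"

    def test_rule3_robust_to_single_stray_spike(self):
        """One isolated spike 80 ms after a clean 20 ms burst must not
        inflate the measured span past the limit."""
        spikes = hfo_burst(0.5, n_up=5, n_dn=5, spread=0.018)
        spikes.append((0.58, 0, "HFO", "ACC_UP", 9))
        ev = _classify(spikes)
        assert ev.kind == "HFO"

    def test_rule4_long_eeg_coactivity_rejected(self):
        spikes = hfo_burst(0.5, spread=0.020)
        spikes += [(0.2 + 0.06 * i, 0, "EEG", "ACC_UP" if i % 2 else "ACC_DN", i % 10)
                   for i in range(15)]  # EEG spikes spanning ~840 ms
        ev = _classify(spikes)
        assert ev.rejection_reason == "rule4_long_eeg_coactivity"

    def test_rule_order_short_circuits(self):
        """An event failing rule 1 is never blamed on a later rule, even
        when rules 2 and 3 would also fail."""
        spikes = [(0.5, 0, "HFO", "ACC_UP", 0), (0.56, 0, "HFO", "ACC_DN", 0)]
        ev = _classify(spikes)
        assert ev.rejection_reason == "rule1_insufficient_neurons"

    def test_raising_min_total_neurons_monotone(self):
        spikes = hfo_burst(0.5, n_up=4, n_dn=4, spread=0.02)
        raster = make_raster(spikes)
        accepted = []
        for min_total in (4, 6, 8, 10):
            rules = DetectionRules(min_total_neurons=min_total)
            events = detect_channel(raster, 0, rules, duration=2.0)
            accepted.append(sum(1 for e in events if e.kind == "HFO"))
        assert accepted == sorted(accepted, reverse=True)


class TestIedHfo:
    def eeg_ied(self, t0, span=0.1, channel=0):
        """Well-separated EEG signature: DN packet, then an UP packet
        close enough (< kernel) that both fall in one activity period."""
        dn = [(t0 + 0.004 * i, channel, "EEG", "ACC_DN", i) for i in range(3)]
        up = [(t0 + span - 0.004 * i, channel, "EEG", "ACC_UP", i) for i in range(3)]
        return dn + up

    def test_separated_eeg_upgrades_to_ied_hfo(self):
        spikes = hfo_burst(0.5, spread=0.02) + self.eeg_ied(0.45)
        raster = make_raster(spikes)
        events = detect_channel(raster, 0, duration=2.0)
        assert [e.kind for e in events if e.kind != "EoI_HFO"] == ["IED_HFO"]

    def test_no_eeg_activity_stays_hfo(self):
        raster = make_raster(hfo_burst(0.5, spread=0.02))
        events = detect_channel(raster, 0, duration=2.0)
        assert [e.kind for e in events] == ["HFO"]

    def test_eeg_span_above_limit_stays_hfo(self):
        # separated DN-then-UP signature but stretched past 300 ms
        spikes = hfo_burst(0.5, spread=0.02)
        spikes += [(0.30 + 0.05 * i, 0, "EEG", "ACC_DN", i % 5) for i in range(4)]
        spikes += [(0.56 + 0.05 * i, 0, "EEG", "ACC_UP", i % 5) for i in range(4)]
        raster = make_raster(spikes)
        events = detect_channel(raster, 0, duration=2.0)
        assert [e.kind for e in events] == ["HFO"]

    def test_mixed_eeg_up_dn_stays_hfo(self):
        spikes = hfo_burst(0.5, spread=0.02)
        spikes += [(0.45 + 0.01 * i, 0, "EEG", POPS[i % 2], i % 10) for i in range(8)]
        raster = make_raster(spikes)
        events = detect_channel(raster, 0, duration=2.0)
        assert [e.kind for e in events] == ["HFO"]

    def test_requires_accepted_hfo(self):
        raster = make_raster(hfo_burst(0.5))
        ev = detect_channel(raster, 0, DetectionRules(min_total_neurons=20), duration=2.0)[0]
        with pytest.raises(ValueError):
            classify_ied_hfo(ev, raster, RULES, [])


class TestRates:
    def _events(self):
        raster = make_raster(
            hfo_burst(0.5, spread=0.02, channel=0)
            + hfo_burst(3.0, spread=0.02, channel=0)
            + hfo_burst(1.5, spread=0.02, channel=1),
            duration=360.0, channels=("CH01", "CH02"),
        )
        return [e for e in __import__("hfosnn.detection", fromlist=["detect"]).detect(
            raster, RULES, duration=360.0) if e.kind == "HFO"]

    def test_rate_arithmetic(self):
        events = self._events()
        rates = event_rates(events, recording_duration=360.0)
        ch0 = rates[(rates.channel == 0) & (rates.kind == "HFO")].iloc[0]
        ch1 = rates[(rates.channel == 1) & (rates.kind == "HFO")].iloc[0]
        assert ch0.rate_per_min == pytest.approx(2 / 6)
        assert ch1.rate_per_min == pytest.approx(1 / 6)

    def test_no_events_zero_rate(self):
        rates = event_rates([], recording_duration=60.0, n_channels=1)
        assert (rates.rate_per_min == 0).all()

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            event_rates([], recording_duration=0.0)


def test_events_tsv_written(tmp_path):
    raster = make_raster(hfo_burst(0.5, spread=0.02))
    events = detect_channel(raster, 0, duration=2.0)
    path = tmp_path / "events.tsv"
    write_events(events, path, channels=["CH01"])
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["onset", "duration", "channel", "kind", "rejection_reason"]
    assert df.iloc[0]["kind"] == "HFO"
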