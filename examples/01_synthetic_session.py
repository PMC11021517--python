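"""Generate a ground-truthed synthetic ECoG session and write it to disk.

The generator fabricates pink-noise background at ECoG-like amplitudes
and injects epileptiform events (HFO bursts, IEDs, co-occurring
IED-HFO) and artifacts at random non-overlapping positions, logging
every injection. Everything downstream of this package is testable
against that log.
"""

import collections

from hfosnn.synthetic import SyntheticConfig, generate_recording, write_recording

config = SyntheticConfig(
    n_channels=2,
    duration=60.0,
    seed=7,
    event_counts={"hfo": 6, "ied": 3, "ied_hfo": 3, "step_artifact": 2, "long_artifact": 1},
)
recording, truth = generate_recording(config)

print(f"recording: {recording.n_channels} channels x {recording.duration:.0f} s "
      f"@ {recording.fs:.0f} Hz ({recording.units})")
counts = collections.Counter(e.kind for e in truth)
for kind, n in sorted(counts.items()):
    print(f"  injected {kind:14s} x {n}")
print("first three ground-truth rows (kind, channel, onset s, offset s):")
print(truth.to_frame().head(3).to_string(index=False))

write_recording(recording, truth, "scratch_example_session")
print("wrote scratch_example_session.{raw,json} and .events.tsv")
print("each row above is one injected event; a detector run on this "
      "recording can be scored exactly against the .events.tsv log")
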