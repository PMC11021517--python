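"""Delta-modulation encoding: tune the threshold, encode, decode.

The ADM turns a band-filtered trace into UP/DN pulses; δ is a
percentile of the amplitude-range distribution measured on the first
5 s. The pulse stream is self-contained: integrating ±δ steps from
x(0) reconstructs the trace to within δ.
"""

import numpy as np

from hfosnn import adm, preprocessing
from hfosnn.synthetic import SyntheticConfig, generate_recording

config = SyntheticConfig(n_channels=1, duration=30.0, seed=1).with_counts(hfo=4, ied=2)
recording, truth = generate_recording(config)

spec = preprocessing.FilterSpec(band=preprocessing.HFO_BAND, fs=recording.fs)
filtered = preprocessing.stream_filter(recording.data[0], spec)

delta = adm.tune_threshold(filtered, adm.HFO_TUNING, recording.fs)
stream = adm.encode(filtered, adm.AdmParams(delta=delta, band="HFO"), recording.fs, "CH01")
ratio = adm.compression_ratio(stream.n_samples, len(stream))
reconstructed = adm.decode(stream)
err = np.max(np.abs(filtered - reconstructed))

print(f"tuned delta       : {delta:.2f} uV (50th percentile of 5 ms window ranges)")
print(f"pulses emitted    : {len(stream)} ({stream.n_up} UP / {stream.n_dn} DN) "
      f"for {stream.n_samples} samples")
print(f"compression ratio : {ratio:.1f}x  (samples per pulse)")
quiet = np.ones(recording.n_samples, dtype=bool)
for e in truth:  # mask the injected events and their filter response
    quiet[int((e.onset - 0.05) * recording.fs): int((e.offset + 0.1) * recording.fs)] = False
print(f"max |x - x_hat|   : {err:.2f} uV overall, "
      f"{np.max(np.abs((filtered - reconstructed)[quiet])):.2f} uV on background")
print("the error is bounded by delta wherever the signal moves less than "
      "delta per sample; narrowband noise flurries and fast-ripple bursts "
      "briefly outrun the one-pulse-per-sample ceiling, where the error "
      "approaches the local signal amplitude — the pulse *timing*, which "
      "downstream detection uses, is preserved")
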