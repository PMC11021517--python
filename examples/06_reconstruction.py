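"""Validate the spike compression by reconstructing the trace from spikes.

A full-FORCE teacher/student pair is trained on snippets from the first
quarter of a synthetic session and evaluated on the rest: if a linear
readout of the student RNN (driven by accumulator spikes alone)
correlates with the original band-filtered ECoG, the sparse spike code
demonstrably preserves signal morphology.
"""

from hfosnn.calibrate import reconstruction_demo
from hfosnn.config import PipelineConfig

report = reconstruction_demo(PipelineConfig())

print(f"snippets: {report['n_train']} train / {report['n_test']} test "
      f"(both ACC UP and ACC DN active, spike span <= 500 ms)")
print(f"signal: {report['n_samples']} samples -> {report['n_pulses']} pulses "
      f"-> {report['n_spikes']} spikes")
print("student-teacher drive mismatch per RLS pass:",
      [round(x, 3) for x in report["mismatch_trace"]])
print(f"median Pearson r: train {report['median']['train']:.3f}, "
      f"test {report['median']['test']:.3f}")
print("the test-set correlation is computed on snippets the model never "
      "saw; values well above chance mean the spike timing alone carries "
      "the waveform shape of the underlying epileptiform events")
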