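"""Entropy-based signal-quality gating in action.

A window containing a numerically zero sample makes the entropy sum
E = -sum(x^2 ln x^2) undefined (0 * ln 0); with gating enabled such windows
are skipped rather than risking an estimate from a flat-lined signal.
"""

import numpy as np

from respyre import PipelineConfig, PPGRecord, SynthConfig, estimate_record, \
    generate

record, truth = generate(SynthConfig(duration_s=270, resp_hz=0.3, seed=21))
samples = record.samples.copy()
samples[int(100 * record.fs)] = 0.0          # sensor flat-line artefact
tainted = PPGRecord(samples=samples, fs=record.fs)

for use_esqi in (True, False):
    ests = estimate_record(tainted, PipelineConfig(window_s=90,
                                                   use_esqi=use_esqi))
    desc = ", ".join(
        f"@{e.window.start_s:.0f}s: " +
        ("skipped (" + e.skip_reason + ")" if e.skipped
         else f"{e.respr:.1f}")
        for e in ests)
    print(f"gating {'on ' if use_esqi else 'off'}: {desc}")
# With gating on, only the window containing the zero sample is skipped;
# with gating off every window produces an estimate.
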