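"""Show what the robustness stages buy on an artefact-laden record.

The same underlying record is generated with spike outliers, then estimated
with and without the Hampel outlier filter.  Spikes compress the useful
dynamic range after peak enhancement; removing them restores accuracy.
"""

import numpy as np

from respyre import PipelineConfig, SynthConfig, estimate_record, generate

cfg = SynthConfig(duration_s=360, resp_hz=12 / 60, hr_bpm=80,
                  spike_rate=4.0, seed=13)
record, truth = generate(cfg)
print(f"truth {truth.resp_brpm:.0f} breaths/min, "
      f"{truth.spike_indices.size} spikes injected")

for label, pipe in [
    ("with Hampel   ", PipelineConfig(window_s=90, use_esqi=False)),
    ("without Hampel", PipelineConfig(window_s=90, use_esqi=False,
                                      use_hampel=False)),
]:
    vals = [e.respr for e in estimate_record(record, pipe) if not e.skipped]
    mae = np.mean(np.abs(np.asarray(vals) - truth.resp_brpm))
    print(f"  {label}: MAE {mae:.2f} breaths/min over {len(vals)} windows")
# A lower MAE with the filter enabled shows the stage earning its place.
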