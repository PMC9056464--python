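"""Sweep window sizes and pick the best one against the reference rate.

Longer windows give the Welch estimate more RR intervals (finer frequency
resolution); very short windows can mis-resolve slow breathing.  The sweep
reports MAE per candidate size and the selected best window.
"""

from respyre import PipelineConfig, SynthConfig, generate, select_best_window

record, truth = generate(SynthConfig(duration_s=480, resp_hz=0.25,
                                     hr_bpm=70, seed=3))
best, results = select_best_window(
    record, PipelineConfig(), candidate_windows=(10, 20, 30, 45, 60, 90, 120))

print(f"truth {truth.resp_brpm:.0f} breaths/min")
print(f"{'window_s':>9} {'MAE':>7} {'RMSE':>7} {'windows':>8}")
for w in sorted(results):
    r = results[w]
    print(f"{w:9g} {r.mae:7.3f} {r.rmse:7.3f} {r.n_windows:8d}")
print(f"best window: {best:g} s (ties go to the smaller, cheaper window)")
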