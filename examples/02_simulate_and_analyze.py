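"""Simulate a calibrated synthetic cohort and run the full report pipeline.

Generates 202 subjects (101 CN / 62 aMCI / 39 AD) whose two-visit score
distributions match the published group summaries, then writes the six
report tables plus a manifest into ./pipeline_out/.
"""

from pathlib import Path

import pandas as pd

from cogchange import PipelineConfig, reference_config, run_pipeline

out = Path(__file__).parent / "pipeline_out"
written = run_pipeline(PipelineConfig(out_dir=out, synthetic=reference_config(seed=42)))
for name, path in sorted(written.items()):
    print(f"wrote {path}")

sens = pd.read_csv(out / "table2_sensitivity.csv")
print("\nSensitivity to change on the simulated cohort:")
print(sens[["group", "instrument", "n", "mean_change", "es", "reliability_r", "d", "band"]]
      .round(3).to_string(index=False))
print(
    "\nWith only ~39-101 subjects per group the empirical ES/d scatter"
    "\naround their generating values; rerun with another seed to see the"
    "\nsampling variability a real single-cohort study is exposed to."
)
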