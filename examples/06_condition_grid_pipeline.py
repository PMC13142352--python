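"""The full condition-grid pipeline with windowed summaries and effect sizes.

Runs the standard 0/1/2/4-ligand-copy grid (planted occupancy ladder
43/38/17/12 waters, field on), writes per-condition CSV/JSON outputs and a
manifest, and prints the pairwise Cohen's d table for pore hydration.
"""

import pandas as pd

from poreblock import RunConfig, default_condition_grid, run_pipeline

config = RunConfig(
    conditions=default_condition_grid(n_frames=200, field_strength=10.0),
    out_dir="scratch/example_run",
    seed=11,
)
reports = run_pipeline(config)

print("condition  waters(mean±sd, last 25%)  passes")
for label in sorted(reports):
    r = reports[label]
    h = r.summaries["hydration"]
    print(f"{label:9s}  {h.mean:6.2f} ± {h.sd:5.2f}            {r.n_events}")

print("\npairwise Cohen's d on pore hydration:")
print(pd.read_csv("scratch/example_run/effect_sizes.csv").to_string(index=False))
# |d| >= 0.8 is a large effect: removing pore waters with increasing ligand
# occupancy dwarfs the frame-to-frame fluctuation of hydration.
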