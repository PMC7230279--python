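"""Run the complete study replica and print the method-comparison summary.

Chains every stage (cohort, features, QC, equations, Auto-CM map, TWIST,
two-run ANN, report) into one run directory of CSV/JSON artifacts.
"""

import json

import pandas as pd

from pedree import RunConfig, run_full_study

run_dir = run_full_study(RunConfig(out_dir="run_example", seed=1))
manifest = json.loads((run_dir / "manifest.json").read_text())

print(f"selected variables: {manifest['selected_variables']}")
t2 = pd.read_csv(run_dir / "metrics_by_subgroup.csv")
overall = t2[t2.subgroup == "overall"][["method", "mae", "imprecision_pct", "pearson_r2"]]
print(overall.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

# The neural network's out-of-sample MAE sits far below every equation's,
# with the highest correlation to measured REE - the qualitative pattern
# the method comparison is about.
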