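"""Stratified severity shares: which body parts carry the predicted burden?

For each stratum (gender, seniority band, production area) the report
normalises the summed predicted per-part severities to percentages — the
numbers behind per-stratum pie charts.
"""

from ohpp import GeneratorConfig, run_pipeline

import pandas as pd

manifest = run_pipeline(GeneratorConfig(n_workers=150, seed=21), "scratch/example_run", k_folds=3, n_explain=5)
print("pipeline stages:", ", ".join(manifest["stages"]))

shares = pd.read_csv("scratch/example_run/severity_shares.csv")
gender = shares[shares["dimension"] == "gender"].set_index("level")
top = gender.drop(columns=["dimension", "n_records"]).idxmax(axis=1)
for level, part in top.items():
    pct = gender.loc[level, part]
    print(f"gender={level}: highest predicted severity share is {part} at {pct:.1f}%")
# shares in each row sum to 100%
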