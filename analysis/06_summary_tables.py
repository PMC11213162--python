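"""The two summary approaches: feature families pooled across bands
(100/36/28/36 features) and single bands across families (25 each), each
evaluated with per-fold PSO selection."""

import pandas as pd

from common import RUN_DIR, study_config
from gfcband.pipeline import run_stage

cfg = study_config(selector="pso")
run_stage("report", cfg, RUN_DIR)

for approach in ("families", "bands"):
    table = pd.read_csv(RUN_DIR / f"summary_{approach}.csv")
    print(f"\n=== approach: {approach} ===")
    print(table.drop(columns=["selected_features"]).to_string(index=False))
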