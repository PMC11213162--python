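"""Assemble the 100-feature table (25 signed-network metrics x 4 bands)."""

import pandas as pd

from common import RUN_DIR, study_config
from gfcband.pipeline import run_stage

cfg = study_config()
run_stage("features", cfg, RUN_DIR)

table = pd.read_csv(RUN_DIR / "feature_table.csv")
n_features = table.shape[1] - 2
print(f"feature table: {table.shape[0]} subjects x {n_features} features")
by_family = pd.Series([c.split(".")[1] for c in table.columns[2:]]).value_counts()
print("features per family (x4 bands):")
print(by_family.to_string())
sep = (table.groupby("group")["ffb.tmh.tmh_p"].mean())
print(f"group means of ffb.tmh.tmh_p: {sep.round(3).to_dict()}")
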