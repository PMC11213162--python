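"""Nested 10-fold SVM-RBF classification of the study cohort on all 100
features, without selection and with per-fold PSO selection."""

import json

from common import RUN_DIR, study_config
from gfcband.pipeline import run_stage

for selector in ("none", "pso"):
    cfg = study_config(selector=selector)
    run_stage("classify", cfg, RUN_DIR)
    rep = json.loads((RUN_DIR / f"cv_report_all_{selector}.json").read_text())
    pooled = rep["pooled"]
    n_sel = sum(f["n_selected"] for f in rep["folds"]) / len(rep["folds"])
    print(f"selector={selector:4s}  acc={pooled['acc']:.3f}  "
          f"sen={pooled['sen']:.3f}  spec={pooled['spec']:.3f}  "
          f"auc={rep['auc']:.3f}  mean selected={n_sel:.1f}/100")
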