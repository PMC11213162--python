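"""Full-band tapered sliding-window FC per subject, the group rank-sum edge
mask and each subject's sparse adjacency."""

import numpy as np

from common import RUN_DIR, EFFECT_EDGES, study_config
from gfcband.pipeline import run_stage

cfg = study_config()
run_stage("fc", cfg, RUN_DIR)

mask = np.loadtxt(RUN_DIR / "fc" / "edge_mask.tsv", delimiter="\t").astype(bool)
iu = np.triu_indices(mask.shape[0], k=1)
n_sig = int(mask[iu].sum())
planted_hit = sum(mask[i, j] for i, j in EFFECT_EDGES)
print(f"rank-sum mask: {n_sig}/{iu[0].size} edges significant at "
      f"alpha={cfg.alpha}")
print(f"planted edges retained in the mask: {planted_hit}/10")
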