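"""Graph Fourier band filtering: per-subject Laplacian spectra of the sparse
adjacency and low/middle/high-band FC matrices."""

import numpy as np

from common import RUN_DIR, study_config
from gfcband.pipeline import run_stage
from gfcband.spectral import band_split

cfg = study_config()
run_stage("gsp", cfg, RUN_DIR)

bands = band_split(cfg.n_rois)
print(f"band split for M={cfg.n_rois}: {len(bands.lfb_modes)} low / "
      f"{len(bands.mfb_modes)} middle / {len(bands.hfb_modes)} high modes")
ev = np.loadtxt(RUN_DIR / "spectra" / "sub-A0000_eigenvalues.tsv")
print(f"example subject eigenvalue range: [{ev.min():.2e}, {ev.max():.3f}] "
      f"({int((np.abs(ev) < 1e-8).sum())} zero modes = graph components)")
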