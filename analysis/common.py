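"""Shared study configuration for the numbered analysis scripts.

The study cohort: M = 20 ROIs, 60 subjects per group, modular base
connectivity, and a planted 0.4 correlation shift on 10 of the 190 edges —
a desk-scale stand-in for the two-group rs-fMRI cohort the method targets.
PSO runs with a reduced iteration budget suited to this problem size.
"""

from pathlib import Path

from gfcband.pipeline import RunConfig
from gfcband.selection import PSOConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "study"

EFFECT_EDGES = [(2 * k, 2 * k + 1) for k in range(10)]


def study_config(selector: str = "pso", seed: int = 1) -> RunConfig:
    return RunConfig(
        n_group_a=60, n_group_b=60, n_rois=20,
        effect_edges=EFFECT_EDGES, effect_size=0.4,
        selector=selector,
        pso=PSOConfig(swarm_size=20, iterations=8, seed=seed),
        seed=seed,
    )
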