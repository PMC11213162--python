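"""End-to-end orchestration: simulate -> fc -> gsp -> features -> classify -> report.

Each stage reads the previous stage's outputs from the run directory and
writes its own, so stages are idempotent given unchanged inputs and can be
run individually (see :mod:`gfcband.cli`). A manifest records a checksum for
every file a stage writes; re-running the full pipeline with the same config
and seed reproduces identical feature tables and reports.

Stage order follows the analysis design: full-band sliding-window FC first,
then the group rank-sum mask and per-subject sparse adjacency, then
graph-spectral band filtering of the time series and band-wise FC, then the
100-feature table, then nested cross-validated classification, and finally
the two summary tables (feature families pooled across bands; single bands
across families).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynfc, evaluate, features as feats, spectral, synthetic
from .selection import PSOConfig, SAConfig

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fc", "gsp", "features", "classify", "report")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    # cohort source: synthetic spec, or a directory of per-subject TSVs
    cohort_dir: str | None = None
    n_group_a: int = 30
    n_group_b: int = 30
    n_rois: int = 20
    n_volumes: int = 140
    n_discard: int = 5
    tr_seconds: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    base_covariance: str = "modular"
    effect_edges: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    effect_size: float = 0.0
    noise_sd: float = 1.0

    # FC stage
    rect_width: int = 50
    gauss_sigma: float = 3.0
    window_shift: int = 1
    alpha: float = 0.05
    fdr: bool = False

    # spectral stage
    signed_laplacian: bool = False

    # selection / classification
    selector: str = "pso"  # pso | sa | none
    pso: PSOConfig = dataclasses.field(default_factory=PSOConfig)
    sa: SAConfig = dataclasses.field(default_factory=SAConfig)
    svm_cost: float = 1.0
    outer_folds: int = 10
    inner_folds: int = 5

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        pso = PSOConfig(**raw.pop("pso", {}))
        sa = SAConfig(**raw.pop("sa", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw, pso=pso, sa=sa)
        if cfg.band_hz is not None:
            cfg.band_hz = tuple(cfg.band_hz)
        cfg.effect_edges = [tuple(e) for e in cfg.effect_edges]
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["effect_edges"] = [list(e) for e in self.effect_edges]
        return yaml.safe_dump(d, sort_keys=False)

    def cohort_spec(self) -> synthetic.CohortSpec:
        return synthetic.CohortSpec(
            n_group_a=self.n_group_a, n_group_b=self.n_group_b,
            n_rois=self.n_rois, n_volumes=self.n_volumes,
            n_discard=self.n_discard, tr_seconds=self.tr_seconds,
            band_hz=self.band_hz, base_covariance=self.base_covariance,
            effect_edges=self.effect_edges, effect_size=self.effect_size,
            noise_sd=self.noise_sd, seed=self.seed)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path):
        self.path = run_dir / "run_manifest.json"
        self.data = (json.loads(self.path.read_text())
                     if self.path.exists() else {"files": {}, "stages": {}})

    def record(self, stage: str, files: list[Path], seconds: float) -> None:
        for f in files:
            self.data["files"][str(f)] = _checksum(f)
        self.data["stages"][stage] = {"n_files": len(files),
                                      "wall_seconds": round(seconds, 3)}
        self.path.write_text(json.dumps(self.data, indent=2))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise StageError(needed_by, f"missing {path.name}; run the '{stage}' "
                                    f"stage first")
    return path


def _load_cohort(config: RunConfig, run_dir: Path, needed_by: str):
    if config.cohort_dir is not None:
        return synthetic.read_cohort(config.cohort_dir)
    _require(run_dir / "cohort" / "manifest.json", "simulate", needed_by)
    return synthetic.read_cohort(run_dir / "cohort")


def stage_simulate(config: RunConfig, run_dir: Path) -> list[Path]:
    if config.cohort_dir is not None:
        logger.info("simulate: external cohort %s, nothing to generate",
                    config.cohort_dir)
        return []
    spec = config.cohort_spec()
    cohort = synthetic.generate_cohort(spec)
    synthetic.write_cohort(cohort, run_dir / "cohort", spec=spec)
    return sorted((run_dir / "cohort").iterdir())


def _fc_path(run_dir: Path, sid: str, band: str) -> Path:
    return run_dir / "fc" / f"{sid}_{band}.tsv"


def stage_fc(config: RunConfig, run_dir: Path) -> list[Path]:
    """Full-band sliding-window FC per subject, the group rank-sum edge mask,
    and each subject's sparse adjacency."""
    cohort = _load_cohort(config, run_dir, "fc")
    taper = dynfc.build_taper(config.rect_width, config.gauss_sigma)
    out = run_dir / "fc"
    out.mkdir(parents=True, exist_ok=True)
    fcs = {"A": [], "B": []}
    written = []
    for ts in cohort:
        fc = dynfc.sliding_window_fc(ts, taper, shift=config.window_shift,
                                     band="ffb", subject_id=ts.subject_id)
        fcs[ts.group].append(fc)
        path = _fc_path(run_dir, ts.subject_id, "ffb")
        np.savetxt(path, fc.values, delimiter="\t", fmt="%.17g")
        written.append(path)
    mask, adjacencies = dynfc.group_sparse_adjacency(
        fcs["A"], fcs["B"], alpha=config.alpha, fdr=config.fdr)
    np.savetxt(out / "edge_mask.tsv", mask.astype(int), delimiter="\t", fmt="%d")
    written.append(out / "edge_mask.tsv")
    pmat = dynfc.edge_rank_tests(fcs["A"], fcs["B"])
    iu = np.triu_indices(mask.shape[0], k=1)
    pd.DataFrame({"roi_i": iu[0], "roi_j": iu[1], "p": pmat[iu]}).to_csv(
        out / "edge_tests.tsv", sep="\t", index=False)
    written.append(out / "edge_tests.tsv")
    for adj in adjacencies:
        path = out / f"{adj.subject_id}_sfc.tsv"
        np.savetxt(path, adj.values, delimiter="\t", fmt="%.17g")
        written.append(path)
    return written


def stage_gsp(config: RunConfig, run_dir: Path) -> list[Path]:
    """Per-subject Laplacian spectrum of the sparse adjacency, band filtering
    of the time series, and band-wise sliding-window FC."""
    cohort = _load_cohort(config, run_dir, "gsp")
    _require(run_dir / "fc" / "edge_mask.tsv", "fc", "gsp")
    taper = dynfc.build_taper(config.rect_width, config.gauss_sigma)
    spectra_dir = run_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    written = []
    bands = spectral.band_split(config.n_rois if config.cohort_dir is None
                                else cohort[0].n_rois)
    for ts in cohort:
        sfc_path = _require(run_dir / "fc" / f"{ts.subject_id}_sfc.tsv", "fc", "gsp")
        adjacency = np.loadtxt(sfc_path, delimiter="\t", ndmin=2)
        lap = spectral.laplacian(adjacency, signed=config.signed_laplacian)
        spectrum = spectral.eigendecompose(lap, source_id=ts.subject_id)
        np.savetxt(spectra_dir / f"{ts.subject_id}_eigenvalues.tsv",
                   spectrum.eigenvalues, delimiter="\t", fmt="%.17g")
        np.savetxt(spectra_dir / f"{ts.subject_id}_eigenvectors.tsv",
                   spectrum.eigenvectors, delimiter="\t", fmt="%.17g")
        written += [spectra_dir / f"{ts.subject_id}_eigenvalues.tsv",
                    spectra_dir / f"{ts.subject_id}_eigenvectors.tsv"]
        for band in ("lfb", "mfb", "hfb"):
            filtered = spectral.band_filter(ts.data, spectrum, bands.modes(band))
            ts_path = spectra_dir / f"{ts.subject_id}_{band}.tsv"
            np.savetxt(ts_path, filtered, delimiter="\t", fmt="%.17g")
            written.append(ts_path)
            fc = dynfc.sliding_window_fc(filtered, taper,
                                         shift=config.window_shift, band=band,
                                         subject_id=ts.subject_id,
                                         undefined="zero")
            fc_path = _fc_path(run_dir, ts.subject_id, band)
            np.savetxt(fc_path, fc.values, delimiter="\t", fmt="%.17g")
            written.append(fc_path)
    return written


def stage_features(config: RunConfig, run_dir: Path) -> list[Path]:
    cohort = _load_cohort(config, run_dir, "features")
    rows, sids, groups = [], [], []
    for ts in cohort:
        mats = {}
        for band in feats.BAND_ORDER:
            path = _require(_fc_path(run_dir, ts.subject_id, band),
                            "fc" if band == "ffb" else "gsp", "features")
            mats[band] = np.loadtxt(path, delimiter="\t", ndmin=2)
        rows.append(feats.extract_features(mats["ffb"], mats["lfb"],
                                           mats["mfb"], mats["hfb"],
                                           modularity_seed=config.seed))
        sids.append(ts.subject_id)
        groups.append(ts.group)
    table = feats.assemble_feature_table(rows, sids, groups)
    table_path = run_dir / "feature_table.csv"
    table.to_csv(table_path, index=False)
    dict_path = run_dir / "feature_dictionary.tsv"
    feats.data_dictionary().to_csv(dict_path, sep="\t", index=False)
    return [table_path, dict_path]


def _load_feature_table(run_dir: Path, needed_by: str) -> pd.DataFrame:
    path = _require(run_dir / "feature_table.csv", "features", needed_by)
    return pd.read_csv(path)


def _run_cv(config: RunConfig, table: pd.DataFrame, columns: list[str]):
    selector_config = {"pso": config.pso, "sa": config.sa, "none": None}[config.selector]
    return evaluate.nested_cv(
        table[columns], table["group"].to_numpy(), selector=config.selector,
        selector_config=selector_config,
        svm_config=evaluate.SVMConfig(cost=config.svm_cost, seed=config.seed),
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        seed=config.seed, feature_names=columns)


def stage_classify(config: RunConfig, run_dir: Path) -> list[Path]:
    """Nested CV on all 100 features with the configured selector."""
    table = _load_feature_table(run_dir, "classify")
    report = _run_cv(config, table, feats.feature_names())
    report_path = run_dir / f"cv_report_all_{config.selector}.json"
    report.save(report_path)
    roc_path = run_dir / f"roc_all_{config.selector}.tsv"
    np.savetxt(roc_path, report.roc_points, delimiter="\t", header="fpr\ttpr",
               comments="")
    return [report_path, roc_path]


def stage_report(config: RunConfig, run_dir: Path) -> list[Path]:
    """The two grouping approaches: feature families pooled across bands, and
    single bands across families."""
    table = _load_feature_table(run_dir, "report")
    written = []
    family_subsets = [("all", feats.feature_names()),
                      ("graph", feats.family_columns("graph")),
                      ("mst", feats.family_columns("mst")),
                      ("triad_tmh_links", feats.family_columns("triad_tmh_links"))]
    band_subsets = [(band, feats.band_columns(band)) for band in feats.BAND_ORDER]
    for approach, subsets in (("families", family_subsets), ("bands", band_subsets)):
        tagged = []
        for tag, columns in subsets:
            report = _run_cv(config, table, columns)
            report.save(run_dir / f"cv_report_{approach}_{tag}_{config.selector}.json")
            written.append(run_dir / f"cv_report_{approach}_{tag}_{config.selector}.json")
            tagged.append((tag, config.selector, len(columns), report))
        summary = evaluate.report_tables(tagged)
        csv_path = run_dir / f"summary_{approach}.csv"
        txt_path = run_dir / f"summary_{approach}.txt"
        summary.to_csv(csv_path, index=False)
        txt_path.write_text(evaluate.format_report_text(summary) + "\n")
        written += [csv_path, txt_path]
    return written


_STAGE_FN = {
    "simulate": stage_simulate,
    "fc": stage_fc,
    "gsp": stage_gsp,
    "features": stage_features,
    "classify": stage_classify,
    "report": stage_report,
}


def run_stage(stage: str, config: RunConfig, run_dir: str | Path) -> list[Path]:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())
    manifest = _Manifest(run_dir)
    start = time.monotonic()
    try:
        files = _STAGE_FN[stage](config, run_dir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
    elapsed = time.monotonic() - start
    manifest.record(stage, [run_dir / "config.yaml"] + files, elapsed)
    logger.info("stage %s: %d files in %.1fs", stage, len(files), elapsed)
    return files


def run_pipeline(config: RunConfig, run_dir: str | Path) -> Path:
    """Execute every stage in order; returns the run directory."""
    run_dir = Path(run_dir)
    for stage in STAGES:
        run_stage(stage, config, run_dir)
    return run_dir
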