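"""Synthetic two-group ROI time-series cohorts with planted connectivity differences.

Real resting-state cohorts of this kind are access-controlled, so every
downstream stage (sliding-window FC, graph-spectral filtering, network
features, selection, classification) is exercised on cohorts drawn from a
controllable generative model: zero-mean multivariate Gaussian noise with a
prescribed stationary correlation matrix, band-pass filtered to the BOLD
low-frequency range, with the scanner's initial-volume discard emulated.

Group B receives a correlation shift (``effect_size``) on a configurable set
of edges; because the same zero-phase filter is applied to every ROI, the
instantaneous cross-correlation structure of the filtered series equals the
generating correlation matrix, so planted effects are recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "CohortSpec",
    "SubjectTimeSeries",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "modular_correlation",
    "random_correlation",
]


def modular_correlation(n_rois: int, n_modules: int = 4, r_within: float = 0.35,
                        r_between: float = 0.05) -> np.ndarray:
    """Block-structured correlation matrix: ``n_modules`` equal-ish modules,
    correlation ``r_within`` inside a module and ``r_between`` across modules."""
    module = np.arange(n_rois) * n_modules // n_rois
    same = module[:, None] == module[None, :]
    c = np.where(same, r_within, r_between)
    np.fill_diagonal(c, 1.0)
    return _nearest_correlation(c)


def random_correlation(n_rois: int, seed: int = 0, n_factors: int | None = None) -> np.ndarray:
    """Random factor-model correlation matrix (positive definite, unit diagonal)."""
    rng = np.random.default_rng(seed)
    k = n_factors if n_factors is not None else max(2, n_rois // 4)
    loadings = rng.normal(size=(n_rois, k)) / np.sqrt(k)
    c = loadings @ loadings.T + np.eye(n_rois)
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def _nearest_correlation(c: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue clipping)
    and rescale to unit diagonal."""
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    w = np.clip(w, eig_floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


@dataclasses.dataclass
class CohortSpec:
    """Cohort-level generative parameters.

    The acquisition defaults mirror a typical 3-year rs-fMRI protocol:
    140 volumes at TR = 2 s with the first 5 discarded (so T = 135 retained
    samples), signals band-limited to 0.01-0.1 Hz.
    """

    n_group_a: int = 142
    n_group_b: int = 136
    n_rois: int = 136
    n_volumes: int = 140
    n_discard: int = 5
    tr_seconds: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    base_covariance: np.ndarray | str = "modular"
    effect_edges: Sequence[tuple[int, int]] = ()
    effect_size: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def resolved_covariance(self) -> np.ndarray:
        if isinstance(self.base_covariance, str):
            if self.base_covariance == "modular":
                return modular_correlation(self.n_rois)
            if self.base_covariance == "random":
                return random_correlation(self.n_rois, seed=self.seed)
            raise ValueError(f"unknown covariance template {self.base_covariance!r}")
        return np.asarray(self.base_covariance, dtype=float)

    def validate(self) -> None:
        if self.n_rois < 4:
            raise ValueError("n_rois must be >= 4")
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed n_discard")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        lo, hi = self.band_hz
        if not (0.0 < lo < hi < nyquist):
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high < Nyquist={nyquist}")
        for i, j in self.effect_edges:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois) or i == j:
                raise ValueError(f"effect edge ({i}, {j}) invalid for M={self.n_rois}")
        c = self.resolved_covariance()
        if c.shape != (self.n_rois, self.n_rois):
            raise ValueError("base_covariance shape mismatch")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("base_covariance must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ValueError("base_covariance must have unit diagonal")


@dataclasses.dataclass
class SubjectTimeSeries:
    """One subject's ROI x time signal matrix with its group label."""

    subject_id: str
    group: str  # "A" (stable-like) or "B" (progressive-like)
    data: np.ndarray  # M x T
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D ROI x time matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite samples in subject {self.subject_id}")
        if np.any(self.data.var(axis=1) <= 0):
            raise ValueError(f"zero-variance ROI in subject {self.subject_id}")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _shifted_correlation(base: np.ndarray, edges: Sequence[tuple[int, int]],
                         delta: float, tol: float = 0.02) -> np.ndarray:
    """Shift the listed edges of a correlation matrix by ``delta`` and repair
    to the nearest PSD correlation matrix; fail if any target correlation then
    misses the requested value by more than ``tol``."""
    c = base.copy()
    for i, j in edges:
        target = c[i, j] + delta
        if not (-1.0 < target < 1.0):
            raise ValueError(
                f"effect_size {delta} pushes correlation at edge ({i}, {j}) to "
                f"{target:.3f}, outside (-1, 1)")
        c[i, j] = c[j, i] = target
    repaired = _nearest_correlation(c)
    bad = [(i, j) for i, j in edges if abs(repaired[i, j] - c[i, j]) > tol]
    if bad:
        raise ValueError(
            f"PSD repair moved planted correlations by more than {tol} at edges {bad}")
    return repaired


def _bandpass_sos(band_hz: tuple[float, float], tr_seconds: float, order: int = 4):
    fs = 1.0 / tr_seconds
    return signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")


def generate_cohort(spec: CohortSpec) -> list[SubjectTimeSeries]:
    """Draw a two-group cohort of band-limited correlated Gaussian time series.

    Group A subjects follow ``base_covariance``; group B follows the same
    matrix with ``effect_edges`` shifted by ``effect_size`` (PSD-repaired).
    Subject ``k`` of either group shares the same random substream, so with
    ``effect_size = 0`` the groups are bit-identical. Identical spec + seed
    gives bit-identical output.
    """
    spec.validate()
    base = _nearest_correlation(spec.resolved_covariance())
    shifted = (_shifted_correlation(base, spec.effect_edges, spec.effect_size)
               if spec.effect_edges and spec.effect_size != 0.0 else base)
    chol = {"A": np.linalg.cholesky(base + 1e-10 * np.eye(spec.n_rois)),
            "B": np.linalg.cholesky(shifted + 1e-10 * np.eye(spec.n_rois))}
    sos = _bandpass_sos(spec.band_hz, spec.tr_seconds)

    cohort: list[SubjectTimeSeries] = []
    for group, n_subjects in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        for k in range(n_subjects):
            # substream keyed by within-group index only: matched pairs across
            # groups share noise, isolating the planted effect
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, k]))
            white = rng.standard_normal((spec.n_rois, spec.n_volumes))
            raw = spec.noise_sd * (chol[group] @ white)
            filtered = signal.sosfiltfilt(sos, raw, axis=1)
            data = filtered[:, spec.n_discard:]
            cohort.append(SubjectTimeSeries(
                subject_id=f"sub-{group}{k:04d}", group=group,
                data=data, tr_seconds=spec.tr_seconds))
    return cohort


# ---------------------------------------------------------------------------
# plain-text persistence: one TSV matrix per subject + a label table + manifest

def write_cohort(cohort: Sequence[SubjectTimeSeries], directory: str | Path,
                 spec: CohortSpec | None = None) -> Path:
    """Write one TSV matrix per subject (rows = ROIs), a label table and a JSON
    manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    label_lines = []
    for ts in cohort:
        fname = f"{ts.subject_id}.tsv"
        np.savetxt(directory / fname, ts.data, delimiter="\t", fmt="%.17g")
        files.append({"subject_id": ts.subject_id, "file": fname,
                      "group": ts.group, "shape": list(ts.data.shape)})
        label_lines.append(f"{ts.subject_id}\t{ts.group}")
    (directory / "labels.tsv").write_text("\n".join(label_lines) + "\n")
    manifest = {
        "files": files,
        "tr_seconds": cohort[0].tr_seconds if cohort else None,
        "spec": _spec_to_json(spec) if spec is not None else None,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(directory: str | Path) -> list[SubjectTimeSeries]:
    """Read a cohort written by :func:`write_cohort`; full stored precision."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    labels = {}
    for line in (directory / "labels.tsv").read_text().splitlines():
        if not line.strip():
            continue
        sid, group = line.split("\t")
        if group not in ("A", "B"):
            raise ValueError(f"unknown group label {group!r} for subject {sid}")
        labels[sid] = group
    cohort = []
    for entry in manifest["files"]:
        path = directory / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"manifest lists missing file {entry['file']}")
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        if list(data.shape) != entry["shape"]:
            raise ValueError(
                f"shape mismatch for {entry['file']}: manifest says {entry['shape']}, "
                f"file has {list(data.shape)}")
        sid = entry["subject_id"]
        cohort.append(SubjectTimeSeries(
            subject_id=sid, group=labels[sid], data=data,
            tr_seconds=manifest.get("tr_seconds") or 2.0))
    return cohort


def _spec_to_json(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    if isinstance(d["base_covariance"], np.ndarray):
        d["base_covariance"] = d["base_covariance"].tolist()
    d["effect_edges"] = [list(e) for e in d["effect_edges"]]
    return d
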