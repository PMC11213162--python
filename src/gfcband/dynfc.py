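"""Tapered sliding-window functional connectivity and the group-informed
sparse adjacency.

Per-subject FC is the median over one-TR-shifted windows of the weighted
Pearson correlation, with window weights given by a rectangle (width 50 TR)
convolved with a Gaussian (sigma 3 TR). The full-band FC matrices of the two
groups are then compared edge-wise with a two-sided Wilcoxon rank-sum test;
edges significant at ``alpha`` form a shared mask, and each subject's sparse
FC keeps its own full-band values on masked edges. That sparse matrix is the
adjacency the graph-spectral stage operates on.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .synthetic import SubjectTimeSeries

__all__ = [
    "Taper",
    "FCMatrix",
    "SparseAdjacency",
    "build_taper",
    "sliding_window_fc",
    "edge_rank_tests",
    "group_sparse_adjacency",
]

BANDS = ("ffb", "lfb", "mfb", "hfb")


@dataclasses.dataclass
class Taper:
    """Non-negative window weights normalized to sum 1."""

    weights: np.ndarray
    rect_width: int = 50
    gauss_sigma: float = 3.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size < 2:
            raise ValueError("taper needs at least 2 weights")
        if np.any(self.weights < 0):
            raise ValueError("taper weights must be non-negative")
        self.weights = self.weights / self.weights.sum()

    @property
    def width(self) -> int:
        return self.weights.size


@dataclasses.dataclass
class FCMatrix:
    """Symmetric signed ROI x ROI connectivity, zero diagonal, one band."""

    values: np.ndarray
    band: str = "ffb"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if np.nanmax(np.abs(v), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("FC entries must lie in [-1, 1]")
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class SparseAdjacency:
    """Full-band FC values on group-significant edges, zero elsewhere."""

    values: np.ndarray
    mask: np.ndarray
    alpha: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("values must be exactly 0 off the mask")
        if np.any(np.diag(self.mask)):
            raise ValueError("mask must be false on the diagonal")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def build_taper(rect_width: int = 50, gauss_sigma: float = 3.0) -> Taper:
    """Convolve a unit rectangle with a discretized Gaussian truncated at
    +/- 4 sigma; length is ``rect_width + 2*ceil(4*sigma)``."""
    if rect_width < 2:
        raise ValueError("rect_width must be >= 2")
    if gauss_sigma <= 0:
        raise ValueError("gauss_sigma must be > 0")
    half = math.ceil(4.0 * gauss_sigma)
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / gauss_sigma) ** 2)
    rect = np.ones(rect_width)
    weights = np.convolve(rect, kernel, mode="full")
    return Taper(weights=weights, rect_width=rect_width, gauss_sigma=gauss_sigma)


def _weighted_corr_matrix(window: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation of the rows of ``window`` (weights sum 1).
    Zero-variance rows give NaN rows/columns."""
    mean = window @ w
    centered = window - mean[:, None]
    cov = (centered * w) @ centered.T
    var = np.diag(cov).copy()
    # a constant row has var ~ eps^2 * power, not exactly 0: flag it
    power = (window ** 2) @ w
    var[var <= 1e-20 * np.maximum(power, 1e-300)] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    return np.clip(corr, -1.0, 1.0, out=corr)


def sliding_window_fc(ts: SubjectTimeSeries | np.ndarray, taper: Taper,
                      shift: int = 1, band: str = "ffb",
                      subject_id: str | None = None,
                      undefined: str = "error") -> FCMatrix:
    """Median over tapered windows of the weighted Pearson correlation.

    Window starts are 0, shift, 2*shift, ... with only fully contained
    windows used: ``floor((T - W)/shift) + 1`` windows in total. Windows in
    which an ROI has zero weighted variance are excluded from that pair's
    median; if every window is excluded for some pair, an error is raised
    (``undefined="error"``) or the pair is set to 0 with a warning
    (``undefined="zero"`` — used for band-filtered series, where an ROI
    isolated in the sparse adjacency carries no energy in some bands).
    """
    data = ts.data if isinstance(ts, SubjectTimeSeries) else np.asarray(ts, float)
    sid = subject_id or (ts.subject_id if isinstance(ts, SubjectTimeSeries) else "")
    m, t = data.shape
    w = taper.weights
    if t < taper.width:
        raise ValueError(f"series length {t} shorter than taper width {taper.width}")
    n_windows = (t - taper.width) // shift + 1
    stack = np.empty((n_windows, m, m))
    for idx in range(n_windows):
        s = idx * shift
        stack[idx] = _weighted_corr_matrix(data[:, s:s + taper.width], w)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN pairs are handled by the `undefined` policy below
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(stack, axis=0)
    off_diag = ~np.eye(m, dtype=bool)
    n_undefined = int(np.isnan(median[off_diag]).sum())
    if n_undefined:
        if undefined == "zero":
            logging.getLogger(__name__).warning(
                "%d ROI pairs had no valid window (zero variance); set to 0",
                n_undefined // 2)
            median = np.nan_to_num(median, nan=0.0)
        else:
            raise ValueError(
                "some ROI pair has no valid window (zero variance everywhere)")
    np.fill_diagonal(median, 0.0)
    return FCMatrix(values=median, band=band, subject_id=sid)


def edge_rank_tests(fcs_a: Sequence[FCMatrix], fcs_b: Sequence[FCMatrix]) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per upper-triangle edge, returned
    as a symmetric M x M matrix (diagonal 1). Uses the tie-corrected normal
    approximation with continuity correction; edges constant across all
    subjects get p = 1."""
    if len(fcs_a) < 2 or len(fcs_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    m = fcs_a[0].n_rois
    iu = np.triu_indices(m, k=1)
    a = np.stack([fc.values[iu] for fc in fcs_a])  # n_a x n_edges
    b = np.stack([fc.values[iu] for fc in fcs_b])
    pooled = np.vstack([a, b])
    constant = np.all(pooled == pooled[0], axis=0)
    pvals = np.ones(iu[0].size)
    varying = ~constant
    if np.any(varying):
        res = stats.mannwhitneyu(a[:, varying], b[:, varying], axis=0,
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        pvals[varying] = np.minimum(res.pvalue, 1.0)
    pmat = np.ones((m, m))
    pmat[iu] = pvals
    pmat[(iu[1], iu[0])] = pvals
    return pmat


def group_sparse_adjacency(fcs_a: Sequence[FCMatrix], fcs_b: Sequence[FCMatrix],
                           alpha: float = 0.05, fdr: bool = False,
                           ) -> tuple[np.ndarray, list[SparseAdjacency]]:
    """Shared significant-edge mask and per-subject sparse adjacencies.

    Edges whose full-band FC differs between groups at ``p < alpha``
    (optionally Benjamini-Hochberg adjusted with ``fdr=True``) form the mask;
    each subject keeps its own full-band values there, zero elsewhere.
    """
    pmat = edge_rank_tests(fcs_a, fcs_b)
    m = pmat.shape[0]
    iu = np.triu_indices(m, k=1)
    pvals = pmat[iu]
    if fdr:
        pvals = stats.false_discovery_control(pvals, method="bh")
    sig = pvals < alpha
    mask = np.zeros((m, m), dtype=bool)
    mask[iu] = sig
    mask |= mask.T
    adjacencies = [
        SparseAdjacency(values=np.where(mask, fc.values, 0.0), mask=mask,
                        alpha=alpha, subject_id=fc.subject_id)
        for fc in list(fcs_a) + list(fcs_b)
    ]
    return mask, adjacencies
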