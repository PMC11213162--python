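"""Graph Fourier analysis of ROI signals on the subject's sparse adjacency.

The combinatorial Laplacian L = D - A of the (by default absolute-valued)
sparse FC adjacency is eigendecomposed; eigenvectors ordered by ascending
eigenvalue are the graph frequency modes. The GFT projects an ROI x time
signal onto these modes; band filtering keeps the first third of modes (low
frequency, signal aligned with the connectivity structure), the last third
(high frequency, liberal with respect to it), or the middle remainder.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.sparse.csgraph import connected_components

from .dynfc import SparseAdjacency

__all__ = [
    "GraphSpectrum",
    "BandDefinition",
    "laplacian",
    "eigendecompose",
    "band_split",
    "gft",
    "igft",
    "band_filter",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GraphSpectrum:
    """Orthonormal Laplacian eigenbasis, ascending eigenvalue order."""

    eigenvectors: np.ndarray  # M x M, columns are modes
    eigenvalues: np.ndarray  # length M, non-decreasing
    source_id: str = ""

    def __post_init__(self) -> None:
        v, lam = self.eigenvectors, self.eigenvalues
        if v.shape[0] != v.shape[1] or lam.shape != (v.shape[0],):
            raise ValueError("inconsistent spectrum shapes")
        if np.any(np.diff(lam) < -1e-10):
            raise ValueError("eigenvalues must be non-decreasing")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    """Disjoint low/middle/high mode index sets covering all M modes."""

    lfb_modes: np.ndarray
    mfb_modes: np.ndarray
    hfb_modes: np.ndarray

    def modes(self, band: str) -> np.ndarray:
        return {"lfb": self.lfb_modes, "mfb": self.mfb_modes,
                "hfb": self.hfb_modes}[band]


def laplacian(adjacency: SparseAdjacency | np.ndarray, signed: bool = False) -> np.ndarray:
    """Combinatorial Laplacian L = D - A with D_kk = sum_j A_kj.

    By default edge weights enter as absolute values so L is PSD and the
    low/high frequency ordering is well defined; ``signed=True`` uses the raw
    signed weights instead.
    """
    a = adjacency.values if isinstance(adjacency, SparseAdjacency) else np.asarray(adjacency, float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not signed:
        a = np.abs(a)
    deg = a.sum(axis=1)
    return np.diag(deg) - a


def eigendecompose(lap: np.ndarray, source_id: str = "") -> GraphSpectrum:
    """Full symmetric eigendecomposition with a deterministic sign convention:
    each eigenvector's largest-magnitude entry (first index on ties) is made
    positive."""
    if not np.all(np.isfinite(lap)):
        raise ValueError("non-finite entries in Laplacian")
    lam, v = np.linalg.eigh((lap + lap.T) / 2.0)
    for k in range(v.shape[1]):
        pivot = np.argmax(np.abs(v[:, k]))
        if v[pivot, k] < 0:
            v[:, k] = -v[:, k]
    n_zero = int(np.sum(np.abs(lam) < 1e-8))
    if n_zero > 1:
        logger.warning("adjacency has %d connected components (%d zero modes)",
                       n_zero, n_zero)
    return GraphSpectrum(eigenvectors=v, eigenvalues=lam, source_id=source_id)


def n_components(adjacency: np.ndarray) -> int:
    """Connected components of the (absolute) adjacency's support."""
    return connected_components(np.abs(adjacency) > 0, directed=False)[0]


def band_split(m: int) -> BandDefinition:
    """Low = first floor(M/3) modes, high = last floor(M/3), middle = rest.

    For M = 136 this yields the 45/46/45 split of the frequency modes.
    """
    if m < 3:
        raise ValueError("need at least 3 modes to split into bands")
    third = m // 3
    return BandDefinition(
        lfb_modes=np.arange(third),
        mfb_modes=np.arange(third, m - third),
        hfb_modes=np.arange(m - third, m),
    )


def gft(x: np.ndarray, spectrum: GraphSpectrum) -> np.ndarray:
    """Graph Fourier transform: x_tilde = V^T x."""
    x = np.asarray(x, float)
    if x.shape[0] != spectrum.n_modes:
        raise ValueError(f"signal has {x.shape[0]} rows, spectrum has "
                         f"{spectrum.n_modes} modes")
    return spectrum.eigenvectors.T @ x


def igft(x_tilde: np.ndarray, spectrum: GraphSpectrum) -> np.ndarray:
    """Inverse GFT: x = V x_tilde."""
    x_tilde = np.asarray(x_tilde, float)
    if x_tilde.shape[0] != spectrum.n_modes:
        raise ValueError("mode-count mismatch")
    return spectrum.eigenvectors @ x_tilde


def band_filter(x: np.ndarray, spectrum: GraphSpectrum,
                modes: np.ndarray) -> np.ndarray:
    """Ideal band filter x_F = V G V^T x, G diagonal with ones on ``modes``."""
    modes = np.asarray(modes)
    if modes.size == 0:
        raise ValueError("empty frequency band")
    x_tilde = gft(x, spectrum)
    g = np.zeros(spectrum.n_modes)
    g[modes] = 1.0
    return igft(g[:, None] * x_tilde, spectrum)
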