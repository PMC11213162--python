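"""Signed-network features of an FC matrix: 25 metrics per frequency band.

Per band the feature families are: 9 global graph metrics (efficiency,
eccentricity summaries, assortativity, clustering, eigenvector centrality,
strength, modularity), 7 minimum-spanning-tree metrics (hop radius/diameter,
max degree, leaf fraction, max betweenness, tree hierarchy LF/(2*BCmax),
kappa = sum(k^2)/sum(k)), 5 triadic-balance metrics (the T0..T3 census of
signed triangles plus the network energy -mean triple product), 2 hub-tendency
indices (sum D^2 / sum D over positive and over negative degrees), and the
counts of positive and negative links. Across the four bands (full, low,
middle, high) this yields the 100-feature vector per subject.

Conventions: path-based metrics use the positive-weight subgraph with edge
length 1/w; the MST is built on distance 1 - w over positive edges; metrics
that are undefined on a given matrix are flagged NaN and imputed with the
cohort median when the feature table is assembled.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .dynfc import FCMatrix

__all__ = [
    "FAMILY_METRICS",
    "BAND_ORDER",
    "feature_names",
    "graph_global_metrics",
    "mst_metrics",
    "triad_metrics",
    "tmh_metrics",
    "link_counts",
    "extract_features",
    "assemble_feature_table",
    "data_dictionary",
]

logger = logging.getLogger(__name__)

BAND_ORDER = ("ffb", "lfb", "mfb", "hfb")

FAMILY_METRICS: dict[str, tuple[str, ...]] = {
    "graph": ("ge", "me", "radius", "diameter", "ac", "mcc", "mec", "ms",
              "modularity"),
    "mst": ("radius", "diameter", "deg_max", "lf", "bc_max", "t_h", "kappa"),
    "triad": ("t0", "t1", "t2", "t3", "un"),
    "tmh": ("tmh_p", "tmh_n"),
    "links": ("n_pos", "n_neg"),
}


def feature_names() -> list[str]:
    """The fixed 100-name feature order: bands x (graph, mst, triad, tmh, links)."""
    return [f"{band}.{family}.{metric}"
            for band in BAND_ORDER
            for family, metrics in FAMILY_METRICS.items()
            for metric in metrics]


def _values(fc: FCMatrix | np.ndarray) -> np.ndarray:
    v = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    v = v.copy()
    np.fill_diagonal(v, 0.0)
    return v


def _positive_graph(w: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    ii, jj = np.nonzero(np.triu(w, k=1) > 0)
    g.add_weighted_edges_from((int(i), int(j), float(w[i, j])) for i, j in zip(ii, jj))
    return g


def graph_global_metrics(fc: FCMatrix | np.ndarray, modularity_seed: int = 0,
                         n_restarts: int = 10) -> dict[str, float]:
    """Nine global metrics of the weighted FC graph.

    Shortest paths use length 1/w on positive edges. GE is the mean inverse
    shortest-path length (disconnected pairs contribute 0); eccentricity
    summaries are NaN on a disconnected positive subgraph. AC is the unweighted
    degree-degree correlation over positive edges (0 with a warning when
    degrees are constant). MCC is the geometric-mean weighted clustering
    coefficient averaged over ROIs; MEC the mean of the unit-norm principal
    eigenvector of |FC|; MS the mean signed strength; modularity the best
    Louvain partition quality over ``n_restarts`` seeded restarts.
    """
    w = _values(fc)
    m = w.shape[0]
    pos = np.where(w > 0, w, 0.0)

    out: dict[str, float] = {}

    # --- path metrics on lengths 1/w
    if not np.any(pos > 0):
        out.update(ge=np.nan, me=np.nan, radius=np.nan, diameter=np.nan)
    else:
        with np.errstate(divide="ignore"):
            lengths = np.where(pos > 0, 1.0 / np.where(pos > 0, pos, 1.0), 0.0)
        dist = shortest_path(lengths, method="D", directed=False)
        off = ~np.eye(m, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
        out["ge"] = float(inv[off].mean())
        ecc = np.where(np.isfinite(dist).all(axis=1), dist.max(axis=1), np.inf)
        if np.all(np.isfinite(ecc)):
            out["me"] = float(ecc.mean())
            out["radius"] = float(ecc.min())
            out["diameter"] = float(ecc.max())
        else:
            out.update(me=np.nan, radius=np.nan, diameter=np.nan)

    # --- assortativity on the positive subgraph (unweighted degrees)
    g = _positive_graph(pos)
    if g.number_of_edges() == 0:
        out["ac"] = np.nan
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            ac = nx.degree_assortativity_coefficient(g)
        if not np.isfinite(ac):
            logger.warning("assortativity undefined (constant degrees); flagged 0")
            ac = 0.0
        out["ac"] = float(ac)

    # --- weighted clustering (geometric-mean triangle formula, weights in [0,1])
    w3 = np.cbrt(pos)
    cyc3 = np.diag(w3 @ w3 @ w3)
    deg = (pos > 0).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, cyc3 / np.where(denom > 0, denom, 1), 0.0)
    out["mcc"] = float(ci.mean())

    # --- mean eigenvector centrality of |FC| (Perron vector, unit 2-norm)
    absw = np.abs(w)
    if np.any(absw > 0):
        lam, vec = np.linalg.eigh(absw)
        principal = np.abs(vec[:, -1])
        principal = principal / np.linalg.norm(principal)
        out["mec"] = float(principal.mean())
    else:
        out["mec"] = np.nan

    # --- mean signed strength
    out["ms"] = float(w.sum(axis=1).mean())

    # --- Louvain modularity on positive weights, gamma=1, best of restarts
    if g.number_of_edges() == 0:
        out["modularity"] = np.nan
    else:
        best = -np.inf
        for r in range(n_restarts):
            communities = nx.community.louvain_communities(
                g, weight="weight", resolution=1.0, seed=modularity_seed + r)
            q = nx.community.modularity(g, communities, weight="weight",
                                        resolution=1.0)
            best = max(best, q)
        out["modularity"] = float(best)

    return out


def minimum_spanning_tree(fc: FCMatrix | np.ndarray) -> nx.Graph:
    """MST of the positive subgraph under the correlation distance d = 1 - w."""
    w = _values(fc)
    g = _positive_graph(np.where(w > 0, w, 0.0))
    for i, j, d in g.edges(data=True):
        d["distance"] = 1.0 - d["weight"]
    if g.number_of_nodes() < w.shape[0] or not nx.is_connected(g):
        raise ValueError("positive-weight subgraph is disconnected; MST undefined")
    return nx.minimum_spanning_tree(g, weight="distance")


def mst_metrics(fc: FCMatrix | np.ndarray) -> dict[str, float]:
    """Seven MST metrics on the unweighted tree topology (hop distances).

    BC_max is normalized by (M-1)(M-2)/2; tree hierarchy T_H = LF/(2*BC_max);
    kappa = sum(k^2)/sum(k) measures degree-distribution breadth.
    """
    tree = fc if isinstance(fc, nx.Graph) else minimum_spanning_tree(fc)
    m = tree.number_of_nodes()
    if m < 3:
        raise ValueError("MST metrics need at least 3 ROIs")
    ecc = nx.eccentricity(tree)  # hop counts
    degrees = np.array([d for _, d in tree.degree()], dtype=float)
    leaves = float(np.sum(degrees == 1))
    bc = nx.betweenness_centrality(tree, normalized=True)
    bc_max = float(max(bc.values()))
    lf = leaves / m
    return {
        "radius": float(min(ecc.values())),
        "diameter": float(max(ecc.values())),
        "deg_max": float(degrees.max()),
        "lf": lf,
        "bc_max": bc_max,
        "t_h": lf / (2.0 * bc_max) if bc_max > 0 else np.nan,
        "kappa": float((degrees ** 2).sum() / degrees.sum()),
    }


def triad_metrics(fc: FCMatrix | np.ndarray) -> dict[str, float]:
    """Signed-triangle census and network energy.

    Triads are ROI triples whose three edges are all nonzero, classified by
    their count of positive edges: T3 (+++ strongly balanced), T2 (++-
    strongly unbalanced), T1 (+-- weakly balanced), T0 (--- weakly
    unbalanced). The energy is Un = -sum of the triads' edge-weight triple
    products divided by the number of triads; all-NaN when no triad exists.
    """
    w = _values(fc)
    p = (w > 0).astype(float)
    n = (w < 0).astype(float)
    b = p + n  # nonzero support
    n_triads = np.trace(b @ b @ b) / 6.0
    if n_triads == 0:
        return {k: np.nan for k in FAMILY_METRICS["triad"]}
    t3 = np.trace(p @ p @ p) / 6.0
    t0 = np.trace(n @ n @ n) / 6.0
    t2 = float(np.sum((p @ p) * n)) / 2.0
    t1 = float(np.sum((n @ n) * p)) / 2.0
    energy = np.trace(w @ w @ w) / 6.0
    return {"t0": float(t0), "t1": float(t1), "t2": float(t2), "t3": float(t3),
            "un": float(-energy / n_triads)}


def tmh_metrics(fc: FCMatrix | np.ndarray) -> dict[str, float]:
    """Tendency-to-make-hub indices sum(D_i^2)/sum(D_i), computed separately
    over positive degrees and over magnitudes of negative degrees; a side with
    no links is flagged NaN."""
    w = _values(fc)
    d_pos = np.where(w > 0, w, 0.0).sum(axis=1)
    d_neg = np.abs(np.where(w < 0, w, 0.0)).sum(axis=1)
    out = {}
    for key, d in (("tmh_p", d_pos), ("tmh_n", d_neg)):
        total = d.sum()
        if total == 0:
            logger.warning("%s undefined: no links of that sign", key)
            out[key] = np.nan
        else:
            out[key] = float((d ** 2).sum() / total)
    return out


def link_counts(fc: FCMatrix | np.ndarray) -> dict[str, float]:
    """Counts of strictly positive and strictly negative upper-triangle entries."""
    w = _values(fc)
    iu = np.triu_indices(w.shape[0], k=1)
    upper = w[iu]
    return {"n_pos": float(np.sum(upper > 0)), "n_neg": float(np.sum(upper < 0))}


def _band_features(fc: FCMatrix | np.ndarray, band: str,
                   modularity_seed: int = 0) -> dict[str, float]:
    feats: dict[str, float] = {}
    for metric, value in graph_global_metrics(fc, modularity_seed=modularity_seed).items():
        feats[f"{band}.graph.{metric}"] = value
    try:
        mst = mst_metrics(fc)
    except ValueError as exc:
        logger.warning("MST metrics undefined for band %s: %s", band, exc)
        mst = {k: np.nan for k in FAMILY_METRICS["mst"]}
    for metric, value in mst.items():
        feats[f"{band}.mst.{metric}"] = value
    for metric, value in triad_metrics(fc).items():
        feats[f"{band}.triad.{metric}"] = value
    for metric, value in tmh_metrics(fc).items():
        feats[f"{band}.tmh.{metric}"] = value
    for metric, value in link_counts(fc).items():
        feats[f"{band}.links.{metric}"] = value
    return feats


def extract_features(fc_ffb: FCMatrix | np.ndarray, fc_lfb: FCMatrix | np.ndarray,
                     fc_mfb: FCMatrix | np.ndarray, fc_hfb: FCMatrix | np.ndarray,
                     modularity_seed: int = 0) -> dict[str, float]:
    """The 100-entry named feature vector for one subject (25 metrics x 4 bands,
    in the fixed :func:`feature_names` order). Undefined metrics are NaN here
    and imputed at table-assembly time."""
    fcs = {"ffb": fc_ffb, "lfb": fc_lfb, "mfb": fc_mfb, "hfb": fc_hfb}
    shapes = {np.asarray(_values(fc)).shape for fc in fcs.values()}
    if len(shapes) != 1:
        raise ValueError("the four band FC matrices must have identical shape")
    feats: dict[str, float] = {}
    for band in BAND_ORDER:
        feats.update(_band_features(fcs[band], band, modularity_seed=modularity_seed))
    assert list(feats) == feature_names()
    return feats


def assemble_feature_table(rows: Sequence[Mapping[str, float]],
                           subject_ids: Sequence[str],
                           groups: Sequence[str]) -> pd.DataFrame:
    """Subjects x 100 feature table with cohort-median imputation of flagged
    (NaN) entries; the imputed count is logged."""
    table = pd.DataFrame(list(rows), columns=feature_names())
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d undefined feature entries with cohort medians",
                    n_missing)
        table = table.fillna(table.median())
        all_undefined = table.columns[table.isna().all()]
        if len(all_undefined):
            logger.warning("features undefined for every subject, set to 0: %s",
                           list(all_undefined))
            table[all_undefined] = 0.0
    table = table.copy()  # defragment before inserting id columns
    table.insert(0, "group", list(groups))
    table.insert(0, "subject_id", list(subject_ids))
    return table


def data_dictionary() -> pd.DataFrame:
    """Feature-name to band/family/metric mapping (for the data-dictionary TSV)."""
    records = []
    for name in feature_names():
        band, family, metric = name.split(".")
        records.append({"feature": name, "band": band, "family": family,
                        "metric": metric})
    return pd.DataFrame(records)


def family_columns(family: str, bands: Sequence[str] = BAND_ORDER) -> list[str]:
    """Feature names of one family across the given bands (e.g. the 36 graph
    features, 28 MST features, 36 triad+tmh+links features)."""
    if family == "triad_tmh_links":
        fams = ("triad", "tmh", "links")
    else:
        fams = (family,)
    return [n for n in feature_names()
            if n.split(".")[0] in bands and n.split(".")[1] in fams]


def band_columns(band: str) -> list[str]:
    """The 25 feature names of one band."""
    return [n for n in feature_names() if n.split(".")[0] == band]
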