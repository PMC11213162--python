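"""Network-feature families against closed forms and brute-force oracles."""

import numpy as np
import pytest

from gfcband.features import (BAND_ORDER, FAMILY_METRICS, assemble_feature_table,
                              band_columns, extract_features, family_columns,
                              feature_names, graph_global_metrics, link_counts,
                              minimum_spanning_tree, mst_metrics, triad_metrics,
                              tmh_metrics)

from . import oracles
from .conftest import random_positive_fc, random_signed_fc


def complete_graph(m, weight=1.0):
    a = np.full((m, m), weight)
    np.fill_diagonal(a, 0.0)
    return a


def star_graph(m=5, weight=1.0):
    a = np.zeros((m, m))
    a[0, 1:] = a[1:, 0] = weight
    return a


class TestGraphGlobalMetrics:
    def test_complete_k4_closed_forms(self):
        g = graph_global_metrics(complete_graph(4))
        assert g["ge"] == pytest.approx(1.0)
        assert g["me"] == pytest.approx(1.0)
        assert g["radius"] == pytest.approx(1.0)
        assert g["diameter"] == pytest.approx(1.0)
        assert g["mcc"] == pytest.approx(1.0)
        assert g["ms"] == pytest.approx(3.0)
        assert g["mec"] == pytest.approx(0.5)
        assert g["modularity"] == pytest.approx(0.0, abs=1e-12)
        assert g["ac"] == 0.0  # regular graph: flagged 0

    def test_star_closed_forms(self):
        g = graph_global_metrics(star_graph(5))
        assert g["radius"] == pytest.approx(1.0)
        assert g["diameter"] == pytest.approx(2.0)
        assert g["me"] == pytest.approx(1.8)
        assert g["ms"] == pytest.approx(1.6)
        assert g["mcc"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_path_metrics_match_dijkstra_oracle(self, seed):
        fc = random_positive_fc(8, seed=seed)
        got = graph_global_metrics(fc)
        expected = oracles.path_metrics(fc)
        for key in ("ge", "me", "radius", "diameter"):
            assert got[key] == pytest.approx(expected[key], abs=1e-10)

    def test_clustering_matches_triple_loop(self):
        fc = random_positive_fc(9, seed=3)
        got = graph_global_metrics(fc)["mcc"]
        assert got == pytest.approx(oracles.clustering_geometric(fc), abs=1e-10)

    def test_all_nonpositive_flags_path_metrics(self):
        g = graph_global_metrics(-random_positive_fc(5, seed=4))
        assert np.isnan(g["ge"]) and np.isnan(g["diameter"])

    def test_roi_permutation_invariance(self):
        rng = np.random.default_rng(5)
        fc = random_signed_fc(8, seed=5)
        perm = rng.permutation(8)
        g1 = graph_global_metrics(fc)
        g2 = graph_global_metrics(fc[np.ix_(perm, perm)])
        for key, val in g1.items():
            assert g2[key] == pytest.approx(val, abs=1e-9), key


class TestMSTMetrics:
    def test_star_closed_forms(self):
        m = mst_metrics(star_graph(5))
        assert m == pytest.approx({"radius": 1.0, "diameter": 2.0,
                                   "deg_max": 4.0, "lf": 0.8, "bc_max": 1.0,
                                   "t_h": 0.4, "kappa": 2.5})

    def test_path_of_four(self):
        a = np.zeros((4, 4))
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 0.9
        m = mst_metrics(a)
        assert m["kappa"] == pytest.approx(10.0 / 6.0)
        assert m["lf"] == pytest.approx(0.5)
        assert m["deg_max"] == 2.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_edge_set_matches_kruskal(self, seed):
        fc = random_positive_fc(10, seed=seed)  # unique weights a.s.
        tree = minimum_spanning_tree(fc)
        got = {frozenset(e) for e in tree.edges()}
        assert got == oracles.kruskal_mst_edges(fc)

    def test_kappa_at_least_mean_degree(self):
        for seed in range(5):
            fc = random_positive_fc(12, seed=seed)
            m = mst_metrics(fc)
            mean_degree = 2.0 * 11 / 12  # a tree has M-1 edges
            assert m["kappa"] >= mean_degree - 1e-12

    def test_disconnected_positive_subgraph_rejected(self):
        a = np.zeros((6, 6))
        a[0, 1] = a[1, 0] = 0.5
        a[2, 3] = a[3, 2] = 0.5
        with pytest.raises(ValueError, match="disconnected"):
            mst_metrics(a)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mst_metrics(complete_graph(2, 0.5))


class TestTriadMetrics:
    def test_all_positive_triangle(self):
        fc = complete_graph(3, 0.5)
        t = triad_metrics(fc)
        assert (t["t0"], t["t1"], t["t2"], t["t3"]) == (0, 0, 0, 1)
        assert t["un"] == pytest.approx(-0.125)

    def test_unbalanced_triangle(self):
        fc = complete_graph(3, 1.0)
        fc[1, 2] = fc[2, 1] = -1.0
        t = triad_metrics(fc)
        assert t["t2"] == 1
        assert t["un"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_census_matches_exhaustive_oracle(self, seed):
        fc = random_signed_fc(10, seed=seed)
        got = triad_metrics(fc)
        expected = oracles.triad_census(fc)
        for key in ("t0", "t1", "t2", "t3"):
            assert got[key] == expected[key]
        assert got["un"] == pytest.approx(expected["un"], abs=1e-10)
        assert got["t0"] + got["t1"] + got["t2"] + got["t3"] == 120  # C(10,3)

    def test_sparse_support_counts_qualifying_triples(self):
        fc = random_signed_fc(9, seed=3, density=0.5)
        got = triad_metrics(fc)
        expected = oracles.triad_census(fc)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, abs=1e-10)

    def test_no_triads_flagged(self):
        t = triad_metrics(star_graph(5))  # star has no triangles
        assert all(np.isnan(v) for v in t.values())


class TestTMH:
    def test_star_positive(self):
        t = tmh_metrics(star_graph(5))
        assert t["tmh_p"] == pytest.approx(2.5)  # 20 / 8
        assert np.isnan(t["tmh_n"])

    def test_uniform_complete_equals_common_degree(self):
        c = 0.3
        t = tmh_metrics(complete_graph(5, c))
        assert t["tmh_p"] == pytest.approx(4 * c)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_loop_oracle(self, seed):
        fc = random_signed_fc(12, seed=seed)
        got = tmh_metrics(fc)
        expected = oracles.tmh(fc)
        assert got["tmh_p"] == pytest.approx(expected["tmh_p"], abs=1e-12)
        assert got["tmh_n"] == pytest.approx(expected["tmh_n"], abs=1e-12)

    def test_linear_scaling(self):
        fc = random_signed_fc(8, seed=2)
        t1, t2 = tmh_metrics(fc), tmh_metrics(3.0 * fc)
        assert t2["tmh_p"] == pytest.approx(3.0 * t1["tmh_p"])
        assert t2["tmh_n"] == pytest.approx(3.0 * t1["tmh_n"])


class TestLinkCounts:
    def test_all_positive_k4(self):
        assert link_counts(complete_graph(4)) == {"n_pos": 6.0, "n_neg": 0.0}

    def test_negation_swaps_counts(self):
        fc = random_signed_fc(7, seed=1)
        c1, c2 = link_counts(fc), link_counts(-fc)
        assert c1["n_pos"] == c2["n_neg"] and c1["n_neg"] == c2["n_pos"]

    def test_total_equals_nonzero_entries(self):
        fc = random_signed_fc(9, seed=2, density=0.6)
        c = link_counts(fc)
        iu = np.triu_indices(9, k=1)
        assert c["n_pos"] + c["n_neg"] == np.count_nonzero(fc[iu])


class TestFeatureVector:
    def test_bookkeeping(self):
        """100 features: 25 per band, 9/7/5/2/2 per family, pools 36/28/36."""
        names = feature_names()
        assert len(names) == 100
        for band in BAND_ORDER:
            assert len(band_columns(band)) == 25
        sizes = {fam: len(m) for fam, m in FAMILY_METRICS.items()}
        assert sizes == {"graph": 9, "mst": 7, "triad": 5, "tmh": 2, "links": 2}
        assert len(family_columns("graph")) == 36
        assert len(family_columns("mst")) == 28
        assert len(family_columns("triad_tmh_links")) == 36

    def test_determinism_and_permutation_invariance(self):
        rng = np.random.default_rng(9)
        mats = [random_signed_fc(8, seed=s) for s in (10, 11, 12, 13)]
        f1 = extract_features(*mats)
        f2 = extract_features(*mats)
        assert f1 == f2
        perm = rng.permutation(8)
        f3 = extract_features(*(m[np.ix_(perm, perm)] for m in mats))
        for key, val in f1.items():
            if np.isfinite(val):
                assert f3[key] == pytest.approx(val, abs=1e-9), key

    def test_imputation_uses_cohort_median(self):
        rows = [{n: 1.0 for n in feature_names()},
                {n: 3.0 for n in feature_names()},
                {n: (np.nan if n == "ffb.graph.ge" else 2.0)
                 for n in feature_names()}]
        table = assemble_feature_table(rows, ["s1", "s2", "s3"], ["A", "A", "B"])
        assert table.shape == (3, 102)
        assert table.loc[2, "ffb.graph.ge"] == 2.0  # median of 1 and 3
        assert not table.drop(columns=["subject_id", "group"]).isna().any().any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shape"):
            extract_features(random_signed_fc(6), random_signed_fc(6),
                             random_signed_fc(6), random_signed_fc(7))
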