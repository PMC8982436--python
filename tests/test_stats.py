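"""Filtering, TS classes, neighbor graphs and dispersion statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from embryoquant import SimConfig
from embryoquant.stats import (
    build_neighbor_graph,
    delaunay_graph,
    filter_low_expression,
    group_by_ts,
    label_adjacency_graph,
    local_dispersion,
)
from embryoquant.synth import (
    assign_domains,
    build_cell_lattice,
    simulate_transcription,
)


def _cells(counts, ts=None, border=None):
    n = len(counts)
    return pd.DataFrame({
        "label": np.arange(1, n + 1),
        "mrna_count": counts,
        "ts_count": ts if ts is not None else np.zeros(n, dtype=int),
        "border": border if border is not None else np.zeros(n, dtype=bool),
    })


class TestFilter:
    def test_fewer_than_ten_is_strict(self):
        kept = filter_low_expression(_cells([0, 9, 10, 11]))
        assert kept["mrna_count"].tolist() == [10, 11]

    def test_zero_threshold_is_identity(self):
        cells = _cells([0, 3, 7])
        assert filter_low_expression(cells, 0).equals(cells)

    def test_all_zero_table_empties(self):
        assert len(filter_low_expression(_cells([0, 0, 0]))) == 0


class TestTSGroups:
    def test_partition_sizes(self):
        groups = group_by_ts(_cells([10] * 5, ts=[0, 1, 2, 3, 4]))
        assert {k: len(v) for k, v in groups.items()} == \
            {"0": 1, "1": 1, "2+": 3}

    def test_empty_table(self):
        groups = group_by_ts(_cells([]))
        assert all(len(v) == 0 for v in groups.values())

    def test_negative_ts_rejected(self):
        with pytest.raises(ValueError):
            group_by_ts(_cells([5], ts=[-1]))

    def test_class_proportions_follow_binomial_law(self):
        """TS classes are binomial in the allele ON-probability."""
        cfg = SimConfig(n_cols=25, n_rows=20, cell_pitch_px=16, seed=6,
                        domains={"rho": (0.0, 1.0), "mir9a": (0.0, 1.0)})
        cm = build_cell_lattice(cfg)
        gt = simulate_transcription(cm, assign_domains(cm, cfg), cfg, "WT")
        groups = group_by_ts(gt.cells.rename(columns={"true_ts": "ts_count"}))
        n = cm.n_cells
        p_on = cfg.k_on / (cfg.k_on + cfg.k_off)
        probs = {"0": (1 - p_on) ** 2, "1": 2 * p_on * (1 - p_on),
                 "2+": p_on**2}
        for cls, p in probs.items():
            # exact binomial test at 0.1% keeps false alarms negligible
            res = binomtest(len(groups[cls]), n, p)
            assert res.pvalue > 1e-3


class TestNeighborGraph:
    def test_grid_adjacency_degrees(self, square_grid_labels):
        g = label_adjacency_graph(square_grid_labels)
        degrees = {v: g.degree(v) for v in g.nodes}
        assert degrees[1] == 2 and degrees[2] == 3 and degrees[5] == 4
        assert g.nodes[5]["border"] is False
        assert g.nodes[1]["border"] is True

    def test_single_cell_graph(self):
        g = label_adjacency_graph(np.ones((5, 5), dtype=int))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_definitions_agree_on_regular_lattice_interior(self):
        cfg = SimConfig(n_cols=8, n_rows=6, cell_pitch_px=24, jitter=0.0)
        cm = build_cell_lattice(cfg)
        ga = label_adjacency_graph(cm.label_image)
        gd = delaunay_graph(cm.cells["label"],
                            cm.cells[["cx", "cy"]].to_numpy(),
                            border_labels=cm.border_labels())
        interior = [v for v in ga.nodes if not ga.nodes[v]["border"]]
        for v in interior:
            na = {u for u in ga.neighbors(v) if not ga.nodes[u]["border"]}
            nd = {u for u in gd.neighbors(v) if not gd.nodes[u]["border"]}
            assert na == nd

    def test_graph_symmetric_on_random_embryos(self):
        for seed in (0, 1, 2):
            cfg = SimConfig(n_cols=6, n_rows=4, cell_pitch_px=20,
                            jitter=0.35, seed=seed)
            cm = build_cell_lattice(cfg)
            g = build_neighbor_graph(cm.label_image)
            assert isinstance(g, nx.Graph)  # undirected == symmetric
            assert all(not g.has_edge(v, v) for v in g.nodes)


class TestDispersion:
    def _star(self, counts, border_focal=False):
        """Focal cell 1 with neighbors 2..n."""
        n = len(counts)
        g = nx.Graph()
        g.add_node(1, border=border_focal)
        for v in range(2, n + 1):
            g.add_node(v, border=False)
            g.add_edge(1, v)
        return _cells(counts), g

    def test_constant_counts_give_zero_dispersion(self):
        cells, g = self._star([5, 5, 5, 5])
        row = local_dispersion(cells, g).set_index("label").loc[1]
        assert row["fano"] == 0.0 and row["cv"] == 0.0

    def test_hand_computed_cluster(self):
        # counts {2,4,6}: mean 4, sample variance 4 -> FF 1.0, CV 0.5
        cells, g = self._star([2, 4, 6])
        row = local_dispersion(cells, g).set_index("label").loc[1]
        assert row["cluster_mean"] == pytest.approx(4.0)
        assert row["cluster_variance"] == pytest.approx(4.0)
        assert row["fano"] == pytest.approx(1.0)
        assert row["cv"] == pytest.approx(0.5)

    def test_small_or_zero_mean_clusters_are_missing(self):
        cells, g = self._star([3, 4])  # cluster of 2
        assert np.isnan(local_dispersion(cells, g)["fano"]).all()
        cells0, g0 = self._star([0, 0, 0, 0])
        row = local_dispersion(cells0, g0).set_index("label").loc[1]
        assert np.isnan(row["fano"]) and np.isnan(row["cv"])

    def test_border_cells_excluded_as_focal(self):
        cells, g = self._star([2, 4, 6], border_focal=True)
        disp = local_dispersion(cells, g)
        assert 1 not in disp["label"].tolist()

    def test_include_focal_flag(self):
        cells, g = self._star([10, 2, 4, 6])
        with_f = local_dispersion(cells, g, include_focal=True)
        without = local_dispersion(cells, g, include_focal=False)
        assert with_f.set_index("label").loc[1, "cluster_size"] == 4
        assert without.set_index("label").loc[1, "cluster_size"] == 3
        assert without.set_index("label").loc[1, "cluster_mean"] == \
            pytest.approx(4.0)

    def test_brute_force_oracle_matches_exactly(self):
        """Independent recomputation of every cluster's statistics."""
        cfg = SimConfig(n_cols=8, n_rows=6, cell_pitch_px=20, jitter=0.3,
                        seed=13, domains={"rho": (0.0, 1.0),
                                          "mir9a": (0.0, 1.0)})
        cm = build_cell_lattice(cfg)
        gt = simulate_transcription(cm, assign_domains(cm, cfg), cfg, "WT")
        cells = cm.cells[["label", "border"]].copy()
        cells["mrna_count"] = gt.cells["true_mrna"].to_numpy()
        g = build_neighbor_graph(cm.label_image)
        disp = local_dispersion(cells, g).set_index("label")
        values = cells.set_index("label")["mrna_count"]
        checked = 0
        for node in g.nodes:
            if g.nodes[node]["border"]:
                assert node not in disp.index
                continue
            members = [node] + list(g.neighbors(node))
            v = [float(values.loc[m]) for m in members]
            mean = sum(v) / len(v)
            var = sum((x - mean) ** 2 for x in v) / (len(v) - 1)
            row = disp.loc[node]
            assert row["cluster_mean"] == mean
            assert row["cluster_variance"] == pytest.approx(var, abs=1e-12)
            if mean > 0:
                assert row["fano"] == pytest.approx(var / mean, abs=1e-12)
                assert row["cv"] == pytest.approx(var**0.5 / mean, abs=1e-12)
            checked += 1
        assert checked > 10

    def test_poisson_lattice_fano_centers_on_one(self):
        """i.i.d. Poisson counts: FF -> 1, CV -> lambda^(-1/2)."""
        lam = 20.0
        cfg = SimConfig(n_cols=25, n_rows=25, cell_pitch_px=12, jitter=0.2,
                        seed=4)
        cm = build_cell_lattice(cfg)
        rng = np.random.default_rng(0)
        cells = cm.cells[["label", "border"]].copy()
        cells["mrna_count"] = rng.poisson(lam, len(cells))
        g = build_neighbor_graph(cm.label_image)
        disp = local_dispersion(cells, g)
        fano = disp["fano"].dropna()
        assert len(fano) >= 500
        assert 0.9 <= fano.mean() <= 1.1
        cv = disp["cv"].dropna()
        assert cv.mean() == pytest.approx(lam**-0.5, rel=0.1)

    def test_scaling_counts_scales_fano_not_cv(self):
        cfg = SimConfig(n_cols=6, n_rows=5, cell_pitch_px=20, jitter=0.25,
                        seed=9)
        cm = build_cell_lattice(cfg)
        rng = np.random.default_rng(3)
        cells = cm.cells[["label", "border"]].copy()
        cells["mrna_count"] = rng.poisson(15.0, len(cells)).astype(float)
        g = build_neighbor_graph(cm.label_image)
        base = local_dispersion(cells, g)
        scaled_cells = cells.copy()
        a = 3.0
        scaled_cells["mrna_count"] = cells["mrna_count"] * a
        scaled = local_dispersion(scaled_cells, g)
        np.testing.assert_allclose(scaled["fano"], base["fano"] * a)
        np.testing.assert_allclose(scaled["cv"], base["cv"])
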