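"""Regulator-gene correlation filters and the merged regulatory network."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicregnet.regmap import (
    annotate_cis,
    correlate_pairs,
    filter_mirna_edges,
    merge_modules,
    read_site_map,
    read_target_list,
    write_merged_graphml,
    write_merged_sif,
)


def frame(arr, prefix):
    return pd.DataFrame(
        arr, columns=[f"{prefix}{j}" for j in range(np.asarray(arr).shape[1])]
    )


class TestCorrelatePairs:
    def test_identical_vectors_r_one(self, rng):
        x = rng.standard_normal(50)
        out = correlate_pairs(frame(x[:, None], "m"), frame(x[:, None], "g"))
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_t_statistic(self):
        # r = 0.5 at n = 100: t = 0.5 sqrt(98/0.75) = 5.715, p ~ 1.2e-7
        r, n = 0.5, 100
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_expected = 2 * stats.t.sf(t, df=n - 2)
        assert t == pytest.approx(5.715, abs=1e-3)
        assert p_expected == pytest.approx(1.2e-7, rel=0.1)
        # build vectors with this exact empirical correlation
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        v = r * x + np.sqrt(1 - r**2) * y
        out = correlate_pairs(frame(x[:, None], "m"), frame(v[:, None], "g"))
        assert out.loc[0, "r"] == pytest.approx(r, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p_expected, rel=1e-6)

    def test_type_one_error_calibrated(self):
        """Independent pairs at n = 100: p <= 0.05 in about 5% of replicates."""
        n_rep = 1000
        rng = np.random.default_rng(2718)
        X = rng.standard_normal((100, n_rep))
        Y = rng.standard_normal((100, n_rep))
        hits = 0
        for j in range(n_rep):
            out = correlate_pairs(frame(X[:, [j]], "m"), frame(Y[:, [j]], "g"))
            hits += out.loc[0, "p"] <= 0.05
        assert abs(hits / n_rep - 0.05) <= 0.015

    def test_zero_variance_pair_skipped(self, rng):
        R = frame(np.column_stack([np.ones(20), rng.standard_normal(20)]), "m")
        G = frame(rng.standard_normal((20, 2)), "g")
        out = correlate_pairs(R, G)
        assert set(out["regulator"]) == {"m1"}

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            correlate_pairs(
                frame(rng.standard_normal((3, 1)), "m"),
                frame(rng.standard_normal((3, 1)), "g"),
            )


class TestMirnaFilter:
    def _pairs(self):
        return pd.DataFrame(
            {
                "regulator": ["mirA", "mirA", "mirB", "mirB", "mirC"],
                "gene": ["g1", "g2", "g1", "g3", "g2"],
                "r": [-0.4, 0.4, -0.5, -0.3, -0.6],
                "p": [0.01, 0.01, 0.002, 0.2, 0.03],
            }
        )

    def _targets(self):
        return pd.DataFrame(
            {
                "mirna_id": ["mirA", "mirA", "mirB", "mirC"],
                "gene_symbol": ["g1", "g2", "g1", "g9"],
                "source": ["db1", "db2", "db1", "db1"],
            }
        )

    def test_all_three_conditions_required(self):
        kept = filter_mirna_edges(self._pairs(), self._targets())
        # mirA-g1: neg, significant, annotated -> kept
        # mirA-g2: positive r -> dropped; mirB-g3: p too big; mirC-g2: not annotated
        assert sorted(zip(kept["regulator"], kept["gene"])) == [
            ("mirA", "g1"), ("mirB", "g1"),
        ]
        assert (kept["r"] < 0).all() and (kept["p"] <= 0.05).all()

    def test_edge_counts_monotone_through_filter_chain(self):
        pairs = self._pairs()
        p_pass = pairs[pairs["p"] <= 0.05]
        sign_pass = p_pass[p_pass["r"] < 0]
        kept = filter_mirna_edges(pairs, self._targets())
        assert len(pairs) >= len(p_pass) >= len(sign_pass) >= len(kept)

    def test_target_list_reader(self, tmp_path):
        path = tmp_path / "targets.tsv"
        self._targets().to_csv(path, sep="\t", index=False)
        df = read_target_list(path)
        assert {"mirna_id", "gene_symbol"} <= set(df.columns)


class TestCisFilter:
    def test_enumerated_fixture(self):
        pairs = pd.DataFrame(
            {
                "regulator": ["s1", "s1", "s2", "s3", "s4", "s9"],
                "gene": ["gA", "gB", "gB", "gC", "gD", "gA"],
                "r": [-0.5, -0.6, 0.4, -0.2, -0.5, -0.9],
                "p": [0.001, 0.001, 0.04, 0.3, 0.01, 0.001],
            }
        )
        site_map = pd.Series({"s1": "gA", "s2": "gB", "s3": "gC", "s4": "gZ"})
        kept = annotate_cis(pairs, site_map)
        # s1-gA: cis + significant; s1-gB: trans; s2-gB: cis + significant
        # (sign not filtered); s3-gC: p too big; s4-gD: trans; s9: unmapped
        assert sorted(zip(kept["regulator"], kept["gene"])) == [
            ("s1", "gA"), ("s2", "gB"),
        ]

    def test_positive_correlation_reported_not_dropped(self):
        pairs = pd.DataFrame(
            {"regulator": ["s2"], "gene": ["gB"], "r": [0.4], "p": [0.01]}
        )
        kept = annotate_cis(pairs, pd.Series({"s2": "gB"}))
        assert len(kept) == 1 and kept.loc[0, "r"] == 0.4

    def test_site_map_reader(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("site_id\tgene_symbol\tchrom\tpos\ncg1\tTP53\tchr17\t7675000\n")
        m = read_site_map(path)
        assert m["cg1"] == "TP53"


class TestMerge:
    def _inputs(self):
        g1 = nx.Graph([("a", "b"), ("b", "c")])
        g2 = nx.Graph([("d", "e")])
        g3 = nx.Graph([("f", "g")])
        edges = {
            1: pd.DataFrame(
                {
                    "regulator": ["mirX"] * 3 + ["cg1"],
                    "gene": ["a", "b", "c", "a"],
                    "r": [-0.5, -0.4, -0.6, -0.3],
                    "p": [0.01] * 4,
                    "edge_type": ["miRNA"] * 3 + ["methylation"],
                    "annotated": [True] * 4,
                }
            ),
            2: pd.DataFrame(
                {
                    "regulator": ["mirX"] * 2,
                    "gene": ["d", "e"],
                    "r": [-0.4, -0.5],
                    "p": [0.01] * 2,
                    "edge_type": ["miRNA"] * 2,
                    "annotated": [True] * 2,
                }
            ),
            3: pd.DataFrame(
                {
                    "regulator": ["mirX", "mirY"],
                    "gene": ["f", "f"],
                    "r": [-0.4, -0.5],
                    "p": [0.01] * 2,
                    "edge_type": ["miRNA"] * 2,
                    "annotated": [True] * 2,
                }
            ),
        }
        return {1: g1, 2: g2, 3: g3}, edges

    def test_shared_regulator_membership_sets(self):
        nets, edges = self._inputs()
        G, table = merge_modules(nets, edges)
        assert G.nodes["mirX"]["modules"] == [1, 2, 3]
        assert G.nodes["cg1"]["modules"] == [1]
        assert G.nodes["a"]["modules"] == [1]

    def test_degree_table_ranked(self):
        nets, edges = self._inputs()
        _, table = merge_modules(nets, edges)
        assert table.iloc[0]["regulator"] == "mirX"
        assert table.iloc[0]["degree"] == 6
        assert list(table["degree"]) == sorted(table["degree"], reverse=True)

    def test_disjoint_modules_stay_disconnected(self):
        nets, _ = self._inputs()
        G, _ = merge_modules(nets, None)
        assert nx.number_connected_components(G) == 3

    def test_idempotent_and_order_invariant(self):
        nets, edges = self._inputs()
        G1, t1 = merge_modules(nets, edges)
        G2, t2 = merge_modules(dict(reversed(list(nets.items()))), edges)
        assert nx.utils.graphs_equal(G1, G2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_exports(self, tmp_path):
        nets, edges = self._inputs()
        G, _ = merge_modules(nets, edges)
        write_merged_graphml(G, tmp_path / "m.graphml")
        back = nx.read_graphml(tmp_path / "m.graphml")
        assert back.nodes["mirX"]["node_type"] == "miRNA"
        assert back.nodes["mirX"]["modules"] == "1,2,3"
        write_merged_sif(G, tmp_path / "m.sif")
        text = (tmp_path / "m.sif").read_text()
        assert "gene-gene" in text and "miRNA" in text
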