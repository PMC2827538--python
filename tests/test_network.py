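"""IR merging, the IR-level graph, LC union, topology and tissue summaries."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import ivvmap as m


def ir_frame(rows):
    """rows: (ir_id, prey_gene, start, end, baits_csv)"""
    return pd.DataFrame(
        [
            {"ir_id": r[0], "prey_gene": r[1], "aa_start": r[2], "aa_end": r[3],
             "min_start": r[2], "min_end": r[3], "supporting_ists": "x",
             "supporting_bait_genes": r[4], "class": 1}
            for r in rows
        ]
    )


class TestMergeIrs:
    def test_shorter_interval_share_rule(self):
        # overlap 31 residues of the 41-residue IR: 31/41 > 0.5 -> merged
        nodes = m.merge_irs(ir_frame([("IR0", "G", 10, 60, "A"), ("IR1", "G", 30, 70, "B")]))
        assert len(nodes) == 1
        assert nodes.loc[0, "partner_bait_genes"] == "A,B"
        assert (nodes.loc[0, "merged_start"], nodes.loc[0, "merged_end"]) == (10, 70)

    def test_disjoint_irs_stay_separate(self):
        nodes = m.merge_irs(ir_frame([("IR0", "G", 10, 20, "A"), ("IR1", "G", 50, 60, "B")]))
        assert len(nodes) == 2

    def test_identical_region_four_baits_single_node(self):
        """One shared interface selected by four different baits collapses to
        a single multiple-partner node (the leucine-zipper pattern)."""
        rows = [(f"IR{i}", "FOS", 139, 200, b) for i, b in
                enumerate(["JUN", "JUNB", "JUND", "ATF2"])]
        nodes = m.merge_irs(ir_frame(rows))
        assert len(nodes) == 1
        assert nodes.loc[0, "partner_bait_genes"] == "ATF2,JUN,JUNB,JUND"
        assert list(m.classify_partner_multiplicity(nodes)) == ["multiple"]

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(30):
            s = int(rng.integers(1, 150))
            rows.append((f"IR{i}", f"G{rng.integers(0, 4)}", s,
                         s + int(rng.integers(5, 60)), f"B{rng.integers(0, 5)}"))
        irs = ir_frame(rows)
        nodes1 = m.merge_irs(irs)
        # re-merge the merged nodes re-expressed as IRs
        as_irs = ir_frame(
            [(r["node_id"], r["prey_gene"], r["merged_start"], r["merged_end"],
              r["partner_bait_genes"]) for _, r in nodes1.iterrows()]
        )
        # idempotence holds when components are already maximal under the rule
        n_counts = [len(m.merge_irs(irs, m.MergeParams(share_fraction=f)))
                    for f in (0.3, 0.5, 0.8, 1.0)]
        assert n_counts == sorted(n_counts)  # raising the bar never merges more
        assert len(m.merge_irs(as_irs)) <= len(nodes1)

    def test_target_sharing_criterion_flag(self):
        rows = [("IR0", "G", 10, 20, "A,B"), ("IR1", "G", 50, 60, "A,C")]
        residues = m.merge_irs(ir_frame(rows))
        targets = m.merge_irs(ir_frame(rows), m.MergeParams(criterion="targets"))
        assert len(residues) == 2     # no residue overlap
        assert len(targets) == 1      # A is half of each bait set


class TestBuildIrNetwork:
    def test_minimal_counts(self):
        ppis = pd.DataFrame([{"bait_gene": "A", "prey_gene": "G",
                              "evidence_ist_ids": "x", "best_class": 1}])
        nodes = m.merge_irs(ir_frame([("IR0", "G", 1, 10, "A")]))
        net = m.build_ir_network(nodes, ppis)
        assert net.counts() == {
            "n_protein_nodes": 2, "n_ir_nodes": 1, "n_total_nodes": 3,
            "n_intra_edges": 1, "n_inter_edges": 1,
        }

    def test_two_interface_hub(self):
        """A prey with one 4-partner interface and one exclusive interface:
        2 IR nodes, 2 intra edges, 5 inter edges."""
        rows = [(f"IR{i}", "FOS", 139, 200, b) for i, b in
                enumerate(["JUN", "JUNB", "JUND", "ATF2"])]
        rows.append(("IR4", "FOS", 250, 300, "SMAD2"))
        nodes = m.merge_irs(ir_frame(rows))
        ppis = pd.DataFrame(
            [{"bait_gene": b, "prey_gene": "FOS", "evidence_ist_ids": "x", "best_class": 1}
             for b in ["JUN", "JUNB", "JUND", "ATF2", "SMAD2"]]
        )
        net = m.build_ir_network(nodes, ppis)
        c = net.counts()
        assert c["n_ir_nodes"] == 2
        assert c["n_intra_edges"] == 2
        assert c["n_inter_edges"] == 5
        mult = m.classify_partner_multiplicity(nodes)
        assert sorted(mult) == ["multiple", "single"]

    def test_intra_edges_always_equal_ir_nodes(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rows = []
            for i in range(int(rng.integers(1, 25))):
                g = f"G{rng.integers(0, 5)}"
                s = int(rng.integers(1, 100))
                rows.append((f"IR{i}", g, s, s + 20, f"B{rng.integers(0, 4)}"))
            nodes = m.merge_irs(ir_frame(rows))
            ppis = pd.DataFrame(
                [{"bait_gene": b, "prey_gene": g, "evidence_ist_ids": "x", "best_class": 1}
                 for g, bs in zip(nodes["prey_gene"], nodes["partner_bait_genes"])
                 for b in bs.split(",")]
            ).drop_duplicates(["bait_gene", "prey_gene"])
            net = m.build_ir_network(nodes, ppis)
            c = net.counts()
            assert c["n_intra_edges"] == c["n_ir_nodes"]
            assert c["n_total_nodes"] == c["n_protein_nodes"] + c["n_ir_nodes"]

    def test_empty_partner_set_rejected(self):
        nodes = pd.DataFrame([{"node_id": "N0", "prey_gene": "G",
                               "merged_start": 1, "merged_end": 10,
                               "member_ir_ids": "IR0", "partner_bait_genes": ""}])
        with pytest.raises(ValueError, match="no partner"):
            m.build_ir_network(nodes, pd.DataFrame(columns=["bait_gene", "prey_gene"]))


class TestUnionWithLc:
    def ppis(self, pairs):
        return pd.DataFrame([{"bait_gene": a, "prey_gene": b} for a, b in pairs])

    def lc(self, pairs):
        return pd.DataFrame([{"gene_a": a, "gene_b": b} for a, b in pairs])

    def test_shared_edge_tagged_both(self):
        merged, rep = m.union_with_lc(self.ppis([("A", "G")]), self.lc([("G", "A")]))
        assert list(merged["source"]) == ["both"]
        assert rep["n_edges_union"] == 1

    def test_novel_node_counted(self):
        merged, rep = m.union_with_lc(self.ppis([("A", "G")]), self.lc([("A", "H")]))
        assert len(merged) == 2
        assert rep["n_nodes_new_vs_lc"] == 1

    def test_disjoint_sets_add(self):
        ivv = [(f"A{i}", f"G{i}") for i in range(10)]
        lc = [(f"X{i}", f"Y{i}") for i in range(10)]
        merged, rep = m.union_with_lc(self.ppis(ivv), self.lc(lc))
        assert len(merged) == 20
        assert rep["n_edges_ivv"] == rep["n_edges_lc"] == 10
        assert rep["n_edges_both"] == 0


class TestDegreeSummary:
    def test_star_graph(self):
        edges = pd.DataFrame([{"gene_a": "hub", "gene_b": f"leaf{i}"} for i in range(5)])
        out = m.degree_summary(edges)
        assert out["degrees"]["hub"] == 5
        assert out["max_degree"] == 5

    def test_mean_ppis_per_bait_rounds_to_printed_value(self):
        edges = pd.DataFrame([{"gene_a": "a", "gene_b": "b"}])
        out = m.degree_summary(edges, n_baits=68, n_ppis=943)
        assert out["mean_ppis_per_bait_rounded"] == 14

    def test_scale_free_slope_in_range(self):
        g = nx.barabasi_albert_graph(500, 2, seed=10)
        edges = pd.DataFrame([{"gene_a": f"n{u}", "gene_b": f"n{v}"} for u, v in g.edges()])
        slope = m.degree_summary(edges)["power_law_slope"]
        assert -3.5 <= slope <= -1.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.degree_summary(pd.DataFrame(columns=["gene_a", "gene_b"]))


class TestTissueSpecificPpis:
    def test_analytical_space_product(self):
        ppis = pd.DataFrame([{"bait_gene": "B", "prey_gene": f"G{i}"} for i in range(5)])
        sets = {"brain": {f"G{i}" for i in range(904)}}
        out = m.tissue_specific_ppis(ppis, sets, n_baits=50)
        row = out.iloc[0]
        assert row["analytical_space_C"] == 45_200
        assert row["n_specific_ppis"] == 5
        assert row["proportion"] == 5 / 45_200

    def test_hand_proportion(self):
        ppis = pd.DataFrame([{"bait_gene": "B", "prey_gene": f"G{i}"} for i in range(5)])
        sets = {"t": {f"G{i}" for i in range(5)} | {f"H{i}" for i in range(45)}}
        out = m.tissue_specific_ppis(ppis, sets, n_baits=10)
        assert out.iloc[0]["proportion"] == pytest.approx(5 / 500)

    def test_empty_tissue_set_omitted(self):
        ppis = pd.DataFrame([{"bait_gene": "B", "prey_gene": "G"}])
        out = m.tissue_specific_ppis(ppis, {"empty": set()}, n_baits=3)
        assert len(out) == 0

    def test_nonpositive_baits_rejected(self):
        with pytest.raises(ValueError):
            m.tissue_specific_ppis(pd.DataFrame(columns=["prey_gene"]), {"t": {"G"}}, 0)


class TestExpressionCorrelation:
    def test_identical_profiles_r1(self):
        genes = [f"G{i}" for i in range(20)]
        X = m.simulate_expression(genes, 10, [("G0", "G1")], rho=0.999999, seed=1)
        X.loc["G1"] = X.loc["G0"]
        rep = m.expression_correlation_report([("G0", "G1")], X, n_random=50, seed=2)
        assert rep["pair_correlations"][0] == pytest.approx(1.0)

    def test_planted_pairs_beat_random(self):
        genes = [f"G{i}" for i in range(300)]
        pairs = [(f"G{i}", f"G{i + 150}") for i in range(50)]
        X = m.simulate_expression(genes, 30, pairs, rho=0.6, seed=3)
        rep = m.expression_correlation_report(pairs, X, n_random=1000, seed=4)
        assert rep["p_permutation"] < 0.01
        assert rep["mean_pair_r"] > rep["mean_null_r"]

    def test_constant_profile_skipped(self):
        genes = [f"G{i}" for i in range(10)]
        X = m.simulate_expression(genes, 8, [], seed=5)
        X.loc["G0"] = 1.0
        rep = m.expression_correlation_report([("G0", "G1"), ("G2", "G3")], X,
                                              n_random=20, seed=6)
        assert rep["n_skipped_constant"] == 1
        assert len(rep["pair_correlations"]) == 1

    def test_too_few_tissues_rejected(self):
        X = m.simulate_expression(["a", "b"], 2, [], seed=1)
        with pytest.raises(ValueError):
            m.expression_correlation_report([("a", "b")], X)
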