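"""Minimum/maximum-region clustering, PPI calling, and domain overlap."""

import numpy as np
import pandas as pd
import pytest

import ivvmap as m
from ivvmap.intervals import intersect_all, jaccard, span
from ivvmap.regions import maximal_common_intersection_sets

from conftest import make_ist_frame
from oracles import brute_clusters


def classified(rows, cls=1, parent="BG0"):
    df = make_ist_frame(rows)
    df["bait_parent_gene"] = parent
    df["class"] = cls
    return df


def cluster_partition(clusters: pd.DataFrame):
    return sorted(sorted(s.split(",")) for s in clusters["member_ist_ids"])


class TestDeriveIrs:
    def test_nested_intervals_innermost_minimum(self):
        rows = [("a", "B0", "G", 10, 50), ("b", "B0", "G", 20, 60), ("c", "B0", "G", 30, 40)]
        clusters, irs = m.derive_irs(classified(rows))
        assert len(clusters) == 1
        assert (clusters.loc[0, "min_start"], clusters.loc[0, "min_end"]) == (30, 40)
        assert (irs.loc[0, "aa_start"], irs.loc[0, "aa_end"]) == (10, 60)

    def test_three_overlap_groups_three_clusters(self):
        """Five ISTs in three overlap groups yield three clusters, each with
        its own minimum/maximum regions."""
        rows = [
            ("a", "B0", "G", 10, 40), ("b", "B0", "G", 20, 50),   # group 1
            ("c", "B0", "G", 70, 100), ("d", "B0", "G", 80, 110),  # group 2
            ("e", "B0", "G", 150, 180),                            # group 3
        ]
        clusters, irs = m.derive_irs(classified(rows))
        assert len(clusters) == 3
        assert len(irs) == 3
        assert cluster_partition(clusters) == [["a", "b"], ["c", "d"], ["e"]]

    def test_single_ist_identity(self):
        clusters, irs = m.derive_irs(classified([("a", "B0", "G", 5, 25)], cls=2))
        assert len(clusters) == 1
        row = clusters.loc[0]
        assert (row["min_start"], row["min_end"]) == (5, 25)
        assert (row["max_start"], row["max_end"]) == (5, 25)

    def test_transitive_chain_splits(self):
        """A overlaps B, B overlaps C, but A and C share nothing: no common
        region exists, so the chain cannot be one cluster."""
        rows = [("a", "B0", "G", 10, 30), ("b", "B0", "G", 25, 50), ("c", "B0", "G", 45, 70)]
        clusters, _ = m.derive_irs(classified(rows))
        assert len(clusters) == 2

    def test_short_overlap_below_minimum_region(self):
        """A 2-residue shared region cannot seed a cluster at the 3-aa rule."""
        rows = [("a", "B0", "G", 10, 30), ("b", "B0", "G", 29, 50)]
        clusters, _ = m.derive_irs(classified(rows))
        assert len(clusters) == 2

    def test_groups_are_per_bait_and_prey(self):
        rows = [("a", "B0", "G", 10, 40)]
        df1 = classified(rows, parent="BG0")
        df2 = classified([("b", "B0", "G", 20, 50)], parent="BG1")
        clusters, _ = m.derive_irs(pd.concat([df1, df2], ignore_index=True))
        assert len(clusters) == 2  # different baits never share a cluster

    def test_class3_rejected(self):
        with pytest.raises(ValueError, match="class-3"):
            m.derive_irs(classified([("a", "B0", "G", 1, 10)], cls=3))

    def test_matches_exhaustive_enumeration(self):
        """Cluster assignment equals exhaustive maximal common-intersection
        enumeration with the documented tie-breaks (groups of <= 12 ISTs)."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(1, 80))
                ivs.append((s, min(100, s + int(rng.integers(0, 40)))))
            rows = [(f"I{i}", "B0", "G", s, e) for i, (s, e) in enumerate(ivs)]
            clusters, _ = m.derive_irs(classified(rows))
            got = sorted(
                sorted(int(x[1:]) for x in s.split(","))
                for s in clusters["member_ist_ids"]
            )
            assert got == brute_clusters(ivs, 3)

    def test_geometry_invariants(self):
        """min region inside every member, members inside max region; every
        IST in exactly one cluster."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 15))
            ivs = [(int(s), int(min(200, s + rng.integers(0, 60))))
                   for s in rng.integers(1, 150, size=n)]
            rows = [(f"I{i}", "B0", "G", s, e) for i, (s, e) in enumerate(ivs)]
            clusters, irs = m.derive_irs(classified(rows))
            assert len(irs) == len(clusters)
            seen = []
            for _, row in clusters.iterrows():
                members = [ivs[int(x[1:])] for x in row["member_ist_ids"].split(",")]
                seen.extend(row["member_ist_ids"].split(","))
                mini = (row["min_start"], row["min_end"])
                maxi = (row["max_start"], row["max_end"])
                assert mini == intersect_all(members)
                assert maxi == span(members)
                for iv in members:
                    assert mini[0] >= iv[0] and mini[1] <= iv[1]
                    assert maxi[0] <= iv[0] and maxi[1] >= iv[1]
            assert sorted(seen) == sorted(f"I{i}" for i in range(n))

    def test_planted_recovery(self, planted_screen):
        """Noise-free straddle screen: one cluster per planted IR, minimum
        region Jaccard >= 0.5 against truth."""
        out = m.run_pipeline(
            planted_screen["ists"], planted_screen["mock"],
            planted_screen["reference"], planted_screen["bait_map"],
        )
        clusters = out["clusters"]
        truth = planted_screen["truth"]
        assert len(clusters) == len(truth.planted_irs)
        by_pair = {(c["bait_parent_gene"], c["prey_gene"]): c for _, c in clusters.iterrows()}
        for p in truth.planted_irs:
            c = by_pair[(p.bait_gene, p.prey_gene)]
            assert jaccard((c["min_start"], c["min_end"]), p.interval) >= 0.5


class TestMaximalSets:
    def test_sweep_equals_subset_enumeration(self):
        rng = np.random.default_rng(55)
        for _ in range(200):
            n = int(rng.integers(1, 10))
            ivs = [(int(s), int(s + rng.integers(0, 30)))
                   for s in rng.integers(1, 60, size=n)]
            got = sorted(map(tuple, maximal_common_intersection_sets(ivs, 3)))
            import itertools

            good = []
            for r in range(1, n + 1):
                for combo in itertools.combinations(range(n), r):
                    s = max(ivs[i][0] for i in combo)
                    e = min(ivs[i][1] for i in combo)
                    if e - s + 1 >= 3:
                        good.append(frozenset(combo))
            maximal = sorted(
                tuple(sorted(g)) for g in good if not any(g < h for h in good)
            )
            assert got == maximal


class TestCallPpis:
    def test_distinct_pair_count(self):
        rows = [("a", "BA", "G", 1, 10), ("b", "BA", "G", 5, 15), ("c", "BB", "H", 1, 10)]
        df = make_ist_frame(rows)
        df["bait_parent_gene"] = df["bait_id"]
        df["class"] = [1, 1, 2]
        ppis = m.call_ppis(df)
        assert len(ppis) == 2
        assert set(zip(ppis["bait_gene"], ppis["prey_gene"])) == {("BA", "G"), ("BB", "H")}
        assert list(ppis["best_class"]) == [1, 2]

    def test_empty_core(self):
        assert len(m.call_ppis(make_ist_frame([]).assign(bait_parent_gene=None))) == 0

    def test_planted_pairs_recovered_exactly(self, planted_screen):
        out = m.run_pipeline(
            planted_screen["ists"], planted_screen["mock"],
            planted_screen["reference"], planted_screen["bait_map"],
        )
        got = set(zip(out["ppis"]["bait_gene"], out["ppis"]["prey_gene"]))
        want = {(p.bait_gene, p.prey_gene) for p in planted_screen["truth"].planted_irs}
        assert got == want


class TestAnnotateDomains:
    IRS = pd.DataFrame(
        [
            {"ir_id": "IR0", "prey_gene": "G", "aa_start": 124, "aa_end": 176,
             "min_start": 130, "min_end": 170, "supporting_ists": "a",
             "supporting_bait_genes": "B", "class": 1},
            {"ir_id": "IR1", "prey_gene": "G", "aa_start": 10, "aa_end": 20,
             "min_start": 10, "min_end": 20, "supporting_ists": "b",
             "supporting_bait_genes": "B", "class": 2},
        ]
    )

    def test_overlap_hits_and_fractions(self):
        domains = pd.DataFrame(
            [{"gene_id": "G", "domain_name": "ferritin", "aa_start": 120, "aa_end": 180},
             {"gene_id": "G", "domain_name": "other", "aa_start": 30, "aa_end": 40}]
        )
        annotated, fractions = m.annotate_domains(self.IRS, domains)
        assert annotated.loc[0, "domain_hits"].startswith("ferritin:")
        assert annotated.loc[1, "domain_hits"] == ""
        assert fractions == {1: 1.0, 2: 0.0}

    def test_unknown_gene_domain_skipped(self):
        domains = pd.DataFrame(
            [{"gene_id": "NOPE", "domain_name": "x", "aa_start": 1, "aa_end": 10}]
        )
        annotated, _ = m.annotate_domains(self.IRS, domains, known_genes={"G"})
        assert (annotated["domain_hits"] == "").all()

    def test_planted_domain_fraction(self, planted_screen):
        """When a quarter of planted IRs coincide with domains, about a
        quarter of recovered IRs carry a domain hit."""
        from ivvmap.simulate import plant_domains

        truth = planted_screen["truth"]
        domains = plant_domains(planted_screen["reference"], truth.planted_irs,
                                domain_fraction=0.4, seed=3)
        out = m.run_pipeline(
            planted_screen["ists"], planted_screen["mock"],
            planted_screen["reference"], planted_screen["bait_map"],
            domains=domains,
        )
        n_planted_hit = sum(
            1 for p in truth.planted_irs
            if ((domains["gene_id"] == p.prey_gene)
                & (domains["domain_name"].str.startswith("DOM_IR"))).any()
        )
        hits = (out["irs"]["domain_hits"].str.contains("DOM_IR")).sum()
        assert hits == n_planted_hit
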