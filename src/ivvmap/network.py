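"""Protein- and IR-level interaction networks.

The IR-level graph refines a classical PPI graph with intermediate IR nodes:
every IR node carries exactly one intra-protein edge to its host prey
protein and one inter-protein edge per supporting bait. Overlapping IRs on
the same prey are merged into a single IR node; IR nodes supported by two or
more distinct baits are the multiple-partner (candidate flexible/competitive)
interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .intervals import length, overlap_len


@dataclass
class MergeParams:
    """IR merge rule: the shorter IR must share at least ``share_fraction``
    of its residues with the other (``criterion="residues"``), or the
    smaller bait set must share that fraction of its baits
    (``criterion="targets"``, the alternative reading kept for sensitivity
    analysis)."""

    share_fraction: float = 0.5
    criterion: str = "residues"

    def __post_init__(self):
        if not 0.0 < self.share_fraction <= 1.0:
            raise ValueError("share_fraction must be in (0, 1]")
        if self.criterion not in ("residues", "targets"):
            raise ValueError(f"unknown merge criterion {self.criterion!r}")


@dataclass
class IRNetwork:
    graph: nx.Graph
    protein_nodes: set = field(default_factory=set)
    ir_nodes: set = field(default_factory=set)

    @property
    def intra_edges(self):
        return [(u, v) for u, v, d in self.graph.edges(data=True) if d["kind"] == "intra"]

    @property
    def inter_edges(self):
        return [(u, v) for u, v, d in self.graph.edges(data=True) if d["kind"] == "inter"]

    def counts(self) -> dict:
        return {
            "n_protein_nodes": len(self.protein_nodes),
            "n_ir_nodes": len(self.ir_nodes),
            "n_total_nodes": len(self.protein_nodes) + len(self.ir_nodes),
            "n_intra_edges": len(self.intra_edges),
            "n_inter_edges": len(self.inter_edges),
        }


def merge_irs(irs: pd.DataFrame, params: MergeParams | None = None) -> pd.DataFrame:
    """Merge overlapping IRs on each prey gene into IR nodes.

    Two IRs are linked when the shorter shares >= share_fraction of its
    residues (or targets) with the other; IR nodes are the connected
    components of that relation, their merged region the component span and
    their partner set the union of supporting baits.
    """
    params = params or MergeParams()
    if len(irs) == 0:
        return pd.DataFrame(columns=["node_id", "prey_gene", "merged_start", "merged_end",
                                     "member_ir_ids", "partner_bait_genes"])
    rows = []
    for prey, grp in irs.groupby("prey_gene", sort=True):
        grp = grp.sort_values("ir_id", kind="mergesort")
        ivs = list(zip(grp["aa_start"].astype(int), grp["aa_end"].astype(int)))
        baits = [set(str(b).split(",")) for b in grp["supporting_bait_genes"]]
        g = nx.Graph()
        g.add_nodes_from(range(len(grp)))
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if params.criterion == "residues":
                    shorter = min(length(ivs[i]), length(ivs[j]))
                    score = overlap_len(ivs[i], ivs[j]) / shorter if shorter else 0.0
                else:
                    smaller = min(len(baits[i]), len(baits[j]))
                    score = len(baits[i] & baits[j]) / smaller if smaller else 0.0
                if score >= params.share_fraction:
                    g.add_edge(i, j)
        for comp in sorted(nx.connected_components(g), key=min):
            comp = sorted(comp)
            members = [grp.iloc[i] for i in comp]
            starts = [int(m["aa_start"]) for m in members]
            ends = [int(m["aa_end"]) for m in members]
            partner = set().union(*(baits[i] for i in comp))
            rows.append(
                {
                    "prey_gene": prey,
                    "merged_start": min(starts),
                    "merged_end": max(ends),
                    "member_ir_ids": ",".join(m["ir_id"] for m in members),
                    "partner_bait_genes": ",".join(sorted(partner)),
                }
            )
    out = pd.DataFrame(rows)
    out.insert(0, "node_id", [f"IRN{i:05d}" for i in range(len(out))])
    return out


def classify_partner_multiplicity(ir_nodes: pd.DataFrame) -> pd.Series:
    """'multiple' when an IR node is supported by >= 2 distinct baits."""
    n = ir_nodes["partner_bait_genes"].map(lambda s: len(str(s).split(",")))
    return pd.Series(np.where(n >= 2, "multiple", "single"), index=ir_nodes.index)


def build_ir_network(ir_nodes: pd.DataFrame, ppis: pd.DataFrame) -> IRNetwork:
    """Assemble the IR-level graph.

    Protein nodes are all bait and prey genes of the PPI table; each IR node
    gets one intra edge to its host prey and one inter edge per partner bait.
    """
    g = nx.Graph()
    proteins = set(ppis["bait_gene"]) | set(ppis["prey_gene"]) if len(ppis) else set()
    proteins |= set(ir_nodes["prey_gene"]) if len(ir_nodes) else set()
    for p in sorted(proteins):
        g.add_node(p, type="protein")
    irs = set()
    for _, node in ir_nodes.iterrows():
        partners = [b for b in str(node["partner_bait_genes"]).split(",") if b]
        if not partners:
            raise ValueError(f"IR node {node['node_id']} has no partner baits")
        nid = node["node_id"]
        irs.add(nid)
        g.add_node(nid, type="ir", prey_gene=node["prey_gene"],
                   region=f"{node['merged_start']}..{node['merged_end']}")
        g.add_edge(nid, node["prey_gene"], kind="intra")
        for b in partners:
            if b == node["prey_gene"]:
                continue  # self-interaction: intra edge already links them
            g.add_edge(b, nid, kind="inter")
    return IRNetwork(graph=g, protein_nodes=proteins, ir_nodes=irs)


def union_with_lc(ppis: pd.DataFrame, lc_edges: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Undirected union of screen PPIs with literature-curated (LC) edges.

    Edges are tagged ivv/lc/both. The novelty report gives raw node/edge
    counts plus both candidate "percent more nodes than LC" readings
    (union-vs-LC and IVV-vs-LC), since either base is defensible.
    """
    ivv = {frozenset((a, b)) for a, b in zip(ppis["bait_gene"], ppis["prey_gene"]) if a != b} \
        if len(ppis) else set()
    lc = {frozenset((a, b)) for a, b in zip(lc_edges["gene_a"], lc_edges["gene_b"]) if a != b} \
        if len(lc_edges) else set()
    rows = []
    for e in sorted(ivv | lc, key=lambda e: tuple(sorted(e))):
        a, b = sorted(e)
        tag = "both" if e in ivv and e in lc else ("ivv" if e in ivv else "lc")
        rows.append({"gene_a": a, "gene_b": b, "source": tag})
    merged = pd.DataFrame(rows, columns=["gene_a", "gene_b", "source"])
    nodes_ivv = set().union(*ivv) if ivv else set()
    nodes_lc = set().union(*lc) if lc else set()
    nodes_union = nodes_ivv | nodes_lc
    report = {
        "n_edges_ivv": len(ivv),
        "n_edges_lc": len(lc),
        "n_edges_both": len(ivv & lc),
        "n_edges_union": len(ivv | lc),
        "n_nodes_ivv": len(nodes_ivv),
        "n_nodes_lc": len(nodes_lc),
        "n_nodes_union": len(nodes_union),
        "n_nodes_new_vs_lc": len(nodes_union - nodes_lc),
        "pct_union_nodes_over_lc": (
            100.0 * (len(nodes_union) - len(nodes_lc)) / len(nodes_lc) if nodes_lc else float("nan")
        ),
        "pct_ivv_nodes_over_lc": (
            100.0 * len(nodes_ivv) / len(nodes_lc) - 100.0 if nodes_lc else float("nan")
        ),
    }
    return merged, report


def degree_summary(edges: pd.DataFrame, n_baits: int | None = None,
                   n_ppis: int | None = None) -> dict:
    """Degree table, binned log-log power-law slope, and mean PPIs per bait.

    The exponent is the least-squares slope of log10(count) on log10(degree)
    over logarithmic degree bins (degrees >= 1), the simple fit appropriate
    to an "approximately power-law" claim.
    """
    if len(edges) == 0:
        raise ValueError("degree_summary needs a nonempty edge list")
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    degs = pd.Series(dict(g.degree()), name="degree").sort_index()
    counts = degs.value_counts().sort_index()
    k = counts.index.to_numpy(dtype=float)
    # logarithmic binning: geometric bin edges, density per bin
    edges_log = np.unique(np.rint(2 ** np.arange(0, np.ceil(np.log2(k.max())) + 1)))
    slope = float("nan")
    if len(edges_log) >= 3:
        centers, dens = [], []
        for lo, hi in zip(edges_log[:-1], edges_log[1:]):
            sel = (k >= lo) & (k < hi)
            if sel.any():
                centers.append(np.sqrt(lo * hi))
                dens.append(counts.to_numpy()[sel].sum() / (hi - lo))
        if len(centers) >= 3:
            slope = float(
                stats.linregress(np.log10(centers), np.log10(dens)).slope
            )
    out = {
        "degrees": degs,
        "power_law_slope": slope,
        "max_degree": int(degs.max()),
    }
    if n_baits:
        npp = n_ppis if n_ppis is not None else len(edges)
        out["mean_ppis_per_bait"] = npp / n_baits
        out["mean_ppis_per_bait_rounded"] = int(round(npp / n_baits))
    return out


def tissue_specific_ppis(
    ppis: pd.DataFrame,
    tissue_sets: dict[str, set[str]],
    n_baits: int,
) -> pd.DataFrame:
    """Per-tissue specific-PPI proportions over the analytical space
    C = (number of tissue-specific genes) x (number of baits).

    A PPI is tissue-specific when its prey gene belongs to the tissue set.
    Tissues with empty sets (C = 0) are omitted: the proportion is undefined.
    """
    if n_baits <= 0:
        raise ValueError("n_baits must be positive")
    rows = []
    for tissue in sorted(tissue_sets):
        genes = tissue_sets[tissue]
        if not genes:
            continue
        c = len(genes) * n_baits
        n_spec = int(ppis["prey_gene"].isin(genes).sum()) if len(ppis) else 0
        rows.append(
            {
                "tissue": tissue,
                "n_specific_genes": len(genes),
                "n_baits": n_baits,
                "analytical_space_C": c,
                "n_specific_ppis": n_spec,
                "proportion": n_spec / c,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tissue", "n_specific_genes", "n_baits", "analytical_space_C",
                 "n_specific_ppis", "proportion"],
    )


def expression_correlation_report(
    pairs: list[tuple[str, str]],
    expression: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
    n_perm: int = 2000,
) -> dict:
    """Compare interacting-pair co-expression against random pairs.

    Pearson r per pair across tissues; the null is ``n_random`` uniformly
    drawn non-interacting pairs; the one-sided p is a label-permutation test
    on the difference of group means. Constant-profile genes are skipped
    with a count.
    """
    if expression.shape[1] < 3:
        raise ValueError("expression matrix needs >= 3 tissues")
    rng = np.random.default_rng(seed)
    X = expression.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(expression.index)}
    sd = X.std(axis=1)

    def corr(i, j):
        return float(np.corrcoef(X[i], X[j])[0, 1])

    skipped = 0
    obs = []
    pair_set = {frozenset(p) for p in pairs}
    for a, b in pairs:
        i, j = idx[a], idx[b]
        if sd[i] == 0.0 or sd[j] == 0.0:
            skipped += 1
            continue
        obs.append(corr(i, j))

    null = []
    n_genes = len(expression.index)
    while len(null) < n_random:
        i, j = rng.integers(0, n_genes, size=2)
        if i == j or sd[i] == 0.0 or sd[j] == 0.0:
            continue
        if frozenset((expression.index[i], expression.index[j])) in pair_set:
            continue
        null.append(corr(i, j))

    obs = np.asarray(obs)
    null = np.asarray(null)
    diff = obs.mean() - null.mean()
    pooled = np.concatenate([obs, null])
    n1 = len(obs)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if perm[:n1].mean() - perm[n1:].mean() >= diff:
            hits += 1
    return {
        "pair_correlations": obs,
        "null_correlations": null,
        "mean_pair_r": float(obs.mean()),
        "mean_null_r": float(null.mean()),
        "mean_difference": float(diff),
        "p_permutation": (hits + 1) / (n_perm + 1),
        "n_skipped_constant": skipped,
    }
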