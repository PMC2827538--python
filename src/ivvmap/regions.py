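"""Derivation of interacting regions (IRs) from classified core ISTs.

Within each (prey gene, bait parent gene) group, ISTs are clustered into
groups that share a *minimum region* — the residues common to every member,
the innermost interval under nesting — of at least ``min_region_len_aa``
residues (default 3). The *maximum region*, the lateral-ends span of the
cluster, is emitted as the interacting region (IR): the interval implicated
as containing the interacting domain or motif.

Cluster candidates are the maximal subsets with a common intersection of the
required width. An IST contained in several competing maximal subsets is
assigned uniquely to the one with the longest common intersection (tie:
leftmost minimum region, then smallest end, then member order), so every
core IST belongs to exactly one cluster. ISTs left without a multi-member
home (including lone class-2 fragments) become singleton clusters whose
minimum and maximum regions are their own interval. A transitive chain of
overlaps without a common shared region splits into separate clusters: a
cluster must genuinely share residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import Interval, intersect_all, length, overlaps, span


@dataclass
class IRParams:
    min_region_len_aa: int = 3

    def __post_init__(self):
        if self.min_region_len_aa < 1:
            raise ValueError("min_region_len_aa must be >= 1")


IR_COLUMNS = [
    "ir_id", "prey_gene", "aa_start", "aa_end", "min_start", "min_end",
    "supporting_ists", "supporting_bait_genes", "class",
]


def maximal_common_intersection_sets(
    intervals: list[Interval], min_len: int
) -> list[list[int]]:
    """All maximal index sets whose common intersection spans >= min_len
    residues.

    A set of closed intervals has a common intersection of width >= w exactly
    when the right-shrunk intervals [s, e - w + 1] share a point; maximal
    such sets are found by sweeping the shrunk start points.
    """
    shrunk = [(s, e - min_len + 1) for s, e in intervals]
    candidates: list[frozenset[int]] = []
    for s, _ in shrunk:
        members = frozenset(
            i for i, (si, ei) in enumerate(shrunk) if si <= s <= ei
        )
        if members:
            candidates.append(members)
    uniq = set(candidates)
    maximal = [
        sorted(c) for c in uniq if not any(c < other for other in uniq)
    ]
    return sorted(maximal)


def _assign_clusters(intervals: list[Interval], min_len: int) -> list[list[int]]:
    """Partition interval indices into clusters per the unique-assignment rule."""
    cliques = maximal_common_intersection_sets(intervals, min_len)
    clique_info = []
    for members in cliques:
        inter = intersect_all([intervals[i] for i in members])
        clique_info.append((members, inter))

    assignment: dict[int, int] = {}
    for i in range(len(intervals)):
        best = None
        for ci, (members, inter) in enumerate(clique_info):
            if i not in members:
                continue
            key = (-length(inter), inter[0], inter[1], tuple(members))
            if best is None or key < best[0]:
                best = (key, ci)
        if best is not None:
            assignment[i] = best[1]

    groups: dict[int, list[int]] = {}
    singletons: list[list[int]] = []
    for i in range(len(intervals)):
        if i in assignment:
            groups.setdefault(assignment[i], []).append(i)
        else:
            singletons.append([i])
    clusters = [sorted(g) for g in groups.values()] + singletons
    return sorted(clusters)


def derive_irs(
    core: pd.DataFrame,
    params: IRParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster core ISTs and emit one IR per cluster.

    ``core`` must be a classified IST table restricted to classes 1 and 2
    with a ``bait_parent_gene`` column. Returns (cluster table, IR table);
    IR coordinates are the cluster maximum regions.
    """
    params = params or IRParams()
    if "class" not in core.columns:
        raise ValueError("core table must be classified")
    if len(core) and core["class"].isin([3]).any():
        raise ValueError("class-3 ISTs are not part of the core set")

    cluster_rows = []
    ir_rows = []
    if len(core):
        grouped = core.groupby(["prey_gene", "bait_parent_gene"], sort=True)
        for (prey, bait), grp in grouped:
            grp = grp.sort_values(["aa_start", "aa_end", "ist_id"], kind="mergesort")
            ivs = list(zip(grp["aa_start"].astype(int), grp["aa_end"].astype(int)))
            ids = grp["ist_id"].tolist()
            classes = grp["class"].tolist()
            for members in _assign_clusters(ivs, params.min_region_len_aa):
                member_ivs = [ivs[i] for i in members]
                mini = intersect_all(member_ivs)
                maxi = span(member_ivs)
                n = len(cluster_rows)
                cluster_rows.append(
                    {
                        "cluster_id": f"C{n:05d}",
                        "prey_gene": prey,
                        "bait_parent_gene": bait,
                        "member_ist_ids": ",".join(ids[i] for i in members),
                        "min_start": mini[0],
                        "min_end": mini[1],
                        "max_start": maxi[0],
                        "max_end": maxi[1],
                    }
                )
                ir_rows.append(
                    {
                        "ir_id": f"IR{n:05d}",
                        "prey_gene": prey,
                        "aa_start": maxi[0],
                        "aa_end": maxi[1],
                        "min_start": mini[0],
                        "min_end": mini[1],
                        "supporting_ists": ",".join(ids[i] for i in members),
                        "supporting_bait_genes": bait,
                        "class": min(classes[i] for i in members),
                    }
                )

    clusters = pd.DataFrame(
        cluster_rows,
        columns=["cluster_id", "prey_gene", "bait_parent_gene", "member_ist_ids",
                 "min_start", "min_end", "max_start", "max_end"],
    )
    irs = pd.DataFrame(ir_rows, columns=IR_COLUMNS)
    return clusters, irs


def call_ppis(core: pd.DataFrame) -> pd.DataFrame:
    """One protein-protein interaction per distinct (bait parent gene, prey
    gene) pair with at least one core IST; best class is 1 when any
    supporting IST is class 1."""
    if len(core) == 0:
        return pd.DataFrame(columns=["bait_gene", "prey_gene", "evidence_ist_ids", "best_class"])
    if "bait_parent_gene" not in core.columns:
        raise ValueError("core table must carry bait_parent_gene")
    rows = []
    for (bait, prey), grp in core.groupby(["bait_parent_gene", "prey_gene"], sort=True):
        rows.append(
            {
                "bait_gene": bait,
                "prey_gene": prey,
                "evidence_ist_ids": ",".join(sorted(grp["ist_id"])),
                "best_class": int(grp["class"].min()),
            }
        )
    return pd.DataFrame(rows)


def annotate_domains(
    irs: pd.DataFrame,
    domains: pd.DataFrame,
    known_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Mark IRs overlapping annotated domains (>= 1 shared residue, same
    gene) and report the known-domain fraction per evidence class.

    Domains on genes absent from ``known_genes`` (when given) are skipped
    with a warning. Returns the annotated IR table (added ``domain_hits``
    column, semicolon-joined "name:start..end") and {class: fraction of IRs
    with >= 1 hit}.
    """
    import logging

    out = irs.copy()
    dom = domains
    if known_genes is not None and len(dom):
        bad = ~dom["gene_id"].isin(known_genes)
        if bad.any():
            logging.getLogger(__name__).warning(
                "annotate_domains: skipping %d domains on unknown genes", bad.sum()
            )
            dom = dom[~bad]
    by_gene = dict(tuple(dom.groupby("gene_id"))) if len(dom) else {}

    hits = []
    for _, ir in out.iterrows():
        found = []
        g = by_gene.get(ir["prey_gene"])
        if g is not None:
            iv = (int(ir["aa_start"]), int(ir["aa_end"]))
            for _, d in g.iterrows():
                div = (int(d["aa_start"]), int(d["aa_end"]))
                if overlaps(iv, div):
                    ov = (max(iv[0], div[0]), min(iv[1], div[1]))
                    found.append(f"{d['domain_name']}:{ov[0]}..{ov[1]}")
        hits.append(";".join(found))
    out["domain_hits"] = hits

    fractions: dict[int, float] = {}
    if len(out):
        for c, grp in out.groupby("class"):
            fractions[int(c)] = float((grp["domain_hits"] != "").mean())
    return out, fractions
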