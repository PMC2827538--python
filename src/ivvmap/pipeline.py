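"""End-to-end pipeline: map -> classify -> core -> IRs -> PPIs -> network.

``run_pipeline`` executes the stages over in-memory tables or files, writes
every artifact with a content-hash manifest, and returns a ``RunReport``
whose internal consistency (class counts summing to the mapped total, one IR
per cluster, one intra edge per IR node, total nodes = protein + IR nodes)
is asserted before the report is returned. Re-running with identical inputs
and seed is byte-identical; no timestamps are written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as iomod
from .mapping import MappingParams, alignments_from_ist_table, classify_ists, core_subset, map_ists
from .network import MergeParams, build_ir_network, classify_partner_multiplicity, merge_irs
from .regions import IRParams, annotate_domains, call_ppis, derive_irs
from .simulate import ReferenceProtein

log = logging.getLogger(__name__)

VERSION = "0.1.0"


@dataclass
class RunReport:
    seed: int
    version: str = VERSION
    params: dict = field(default_factory=dict)
    n_input_records: int = 0
    n_mapped_ists: int = 0
    n_dropped_by_filters: int = 0
    class_counts: dict = field(default_factory=dict)
    n_core_ists: int = 0
    n_clusters: int = 0
    n_irs: int = 0
    n_ppis: int = 0
    n_prey_proteins: int = 0
    n_ir_nodes: int = 0
    n_protein_nodes: int = 0
    n_total_nodes: int = 0
    n_intra_edges: int = 0
    n_inter_edges: int = 0
    n_multiple_partner_nodes: int = 0

    def check_consistency(self) -> None:
        """The arithmetic identities every run must satisfy."""
        assert sum(self.class_counts.values()) == self.n_mapped_ists, (
            "per-class IST counts must sum to the mapped total"
        )
        assert self.n_core_ists == self.class_counts.get(1, 0) + self.class_counts.get(2, 0)
        assert self.n_irs == self.n_clusters, "one IR per cluster"
        assert self.n_intra_edges == self.n_ir_nodes, "one intra edge per IR node"
        assert self.n_total_nodes == self.n_protein_nodes + self.n_ir_nodes

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_counts"] = {str(k): v for k, v in self.class_counts.items()}
        return d


def run_pipeline(
    ists: pd.DataFrame,
    mock: pd.DataFrame,
    reference: list[ReferenceProtein],
    bait_to_parent: dict[str, str],
    mapping_params: MappingParams | None = None,
    ir_params: IRParams | None = None,
    merge_params: MergeParams | None = None,
    domains: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Run the full in-silico analysis on a pre-mapped IST table.

    ``ists``/``mock`` follow the synthetic-data TSV schema (alignment fields
    included, so the quality filters are applied here exactly as they would
    be to raw alignment records). Returns a dict of stage outputs plus the
    ``RunReport``; when ``out_dir`` is given every table is written with a
    manifest.
    """
    mapping_params = mapping_params or MappingParams()
    ir_params = ir_params or IRParams()
    merge_params = merge_params or MergeParams()

    alignments = alignments_from_ist_table(ists) if len(ists) else ists.iloc[0:0]
    mapped = map_ists(alignments, reference, mapping_params)
    mock_alignments = alignments_from_ist_table(mock) if len(mock) else mock.iloc[0:0]
    mock_mapped = map_ists(mock_alignments, reference, mapping_params)

    classified = classify_ists(mapped, mock_mapped, bait_to_parent)
    core = core_subset(classified)
    clusters, irs = derive_irs(core, ir_params)
    ppis = call_ppis(core)
    if domains is not None and len(irs):
        irs, domain_fractions = annotate_domains(
            irs, domains, known_genes={p.gene_id for p in reference}
        )
    else:
        domain_fractions = {}
    ir_nodes = merge_irs(irs, merge_params)
    net = build_ir_network(ir_nodes, ppis)
    multiplicity = classify_partner_multiplicity(ir_nodes) if len(ir_nodes) else pd.Series(dtype=object)

    counts = net.counts()
    report = RunReport(
        seed=seed,
        params={
            "mapping": dataclasses.asdict(mapping_params),
            "ir": dataclasses.asdict(ir_params),
            "merge": dataclasses.asdict(merge_params),
        },
        n_input_records=len(ists),
        n_mapped_ists=len(classified),
        n_dropped_by_filters=len(ists) - len(classified),
        class_counts={int(c): int(n) for c, n in
                      classified["class"].value_counts().items()} if len(classified) else {},
        n_core_ists=len(core),
        n_clusters=len(clusters),
        n_irs=len(irs),
        n_ppis=len(ppis),
        n_prey_proteins=len(set(ppis["prey_gene"]) | set(ppis["bait_gene"])) if len(ppis) else 0,
        n_ir_nodes=counts["n_ir_nodes"],
        n_protein_nodes=counts["n_protein_nodes"],
        n_total_nodes=counts["n_total_nodes"],
        n_intra_edges=counts["n_intra_edges"],
        n_inter_edges=counts["n_inter_edges"],
        n_multiple_partner_nodes=int((multiplicity == "multiple").sum()),
    )
    report.check_consistency()

    outputs = {
        "classified_ists": classified,
        "core_ists": core,
        "clusters": clusters,
        "irs": irs,
        "ppis": ppis,
        "ir_nodes": ir_nodes,
        "network": net,
        "multiplicity": multiplicity,
        "domain_fractions": domain_fractions,
        "report": report,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def save(df, name):
            p = out / name
            iomod.write_tsv(df, p)
            written.append(p)

        save(classified, "ists_classified.tsv")
        save(core, "ists_core.tsv")
        save(clusters, "clusters.tsv")
        p = out / "irs.tsv"
        iomod.write_irs(irs, p) if len(irs) else iomod.write_tsv(irs, p)
        written.append(p)
        save(ppis, "ppis.tsv")
        save(ir_nodes, "ir_nodes.tsv")
        iomod.export_graphml(net.graph, out / "ir_network.graphml")
        written.append(out / "ir_network.graphml")
        iomod.export_sif(net.graph, out / "ir_network.sif")
        written.append(out / "ir_network.sif")
        report_path = out / "run_report.json"
        with open(report_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(report_path)
        iomod.write_manifest(written, out / "manifest.json")
    return outputs
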