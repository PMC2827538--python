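"""Readers, writers and region-string parsing.

All tabular artifacts are TSV; the reference proteome is FASTA plus a TSV
metadata table; disorder tracks use the DISOPRED2 text layout; graphs export
to GraphML and Cytoscape SIF. Region strings are 1-based inclusive and
accept both the ``38..63`` and the dotted ``124.176`` dialect.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import pandas as pd

from .intervals import Interval
from .simulate import ReferenceProtein

_REGION_RE = re.compile(r"^\s*(\d+)\s*\.\.?\s*(\d+)\s*$")


def parse_region_string(text: str) -> Interval:
    """Parse ``"a..b"`` or ``"a.b"`` into a 1-based inclusive interval."""
    m = _REGION_RE.match(text)
    if not m:
        raise ValueError(f"malformed region string {text!r}")
    a, b = int(m.group(1)), int(m.group(2))
    if a > b:
        raise ValueError(f"region start {a} exceeds end {b}")
    return (a, b)


def format_region(iv: Interval) -> str:
    return f"{iv[0]}..{iv[1]}"


# ---------------------------------------------------------------------------
# reference


def write_reference(reference: list[ReferenceProtein], fasta_path, meta_path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(p.sequence or "X" * p.aa_length), id=p.gene_id,
                  description=p.symbol)
        for p in reference
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {"gene_id": p.gene_id, "symbol": p.symbol, "aa_length": p.aa_length,
             "cds_length": p.cds_length}
            for p in reference
        ]
    ).to_csv(meta_path, sep="\t", index=False)


def read_reference(fasta_path, meta_path) -> list[ReferenceProtein]:
    from Bio import SeqIO

    meta = pd.read_csv(meta_path, sep="\t").set_index("gene_id")
    proteins = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        proteins.append(
            ReferenceProtein(
                gene_id=rec.id,
                symbol=str(row["symbol"]),
                aa_length=int(row["aa_length"]),
                cds_length=int(row["cds_length"]),
                sequence=str(rec.seq),
            )
        )
    return proteins


# ---------------------------------------------------------------------------
# tables


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_irs(irs: pd.DataFrame, path) -> None:
    """IR table with serialized ``start..end`` region strings."""
    out = irs.copy()
    out["region"] = [format_region((s, e)) for s, e in zip(out["aa_start"], out["aa_end"])]
    out["min_region"] = [format_region((s, e)) for s, e in zip(out["min_start"], out["min_end"])]
    write_tsv(out, path)


def read_irs(path) -> pd.DataFrame:
    df = read_tsv(path)
    if "aa_start" not in df.columns and "region" in df.columns:
        ivs = [parse_region_string(r) for r in df["region"]]
        df["aa_start"] = [s for s, _ in ivs]
        df["aa_end"] = [e for _, e in ivs]
    return df


# ---------------------------------------------------------------------------
# graphs


def export_graphml(graph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph, str(path))


def export_sif(graph, path) -> None:
    """Cytoscape SIF: one ``source<TAB>kind<TAB>target`` line per edge."""
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{d.get('kind', 'pp')}\t{v}\n")


# ---------------------------------------------------------------------------
# manifest


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list, out_path) -> dict:
    manifest = {Path(p).name: sha256_file(p) for p in sorted(map(str, paths))}
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
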