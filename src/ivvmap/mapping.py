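"""Mapping and classification of interaction sequence tags (ISTs).

Raw prey-fragment alignments against reference coding sequences are filtered
(e-value, match length, frameshift), converted from nucleotide to amino-acid
coordinates, and classified into the three evidence tiers:

* class 1 — overlaps another prey fragment from the same bait protein
  (bait constructs pooled by parent gene);
* class 2 — a lone fragment;
* class 3 — overlaps a fragment recovered in the baitless mock selection
  (technical false positive; applied first, and excluded from the core set).

Overlap means at least one shared residue on the same prey gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ReferenceProtein

log = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = [
    "query_id", "bait_id", "subject_gene", "nt_start", "nt_end",
    "e_value", "match_len_nt", "frameshift_flag",
]


@dataclass
class MappingParams:
    """Alignment-quality filters for positive matches."""

    max_e_value: float = 1.0e-5
    min_match_len_nt: int = 30
    exclude_frameshift: bool = True

    def __post_init__(self):
        if self.max_e_value <= 0 or self.min_match_len_nt <= 0:
            raise ValueError("mapping thresholds must be positive")


def nt_to_aa_interval(nt_start: int, nt_end: int) -> tuple[int, int]:
    """Convert a 1-based CDS nucleotide interval to the amino-acid interval
    of fully covered codons: [ceil(s/3), floor(e/3)]. May come out empty
    (start > end) for sub-codon matches."""
    return (math.ceil(nt_start / 3), math.floor(nt_end / 3))


def read_blast_tab(path, bait_id: str | None = None) -> pd.DataFrame:
    """Read BLAST tabular output (outfmt 6) into the alignment-record schema.

    Subject start/end are taken as the CDS nucleotide interval (reoriented if
    reversed); frameshift flags are not present in outfmt 6 and default to
    False. ``bait_id`` labels every record when the file is one selection.
    """
    names = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
             "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    raw = pd.read_csv(path, sep="\t", names=names, comment="#")
    out = pd.DataFrame(
        {
            "query_id": raw["qseqid"],
            "bait_id": bait_id if bait_id is not None else "NA",
            "subject_gene": raw["sseqid"],
            "nt_start": raw[["sstart", "send"]].min(axis=1),
            "nt_end": raw[["sstart", "send"]].max(axis=1),
            "e_value": raw["evalue"],
            "match_len_nt": raw["length"],
            "frameshift_flag": False,
        }
    )
    return out


def alignments_from_ist_table(ists: pd.DataFrame) -> pd.DataFrame:
    """Re-express a pre-mapped IST table as alignment records (nt = 3 x aa),
    the second entry point into ``map_ists``."""
    return pd.DataFrame(
        {
            "query_id": ists["ist_id"],
            "bait_id": ists["bait_id"],
            "subject_gene": ists["prey_gene"],
            "nt_start": 3 * (ists["aa_start"] - 1) + 1,
            "nt_end": 3 * ists["aa_end"],
            "e_value": ists["e_value"],
            "match_len_nt": ists["nt_match_len"],
            "frameshift_flag": ists["frameshift_flag"],
        }
    )


def map_ists(
    alignments: pd.DataFrame,
    reference: list[ReferenceProtein],
    params: MappingParams | None = None,
) -> pd.DataFrame:
    """Filter alignment records and map survivors to amino-acid ISTs.

    Thresholds are inclusive (e-value <= max, match length >= min). Multiple
    hits per query resolve to the best e-value, ties broken by longest match
    then lexicographic subject id. Records whose nt interval covers no full
    codon are dropped with a logged count.
    """
    params = params or MappingParams()
    ref_len = {p.gene_id: p.aa_length for p in reference}
    unknown = set(alignments["subject_gene"]) - set(ref_len) if len(alignments) else set()
    if unknown:
        raise ValueError(f"alignment subjects not in reference: {sorted(unknown)[:5]}")

    if len(alignments) == 0:
        return pd.DataFrame(columns=["ist_id", "bait_id", "prey_gene",
                                     "aa_start", "aa_end", "e_value", "match_len_nt"])

    keep = (alignments["e_value"] <= params.max_e_value) & (
        alignments["match_len_nt"] >= params.min_match_len_nt
    )
    if params.exclude_frameshift:
        keep &= ~alignments["frameshift_flag"].astype(bool)
    surv = alignments[keep].copy()

    # best hit per query: lowest e-value, longest match, lexicographic subject
    surv = surv.sort_values(
        ["query_id", "e_value", "match_len_nt", "subject_gene"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates("query_id", keep="first")

    surv["aa_start"] = ((surv["nt_start"].astype(int) + 2) // 3).clip(lower=1)
    lengths = surv["subject_gene"].map(ref_len)
    surv["aa_end"] = (surv["nt_end"].astype(int) // 3).clip(upper=lengths)
    nonempty = surv["aa_start"] <= surv["aa_end"]
    if (~nonempty).sum():
        log.info("map_ists: dropped %d records with empty aa interval", (~nonempty).sum())
    surv = surv[nonempty]

    out = pd.DataFrame(
        {
            "ist_id": surv["query_id"],
            "bait_id": surv["bait_id"],
            "prey_gene": surv["subject_gene"],
            "aa_start": surv["aa_start"].astype(int),
            "aa_end": surv["aa_end"].astype(int),
            "e_value": surv["e_value"],
            "match_len_nt": surv["match_len_nt"].astype(int),
        }
    ).reset_index(drop=True)
    return out


def _overlap_any(starts, ends, mock_starts, mock_ends) -> np.ndarray:
    """For each interval i, True when it shares >= 1 residue with any interval
    in the second set."""
    if len(mock_starts) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    s = np.asarray(starts)[:, None]
    e = np.asarray(ends)[:, None]
    ms = np.asarray(mock_starts)[None, :]
    me = np.asarray(mock_ends)[None, :]
    return ((s <= me) & (ms <= e)).any(axis=1)


def classify_ists(
    ists: pd.DataFrame,
    mock: pd.DataFrame,
    bait_to_parent: dict[str, str],
) -> pd.DataFrame:
    """Assign class labels 1/2/3 to every IST.

    Mock exclusion has precedence: any IST overlapping a mock fragment on the
    same prey gene is class 3 regardless of same-bait overlap. Among the
    remaining ISTs, class 1 requires overlap with at least one other
    surviving IST from the same bait parent gene on the same prey gene;
    class-3 fragments do not serve as class-1 partners. Symmetric and
    idempotent.
    """
    out = ists.copy().reset_index(drop=True)
    if len(out) == 0:
        out["bait_parent_gene"] = pd.Series(dtype=object)
        out["class"] = pd.Series(dtype="int64")
        return out
    unknown = set(out["bait_id"]) - set(bait_to_parent)
    if unknown:
        raise ValueError(f"unknown bait ids: {sorted(unknown)}")
    out["bait_parent_gene"] = out["bait_id"].map(bait_to_parent)

    cls = np.full(len(out), 2, dtype=int)
    mock_by_gene: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if mock is not None and len(mock):
        for g, grp in mock.groupby("prey_gene"):
            mock_by_gene[g] = (grp["aa_start"].to_numpy(), grp["aa_end"].to_numpy())

    for g, grp in out.groupby("prey_gene"):
        idx = grp.index.to_numpy()
        s = grp["aa_start"].to_numpy()
        e = grp["aa_end"].to_numpy()
        ms, me = mock_by_gene.get(g, (np.array([]), np.array([])))
        is3 = _overlap_any(s, e, ms, me)
        cls[idx[is3]] = 3
        # class 1 among non-mock-overlapping, pooled by bait parent gene
        rem = ~is3
        parents = grp["bait_parent_gene"].to_numpy()
        for parent in np.unique(parents[rem]):
            sel = rem & (parents == parent)
            if sel.sum() < 2:
                continue
            ss, ee = s[sel], e[sel]
            pair = (ss[:, None] <= ee[None, :]) & (ss[None, :] <= ee[:, None])
            np.fill_diagonal(pair, False)
            cls[idx[sel][pair.any(axis=1)]] = 1
    out["class"] = cls
    return out


def core_subset(ists: pd.DataFrame) -> pd.DataFrame:
    """The core evidence set: classes 1 and 2 (mock-overlapping class 3
    excluded as technical false positives)."""
    if "class" not in ists.columns or ists["class"].isna().any():
        raise ValueError("ISTs must be classified before taking the core subset")
    return ists[ists["class"].isin([1, 2])].reset_index(drop=True)
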