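"""Intrinsic-disorder composition of region and protein datasets.

Disorder tracks come from DISOPRED2-style per-residue calls (the default 5%
false-positive-rate threshold of that predictor decides the mark in the
file; this module only parses the calls). Datasets of regions or whole
proteins are summarized as residue-pooled disordered proportions and
compared with Fisher's exact test; the matched null is a set of random
regions re-drawn from the proteome with the same length distribution as the
observed IRs. Partner-count comparisons between multiple- and single-IR
prey proteins use the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval

log = logging.getLogger(__name__)


@dataclass
class RegionDataset:
    """A named collection of (gene, interval) regions; an interval covering
    the whole protein stands in for a protein-level entry."""

    name: str
    regions: list[tuple[str, Interval]] = field(default_factory=list)

    @classmethod
    def from_irs(cls, name: str, irs: pd.DataFrame) -> "RegionDataset":
        return cls(name, [(g, (int(s), int(e))) for g, s, e in
                          zip(irs["prey_gene"], irs["aa_start"], irs["aa_end"])])

    @classmethod
    def whole_proteins(cls, name: str, genes: list[str],
                       lengths: dict[str, int]) -> "RegionDataset":
        return cls(name, [(g, (1, lengths[g])) for g in genes])


# ---------------------------------------------------------------------------
# DISOPRED2-style text format


def parse_disopred2(path) -> np.ndarray:
    """Parse one DISOPRED2 output file into a binary track (1 = disordered).

    Expected data lines: residue index, amino acid, state mark ('*'
    disordered, '.' ordered), confidence. Residue indices must be contiguous
    from 1; a gap is rejected with its line number.
    """
    states = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 3 or not parts[0].isdigit():
                continue  # header / comment
            idx, mark = int(parts[0]), parts[2]
            if idx != len(states) + 1:
                raise ValueError(
                    f"{path}: residue index {idx} at line {lineno}, expected {len(states) + 1}"
                )
            if mark not in ("*", "."):
                raise ValueError(f"{path}: bad state mark {mark!r} at line {lineno}")
            states.append(1 if mark == "*" else 0)
    if not states:
        raise ValueError(f"{path}: no residue records found")
    return np.asarray(states, dtype=np.int8)


def write_disopred2(track: np.ndarray, sequence: str | None, path) -> None:
    """Write a track in the DISOPRED2 plain-text layout (round-trips with
    :func:`parse_disopred2`)."""
    with open(path, "w") as fh:
        fh.write("# ----- DISOPRED version 2 -----\n")
        fh.write("# Disordered residues are marked with asterisks (*)\n")
        for i, state in enumerate(track):
            aa = sequence[i] if sequence else "X"
            mark = "*" if state else "."
            conf = 0.9 if state else 0.05
            fh.write(f"{i + 1:>5} {aa} {mark} {conf:.2f}\n")


# ---------------------------------------------------------------------------
# proportions and tests


def disorder_counts(dataset: RegionDataset, profiles: dict[str, np.ndarray],
                    skip_missing: bool = False) -> tuple[int, int]:
    """(disordered, total) residue counts pooled over all regions."""
    disordered = total = 0
    missing = []
    for gene, (s, e) in dataset.regions:
        track = profiles.get(gene)
        if track is None:
            missing.append(gene)
            continue
        if not (1 <= s <= e <= len(track)):
            raise ValueError(f"{dataset.name}: region {s}..{e} outside {gene}")
        seg = track[s - 1:e]
        disordered += int(seg.sum())
        total += len(seg)
    if missing and not skip_missing:
        raise ValueError(
            f"{dataset.name}: no disorder profile for {sorted(set(missing))[:5]}"
        )
    if missing:
        log.warning("%s: skipped %d regions without profiles", dataset.name, len(missing))
    return disordered, total


def disorder_proportion(dataset: RegionDataset, profiles: dict[str, np.ndarray],
                        skip_missing: bool = False) -> dict:
    d, t = disorder_counts(dataset, profiles, skip_missing=skip_missing)
    return {
        "dataset": dataset.name,
        "disordered_residues": d,
        "total_residues": t,
        "proportion": d / t if t else float("nan"),
    }


def random_region_null(
    profiles: dict[str, np.ndarray],
    source: RegionDataset,
    n: int = 10000,
    seed: int = 0,
) -> RegionDataset:
    """Random regions matched to the source length distribution.

    Lengths are resampled from the source's empirical lengths; the host gene
    is uniform among genes long enough; the start uniform among valid
    positions. A length longer than every protein is redrawn with a log
    entry. Deterministic per seed. The conventional null size is n = 10000.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([e - s + 1 for _, (s, e) in source.regions])
    if len(lengths) == 0:
        raise ValueError("source dataset has no regions")
    genes = sorted(profiles)
    gene_lens = np.array([len(profiles[g]) for g in genes])
    max_len = gene_lens.max()
    regions = []
    redrawn = 0
    while len(regions) < n:
        L = int(lengths[rng.integers(0, len(lengths))])
        if L > max_len:
            redrawn += 1
            continue
        eligible = np.flatnonzero(gene_lens >= L)
        g = genes[int(eligible[rng.integers(0, len(eligible))])]
        start = int(rng.integers(1, len(profiles[g]) - L + 2))
        regions.append((g, (start, start + L - 1)))
    if redrawn:
        log.info("random_region_null: redrew %d over-long lengths", redrawn)
    return RegionDataset(name="random_regions", regions=regions)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """(odds ratio, two-sided exact p) for a 2x2 count table. The two-sided
    p sums all tables with point probability <= the observed one. A zero
    margin makes the table degenerate: p = 1."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        odds = float("nan")
        return odds, 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def compare_disorder(
    dataset_a: RegionDataset,
    dataset_b: RegionDataset,
    profiles: dict[str, np.ndarray],
    skip_missing: bool = False,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> dict:
    """Fisher's exact test on the pooled 2x2 (dataset x disordered/ordered)
    residue table.

    Residue pooling treats residues as independent, as the standard analysis
    does despite within-protein correlation; ``n_bootstrap`` > 0 additionally
    reports a per-region bootstrap p for the proportion difference, labelled
    as an extension.
    """
    da, ta = disorder_counts(dataset_a, profiles, skip_missing)
    db, tb = disorder_counts(dataset_b, profiles, skip_missing)
    table = [[da, ta - da], [db, tb - db]]
    odds, p = fisher_exact_2x2(table)
    out = {
        "table": table,
        "proportion_a": da / ta if ta else float("nan"),
        "proportion_b": db / tb if tb else float("nan"),
        "odds_ratio": odds,
        "p_fisher": p,
        "degenerate_margin": ta == 0 or tb == 0 or da + db == 0 or (ta - da) + (tb - db) == 0,
    }
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        obs = abs(out["proportion_a"] - out["proportion_b"])

        def region_stats(ds):
            return np.array(
                [
                    (profiles[g][s - 1:e].sum(), e - s + 1)
                    for g, (s, e) in ds.regions if g in profiles
                ],
                dtype=float,
            )

        ra, rb = region_stats(dataset_a), region_stats(dataset_b)
        pooled = np.vstack([ra, rb])
        na = len(ra)
        hits = 0
        for _ in range(n_bootstrap):
            perm = rng.permutation(len(pooled))
            a, b = pooled[perm[:na]], pooled[perm[na:]]
            diff = abs(a[:, 0].sum() / a[:, 1].sum() - b[:, 0].sum() / b[:, 1].sum())
            if diff >= obs:
                hits += 1
        out["p_region_bootstrap"] = (hits + 1) / (n_bootstrap + 1)
        out["p_region_bootstrap_note"] = "per-region permutation extension, not the primary test"
    return out


def partner_count_comparison(
    multi_prey: set,
    single_prey: set,
    partner_counts: dict[str, float],
) -> dict:
    """Compare known-partner counts between prey proteins with multiple-IR
    interfaces and the rest: group means plus a two-sided Wilcoxon rank-sum
    p (exact enumeration when both groups are <= 10 without ties, else the
    normal approximation with tie correction)."""
    missing = (multi_prey | single_prey) - set(partner_counts)
    if missing:
        raise ValueError(f"partner counts missing for {sorted(missing)[:5]}")
    a = np.array([partner_counts[g] for g in sorted(multi_prey)], dtype=float)
    b = np.array([partner_counts[g] for g in sorted(single_prey)], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "mean_multiple": float(a.mean()),
        "mean_single": float(b.mean()),
        "n_multiple": len(a),
        "n_single": len(b),
        "p_ranksum": float(res.pvalue),
        "method": method,
    }
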