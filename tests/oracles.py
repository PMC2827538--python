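"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive (exhaustive enumeration, exact
rational arithmetic) and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def interval_overlap(a, b) -> bool:
    return max(a[0], b[0]) <= min(a[1], b[1])


def brute_classify(ists, mock):
    """Exhaustive pairwise classification.

    ``ists``: list of (ist_id, bait_parent_gene, prey_gene, start, end);
    ``mock``: list of (prey_gene, start, end). Returns {ist_id: class}.
    """
    def hits_mock(gene, iv):
        return any(g == gene and interval_overlap(iv, (ms, me)) for g, ms, me in mock)

    mock3 = {iid for iid, _, gene, s, e in ists if hits_mock(gene, (s, e))}
    cls = {iid: 3 for iid in mock3}
    for i, (iid, bait, gene, s, e) in enumerate(ists):
        if iid in mock3:
            continue
        partner = any(
            j != i
            and jid not in mock3  # class-3 fragments are not class-1 partners
            and jbait == bait
            and jgene == gene
            and interval_overlap((s, e), (js, je))
            for j, (jid, jbait, jgene, js, je) in enumerate(ists)
        )
        cls[iid] = 1 if partner else 2
    return cls


def common_intersection(intervals):
    return (max(s for s, _ in intervals), min(e for _, e in intervals))


def brute_clusters(intervals, min_len):
    """Partition of interval indices by exhaustive subset enumeration.

    All maximal subsets whose common intersection spans >= min_len residues,
    then unique assignment of each interval to its best containing subset
    (longest intersection, then leftmost/smallest minimum region, then
    member tuple), unassigned intervals as singletons. Mirrors the stated
    rule, not the implementation.
    """
    n = len(intervals)
    good = []
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            s, e = common_intersection([intervals[i] for i in combo])
            if e - s + 1 >= min_len:
                good.append(frozenset(combo))
    maximal = [g for g in good if not any(g < h for h in good)]

    assignment = {}
    for i in range(n):
        options = []
        for m in maximal:
            if i in m:
                s, e = common_intersection([intervals[j] for j in m])
                options.append(((-(e - s + 1), s, e, tuple(sorted(m))), m))
        if options:
            assignment[i] = min(options)[1]
    groups = {}
    clusters = []
    for i in range(n):
        if i in assignment:
            groups.setdefault(assignment[i], []).append(i)
        else:
            clusters.append([i])
    clusters.extend(sorted(g) for g in groups.values())
    return sorted(sorted(c) for c in clusters)


def hypergeom_pmf(k, N, K, n) -> Fraction:
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hypergeom_sf_brute(kmin, N, K, n) -> float:
    """P(X >= kmin) by exact tail summation."""
    return float(sum(hypergeom_pmf(k, N, K, n) for k in range(kmin, min(K, n) + 1)))


def fisher_two_sided_brute(a, b, c, d) -> float:
    """Two-sided Fisher p by summing every table (with the observed margins)
    whose exact point probability is <= the observed one."""
    r1, c1, N = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, N, c1, r1)
    total = Fraction(0)
    for k in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
        p = hypergeom_pmf(k, N, c1, r1)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def ranksum_exact_two_sided(x, y) -> float:
    """Two-sided rank-sum p by enumerating every assignment of the pooled
    values to the two groups (ties absent)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    ws = [sum(pooled.index(v) + 1 for v in combo)
          for combo in itertools.combinations(pooled, n)]
    mean_w = sum(ws) / len(ws)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / len(ws)
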