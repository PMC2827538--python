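#!/usr/bin/env python
"""Cluster core ISTs into interacting regions (IRs) and call PPIs.

Each (prey, bait) group is partitioned into clusters sharing a >= 3 aa
minimum region; the cluster span (maximum region) is the IR. Recovery is
scored against the planted truth by minimum-region Jaccard.
"""

from pathlib import Path

import ivvmap as m
from ivvmap import io as iomod

RES = Path(__file__).resolve().parent.parent / "results"


def main():
    core = iomod.read_tsv(RES / "ists_core.tsv")
    clusters, irs = m.derive_irs(core)
    ppis = m.call_ppis(core)
    iomod.write_tsv(clusters, RES / "clusters.tsv")
    iomod.write_irs(irs, RES / "irs.tsv")
    iomod.write_tsv(ppis, RES / "ppis.tsv")

    truth = iomod.read_tsv(RES / "sim" / "truth_planted_irs.tsv")
    overlap_hit = 0
    for _, t in truth.iterrows():
        iv = m.parse_region_string(t["region"])
        grp = clusters[(clusters["bait_parent_gene"] == t["bait_gene"])
                       & (clusters["prey_gene"] == t["prey_gene"])]
        if any(m.overlaps((c["max_start"], c["max_end"]), iv) for _, c in grp.iterrows()):
            overlap_hit += 1

    print(f"{len(core)} core ISTs -> {len(clusters)} clusters = {len(irs)} IRs, "
          f"{len(ppis)} PPIs")
    print(f"planted interfaces covered by >= 1 derived IR: {overlap_hit}/{len(truth)}")
    print("randomly primed fragments are staggered, so a planted interface "
          "typically splits into a few clusters whose IRs all cover it; "
          "exact single-cluster recovery holds only for fragments that fully "
          "straddle the interface (see the recovery checks in the test suite)")


if __name__ == "__main__":
    main()
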