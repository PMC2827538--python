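#!/usr/bin/env python
"""Disorder composition of the recovered IRs and the partner-count contrast.

Compares the residue-pooled disorder proportion of the IR set against a
10,000-region length-matched random null (Fisher's exact test), and the
simulated known-partner counts of multiple- vs single-interface prey
proteins (Wilcoxon rank-sum).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import ivvmap as m
from ivvmap.disorder import RegionDataset

RES = Path(__file__).resolve().parent.parent / "results"
SEED = 1_234_567


def main():
    from ivvmap import io as iomod

    irs = iomod.read_irs(RES / "irs.tsv")
    profiles = {p.stem: m.parse_disopred2(p)
                for p in sorted((RES / "sim" / "disorder").glob("*.diso"))}

    ir_ds = RegionDataset.from_irs("ivv_core_ir", irs)
    null_ds = m.random_region_null(profiles, ir_ds, n=10_000, seed=SEED)
    rows = [m.disorder_proportion(ir_ds, profiles),
            m.disorder_proportion(null_ds, profiles)]
    comp = m.compare_disorder(ir_ds, null_ds, profiles, n_bootstrap=500, seed=SEED)
    iomod.write_tsv(pd.DataFrame(rows), RES / "disorder_summary.tsv")

    nodes = iomod.read_tsv(RES / "ir_nodes.tsv")
    multi = set(nodes.loc[nodes["multiplicity"] == "multiple", "prey_gene"])
    single = set(nodes.loc[nodes["multiplicity"] == "single", "prey_gene"]) - multi
    rng = np.random.default_rng(SEED)
    counts = {g: int(rng.poisson(11)) for g in multi}
    counts |= {g: int(rng.poisson(7)) for g in single}
    partner = m.partner_count_comparison(multi, single, counts)
    with open(RES / "disorder_and_partners.json", "w") as fh:
        json.dump({"disorder_comparison": {k: v for k, v in comp.items() if k != "table"},
                   "partner_comparison": partner}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    print(f"IR disorder {rows[0]['proportion']:.3f} vs matched random "
          f"{rows[1]['proportion']:.3f}")
    print(f"residue-pooled Fisher p = {comp['p_fisher']:.3g} "
          f"(anti-conservative: residues within a region are correlated); "
          f"per-region bootstrap p = {comp['p_region_bootstrap']:.3g} -- "
          f"the generator plants no IR/disorder association, so the "
          f"region-level test shows parity")
    print(f"partner counts: multiple-interface prey mean {partner['mean_multiple']:.1f} "
          f"vs single {partner['mean_single']:.1f} "
          f"(rank-sum p = {partner['p_ranksum']:.3g}, n = {partner['n_multiple']} vs "
          f"{partner['n_single']})")


if __name__ == "__main__":
    main()
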