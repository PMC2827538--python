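#!/usr/bin/env python
"""Generate the synthetic mRNA-display screen used by the downstream steps.

Writes the reference proteome, bait panel, per-bait IST libraries with 20
planted interacting regions plus one three-bait shared interface, the
baitless mock library, disorder tracks and the planted truth under
results/sim/.
"""

from pathlib import Path

import numpy as np

import ivvmap as m
from ivvmap import io as iomod
from ivvmap.disorder import write_disopred2

SEED = 20_260_930 % (2**31)
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ref = m.make_reference(150, {"name": "uniform", "low": 150, "high": 500}, seed=SEED)
    baits = m.make_baits(ref, 10, seed=SEED + 1)
    rng = np.random.default_rng(SEED + 2)
    planted = []
    for i, b in enumerate(baits):
        for j in range(2):
            prey = ref[(7 * i + 3 * j + 11) % len(ref)]
            start = int(rng.integers(10, prey.aa_length - 60))
            planted.append(m.PlantedIR(b.parent_gene, prey.gene_id, start, start + 40))
    for b in baits[:3]:  # shared (competitive) interface
        planted.append(m.PlantedIR(b.parent_gene, ref[5].gene_id, 50, 90))

    cfg = m.SimulationConfig(
        n_prey_genes=len(ref), n_baits=len(baits), planted_irs=planted,
        n_fragments_per_bait=60, n_mock_fragments=40, seed=SEED + 3,
    )
    ists, mock, truth = m.simulate_selection(ref, baits, cfg)
    tracks = m.simulate_disorder(ref, cfg.disorder, seed=SEED + 4)

    iomod.write_reference(ref, OUT / "reference.fasta", OUT / "reference.tsv")
    iomod.write_tsv(ists, OUT / "ists.tsv")
    iomod.write_tsv(mock, OUT / "mock.tsv")
    import pandas as pd

    iomod.write_tsv(
        pd.DataFrame([{"bait_id": b.bait_id, "parent_gene": b.parent_gene,
                       "region": iomod.format_region(b.region),
                       "is_full_length": b.is_full_length} for b in baits]),
        OUT / "baits.tsv",
    )
    iomod.write_tsv(
        pd.DataFrame([{"bait_gene": p.bait_gene, "prey_gene": p.prey_gene,
                       "region": iomod.format_region(p.interval)} for p in planted]),
        OUT / "truth_planted_irs.tsv",
    )
    dis = OUT / "disorder"
    dis.mkdir(exist_ok=True)
    by_id = {p.gene_id: p for p in ref}
    for g, t in tracks.items():
        write_disopred2(t, by_id[g].sequence, dis / f"{g}.diso")

    print(f"simulated {len(ists)} bait-library ISTs and {len(mock)} mock fragments")
    print(f"planted {len(planted)} IRs ({len(baits)} baits, 1 shared interface) -> {OUT}")


if __name__ == "__main__":
    main()
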