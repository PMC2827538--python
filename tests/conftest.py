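import numpy as np
import pandas as pd
import pytest

import ivvmap as m
from ivvmap.simulate import IST_COLUMNS


def make_ist_frame(rows):
    """rows: (ist_id, bait_id, prey_gene, start, end) -> minimal IST table."""
    return pd.DataFrame(
        [
            {
                "ist_id": r[0], "bait_id": r[1], "prey_gene": r[2],
                "aa_start": r[3], "aa_end": r[4],
                "nt_match_len": 3 * (r[4] - r[3] + 1),
                "e_value": 1e-20, "frameshift_flag": False, "library": "bait",
            }
            for r in rows
        ],
        columns=IST_COLUMNS if not rows else None,
    )


def random_ist_instance(rng, n_ists, n_baits=2, n_genes=2, n_mock=2, L=120):
    """A random small classification instance plus its tuple form for oracles."""
    ists, tuples = [], []
    for i in range(n_ists):
        s = int(rng.integers(1, L - 5))
        e = int(s + rng.integers(1, 40))
        e = min(e, L)
        k = rng.integers(0, n_baits)
        gene = f"G{rng.integers(0, n_genes)}"
        ists.append((f"I{i}", f"B{k}", gene, s, e))
        tuples.append((f"I{i}", f"BG{k}", gene, s, e))  # oracle sees parent genes
    mock = []
    for i in range(n_mock):
        s = int(rng.integers(1, L - 5))
        e = min(int(s + rng.integers(1, 40)), L)
        mock.append((f"G{rng.integers(0, n_genes)}", s, e))
    return ists, mock, tuples


@pytest.fixture(scope="session")
def small_reference():
    return m.make_reference(40, {"name": "uniform", "low": 150, "high": 400}, seed=11)


@pytest.fixture(scope="session")
def planted_screen(small_reference):
    """Noise-free straddle-mode screen: 5 baits, one planted IR each."""
    ref = small_reference
    baits = m.make_baits(ref, 5, seed=12, domain_fraction=0.0)
    rng = np.random.default_rng(13)
    planted = []
    for i, b in enumerate(baits):
        prey = ref[10 + i]
        start = int(rng.integers(20, 60))
        planted.append(m.PlantedIR(b.parent_gene, prey.gene_id, start, start + 30))
    cfg = m.SimulationConfig(
        n_prey_genes=len(ref), n_baits=len(baits), planted_irs=planted,
        n_fragments_per_bait=20, n_mock_fragments=0, background_fraction=0.0,
        frameshift_rate=0.0, weak_alignment_rate=0.0,
        planted_mode="straddle", seed=14,
    )
    ists, mock, truth = m.simulate_selection(ref, baits, cfg)
    bait_map = {b.bait_id: b.parent_gene for b in baits}
    return {"reference": ref, "baits": baits, "bait_map": bait_map,
            "config": cfg, "ists": ists, "mock": mock, "truth": truth}
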