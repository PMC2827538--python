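"""Synthetic mRNA-display (IVV) screen generator with full ground truth.

The generator emulates the data-generating process of an in vitro selection
screen: a reference proteome, a panel of bait constructs, per-bait libraries
of randomly primed prey fragments concentrated on planted interacting
regions, a baitless mock library of pure background fragments, per-residue
intrinsic-disorder tracks, Pfam-style domain intervals, tissue expression
matrices and toy two-chain structures. Every random draw flows from a single
seed, so identical configurations are byte-identical, and the planted truth
is returned alongside the observations so downstream recovery is testable
without any external data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Interval, clip, length

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ReferenceProtein:
    """One reference protein (RefSeq-like entry).

    ``cds_length`` includes the stop codon, hence 3*aa_length + 3.
    """

    gene_id: str
    symbol: str
    aa_length: int
    cds_length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.aa_length < 1:
            raise ValueError(f"{self.gene_id}: aa_length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.aa_length:
            raise ValueError(f"{self.gene_id}: sequence length != aa_length")


@dataclass(frozen=True)
class BaitConstruct:
    """A bait protein construct: a full-length protein or one of its domains."""

    bait_id: str
    parent_gene: str
    region: Interval
    is_full_length: bool


@dataclass(frozen=True)
class PlantedIR:
    """Ground-truth interacting region: bait parent gene x prey interval."""

    bait_gene: str
    prey_gene: str
    start: int
    end: int

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class DisorderParams:
    """Markov-block disorder model: target coverage and mean disordered run length."""

    coverage: float = 0.35
    mean_block_len: float = 30.0

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("disorder coverage must be in [0, 1]")
        if self.mean_block_len < 1.0:
            raise ValueError("mean_block_len must be >= 1")


@dataclass
class SimulationConfig:
    """Conditions of one synthetic screen.

    Defaults mirror the real screen's scale where stated (six selection
    rounds; a randomly primed library whose fragments are a few hundred nt)
    and realistic values otherwise, documented in the methods note.

    ``planted_mode``:
      * ``"envelope"`` — planted-fragment start uniform in
        [IR.start - L + 1, IR.end] (L = fragment aa length), so every planted
        fragment overlaps its IR by >= 1 residue; staggered fragments as
        random priming produces them.
      * ``"straddle"`` — every planted fragment fully covers its IR, with
        total flanking length <= the IR length; guarantees each planted IR is
        recoverable as a single cluster at Jaccard >= 0.5.
    """

    n_prey_genes: int = 200
    n_baits: int = 10
    planted_irs: list[PlantedIR] = field(default_factory=list)
    fragment_length_distribution: dict = field(
        default_factory=lambda: {"name": "lognormal", "mu": math.log(300.0), "sigma": 0.5}
    )
    n_fragments_per_bait: int = 40
    n_mock_fragments: int = 50
    background_fraction: float = 0.3
    frameshift_rate: float = 0.05
    weak_alignment_rate: float = 0.02
    disorder: DisorderParams = field(default_factory=DisorderParams)
    n_rounds: int = 6
    enrichment_factor: float = 2.0
    planted_mode: str = "envelope"
    seed: int = 0

    def __post_init__(self):
        for name in ("background_fraction", "frameshift_rate", "weak_alignment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.planted_mode not in ("envelope", "straddle"):
            raise ValueError(f"unknown planted_mode {self.planted_mode!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated screen.

    ``true_classes`` is the source-based expectation (planted fragment ->
    class 1, background -> class 2); realized classes may differ once mock
    overlap is taken into account, which is what the classifier measures.
    """

    planted_irs: list[PlantedIR]
    true_classes: dict[str, int]
    true_source: dict[str, str]
    true_disorder: dict[str, np.ndarray] = field(default_factory=dict)


IST_COLUMNS = [
    "ist_id", "bait_id", "prey_gene", "aa_start", "aa_end",
    "nt_match_len", "e_value", "frameshift_flag", "library",
]


def empty_ist_table() -> pd.DataFrame:
    return pd.DataFrame(columns=IST_COLUMNS)


# ---------------------------------------------------------------------------
# reference proteome and bait panel


def _draw_lengths(n: int, dist: dict, rng: np.random.Generator) -> np.ndarray:
    name = dist.get("name", "lognormal")
    if name == "fixed":
        return np.full(n, int(dist["length"]))
    if name == "lognormal":
        return np.rint(rng.lognormal(dist["mu"], dist["sigma"], size=n)).astype(int)
    if name == "uniform":
        return rng.integers(int(dist["low"]), int(dist["high"]) + 1, size=n)
    raise ValueError(f"unknown length distribution {name!r}")


def make_reference(
    n_genes: int,
    length_distribution: dict | None = None,
    seed: int = 0,
    with_sequence: bool = True,
) -> list[ReferenceProtein]:
    """Synthesize a reference proteome.

    Lengths are drawn from ``length_distribution`` (default lognormal,
    median exp(6) ~ 403 aa, about the human average) and clipped to >= 50 aa.
    Deterministic for a fixed seed; gene ids are unique.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    dist = length_distribution or {"name": "lognormal", "mu": 6.0, "sigma": 0.5}
    rng = np.random.default_rng(seed)
    lengths = np.maximum(_draw_lengths(n_genes, dist, rng), 50)
    proteins = []
    for i, L in enumerate(lengths):
        L = int(L)
        seq = None
        if with_sequence:
            seq = "".join(np.asarray(list(AA_ALPHABET))[rng.integers(0, 20, size=L)])
        proteins.append(
            ReferenceProtein(
                gene_id=f"G{i:05d}",
                symbol=f"SYM{i}",
                aa_length=L,
                cds_length=3 * L + 3,
                sequence=seq,
            )
        )
    return proteins


def make_baits(
    reference: list[ReferenceProtein],
    n_baits: int,
    seed: int = 0,
    domain_fraction: float = 0.3,
) -> list[BaitConstruct]:
    """Pick bait constructs from the reference.

    A fraction are domain constructs (a random subregion of >= 50 aa when the
    parent allows), the rest full length. Domain constructs share their
    parent gene with the corresponding full-length reading of the bait, which
    exercises the pool-by-parent-gene classification rule.
    """
    if n_baits < 1:
        raise ValueError("n_baits must be >= 1")
    rng = np.random.default_rng(seed)
    parents = [reference[i] for i in rng.choice(len(reference), size=n_baits, replace=False)]
    baits = []
    for i, parent in enumerate(parents):
        full = rng.random() >= domain_fraction or parent.aa_length < 100
        if full:
            region = (1, parent.aa_length)
        else:
            dlen = int(rng.integers(50, parent.aa_length // 2 + 1))
            start = int(rng.integers(1, parent.aa_length - dlen + 2))
            region = (start, start + dlen - 1)
        baits.append(
            BaitConstruct(
                bait_id=f"B{i:03d}",
                parent_gene=parent.gene_id,
                region=region,
                is_full_length=full,
            )
        )
    return baits


# ---------------------------------------------------------------------------
# fragment libraries


def _fragment_aa_length(dist: dict, rng: np.random.Generator) -> int:
    nt = int(max(30, _draw_lengths(1, dist, rng)[0]))
    return max(1, nt // 3)


def _place_background(ref_by_id: dict[str, ReferenceProtein], dist: dict,
                      rng: np.random.Generator) -> tuple[str, Interval]:
    gene_ids = sorted(ref_by_id)
    gene = gene_ids[int(rng.integers(0, len(gene_ids)))]
    L = ref_by_id[gene].aa_length
    flen = min(_fragment_aa_length(dist, rng), L)
    start = int(rng.integers(1, L - flen + 2))
    return gene, (start, start + flen - 1)


def _place_planted(ir: PlantedIR, prot: ReferenceProtein, dist: dict,
                   mode: str, rng: np.random.Generator) -> Interval:
    ir_len = length(ir.interval)
    if mode == "straddle":
        flank_total = int(rng.integers(0, ir_len + 1))
        left = int(rng.integers(0, flank_total + 1))
        iv = (ir.start - left, ir.end + (flank_total - left))
    else:
        flen = _fragment_aa_length(dist, rng)
        start = int(rng.integers(ir.start - flen + 1, ir.end + 1))
        iv = (start, start + flen - 1)
    return clip(iv, 1, prot.aa_length)


def simulate_selection(
    reference: list[ReferenceProtein],
    baits: list[BaitConstruct],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate per-bait selections plus a baitless mock library.

    Returns (IST table, mock table, truth). Each fragment carries a synthetic
    alignment record (e-value, nt match length, frameshift flag) so the
    mapping filters are exercised: a ``weak_alignment_rate`` fraction receive
    a failing e-value, and frameshift flags are Bernoulli(frameshift_rate).
    Planted fragments are drawn with sampling weight multiplied by
    ``enrichment_factor ** n_rounds`` relative to background, modelling the
    final library composition after affinity selection.
    """
    ref_by_id = {p.gene_id: p for p in reference}
    for ir in config.planted_irs:
        if ir.prey_gene not in ref_by_id:
            raise ValueError(f"planted IR prey gene {ir.prey_gene} not in reference")
        prot = ref_by_id[ir.prey_gene]
        if not (1 <= ir.start <= ir.end <= prot.aa_length):
            raise ValueError(
                f"planted IR {ir.start}..{ir.end} outside {ir.prey_gene} (len {prot.aa_length})"
            )
        if ir.bait_gene not in {b.parent_gene for b in baits}:
            raise ValueError(f"planted IR bait gene {ir.bait_gene} has no bait construct")

    rng = np.random.default_rng(config.seed)
    dist = config.fragment_length_distribution
    rows: list[dict] = []
    true_classes: dict[str, int] = {}
    true_source: dict[str, str] = {}
    planted_by_gene: dict[str, list[PlantedIR]] = {}
    for ir in config.planted_irs:
        planted_by_gene.setdefault(ir.bait_gene, []).append(ir)

    def emit(table: str, bait_id: str, gene: str, iv: Interval, source: str):
        n = len(rows)
        ist_id = f"{'IST' if table == 'bait' else 'MCK'}{n:06d}"
        aa_len = length(iv)
        weak = rng.random() < config.weak_alignment_rate
        e_value = 10.0 ** rng.uniform(-4, -1) if weak else 10.0 ** rng.uniform(-50, -6)
        rows.append(
            {
                "ist_id": ist_id,
                "bait_id": bait_id,
                "prey_gene": gene,
                "aa_start": iv[0],
                "aa_end": iv[1],
                "nt_match_len": 3 * aa_len,
                "e_value": e_value,
                "frameshift_flag": bool(rng.random() < config.frameshift_rate),
                "library": table,
            }
        )
        true_classes[ist_id] = 1 if source == "planted" else 2
        true_source[ist_id] = source

    enrich = config.enrichment_factor ** config.n_rounds
    for bait in baits:
        planted = planted_by_gene.get(bait.parent_gene, [])
        w_planted = (1.0 - config.background_fraction) * enrich if planted else 0.0
        w_bg = config.background_fraction if planted else 1.0
        if w_planted + w_bg == 0.0:
            continue
        p_planted = w_planted / (w_planted + w_bg)
        for _ in range(config.n_fragments_per_bait):
            if planted and rng.random() < p_planted:
                ir = planted[int(rng.integers(0, len(planted)))]
                iv = _place_planted(ir, ref_by_id[ir.prey_gene], dist,
                                    config.planted_mode, rng)
                emit("bait", bait.bait_id, ir.prey_gene, iv, "planted")
            else:
                gene, iv = _place_background(ref_by_id, dist, rng)
                emit("bait", bait.bait_id, gene, iv, "background")

    bait_rows = len(rows)
    for _ in range(config.n_mock_fragments):
        gene, iv = _place_background(ref_by_id, dist, rng)
        emit("mock", "MOCK", gene, iv, "background")

    df = pd.DataFrame(rows, columns=IST_COLUMNS) if rows else empty_ist_table()
    ists = df.iloc[:bait_rows].reset_index(drop=True)
    mock = df.iloc[bait_rows:].reset_index(drop=True)
    truth = SyntheticTruth(
        planted_irs=list(config.planted_irs),
        true_classes=true_classes,
        true_source=true_source,
    )
    return ists, mock, truth


# ---------------------------------------------------------------------------
# disorder, expression, toy structures


def simulate_disorder(
    reference: list[ReferenceProtein],
    params: DisorderParams,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-protein binary disorder tracks (1 = disordered).

    A two-state Markov chain over residues with stationary disordered
    fraction ``coverage`` and mean disordered run length ``mean_block_len``,
    started from stationarity, so the genome-wide disordered fraction matches
    the configured coverage in expectation.
    """
    c, m = params.coverage, params.mean_block_len
    rng = np.random.default_rng(seed)
    tracks: dict[str, np.ndarray] = {}
    if c == 0.0 or c == 1.0:
        for p in reference:
            tracks[p.gene_id] = np.full(p.aa_length, int(c), dtype=np.int8)
        return tracks
    p_dd = 1.0 - 1.0 / m                 # stay disordered
    p_od = c / ((1.0 - c) * m)           # ordered -> disordered
    if p_od > 1.0:
        raise ValueError("mean_block_len too short for requested coverage")
    for p in reference:
        track = np.empty(p.aa_length, dtype=np.int8)
        u = rng.random(p.aa_length)
        state = int(u[0] < c)
        track[0] = state
        for i in range(1, p.aa_length):
            stay = p_dd if state else 1.0 - p_od
            if u[i] >= stay and state or u[i] < p_od and not state:
                state = 1 - state
            track[i] = state
        tracks[p.gene_id] = track
    return tracks


def simulate_expression(
    genes: list[str],
    n_tissues: int,
    correlated_pairs: list[tuple[str, str]] | None = None,
    rho: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x tissue expression matrix with planted correlated pairs.

    All profiles are standard normal across tissues; for each planted pair
    (a, b) the b profile is rho * a + sqrt(1 - rho^2) * noise, giving expected
    profile correlation rho.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((len(genes), n_tissues))
    idx = {g: i for i, g in enumerate(genes)}
    for a, b in correlated_pairs or []:
        X[idx[b]] = rho * X[idx[a]] + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n_tissues)
    return pd.DataFrame(X, index=genes, columns=[f"tissue_{t}" for t in range(n_tissues)])


def tissue_specific_sets(expression: pd.DataFrame, z_threshold: float = 2.0) -> dict[str, set[str]]:
    """Tissue-specific gene sets.

    A gene belongs to the set of its peak-expression tissue when that peak is
    at least ``z_threshold`` SDs above the mean of the remaining tissues
    (strictly greater when the remaining tissues are constant). A gene
    expressed in exactly one tissue is therefore specific to exactly that
    tissue, and a flat gene to none.
    """
    X = expression.to_numpy(dtype=float)
    sets: dict[str, set[str]] = {t: set() for t in expression.columns}
    for gi, gene in enumerate(expression.index):
        t = int(X[gi].argmax())
        others = np.delete(X[gi], t)
        mu, sd = others.mean(), others.std(ddof=0)
        peak = X[gi, t]
        if (sd > 0 and peak >= mu + z_threshold * sd) or (sd == 0 and peak > mu):
            sets[expression.columns[t]].add(gene)
    return sets


def plant_domains(
    reference: list[ReferenceProtein],
    planted_irs: list[PlantedIR],
    domain_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Pfam-style domain table: a fraction of planted IRs coincide with a
    named domain; remaining domains are placed uniformly at random."""
    rng = np.random.default_rng(seed)
    ref_by_id = {p.gene_id: p for p in reference}
    rows = []
    for i, ir in enumerate(planted_irs):
        if rng.random() < domain_fraction:
            rows.append({"gene_id": ir.prey_gene, "domain_name": f"DOM_IR{i}",
                         "aa_start": ir.start, "aa_end": ir.end})
    for j in range(len(planted_irs)):
        p = ref_by_id[sorted(ref_by_id)[int(rng.integers(0, len(ref_by_id)))]]
        dlen = min(p.aa_length, int(rng.integers(20, 120)))
        start = int(rng.integers(1, p.aa_length - dlen + 2))
        rows.append({"gene_id": p.gene_id, "domain_name": f"DOM_RND{j}",
                     "aa_start": start, "aa_end": start + dlen - 1})
    return pd.DataFrame(rows, columns=["gene_id", "domain_name", "aa_start", "aa_end"])


def toy_two_chain_structure(
    positions_a: dict[int, np.ndarray],
    positions_b: dict[int, np.ndarray],
    chain_a: str = "A",
    chain_b: str = "B",
):
    """Build a Bio.PDB structure with one CA atom per residue at the given
    coordinates. An analytic fixture for contact-map code (synthetic, not a
    real complex)."""
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("synthetic")
    sb.init_model(0)
    for chain_id, positions in ((chain_a, positions_a), (chain_b, positions_b)):
        sb.init_chain(chain_id)
        sb.init_seg("    ")
        for resnum in sorted(positions):
            sb.init_residue("GLY", " ", int(resnum), " ")
            coord = np.asarray(positions[resnum], dtype=float)
            sb.init_atom("CA", coord, 0.0, 1.0, " ", " CA ", element="C")
    return sb.get_structure()


def toy_complex(
    n_res_a: int,
    n_res_b: int,
    interface_b: Interval,
    contact_distance: float = 3.8,
    far_distance: float = 40.0,
    spacing: float = 6.0,
):
    """Synthetic two-chain complex: chain B residues inside ``interface_b``
    sit ``contact_distance`` from chain A, all others ``far_distance`` away."""
    pos_a = {i: np.array([i * spacing, 0.0, 0.0]) for i in range(1, n_res_a + 1)}
    pos_b = {}
    for j in range(1, n_res_b + 1):
        d = contact_distance if interface_b[0] <= j <= interface_b[1] else far_distance
        x = min(j, n_res_a) * spacing
        pos_b[j] = np.array([x, d, 0.0])
    return toy_two_chain_structure(pos_a, pos_b)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_irs"] = [dataclasses.asdict(ir) for ir in config.planted_irs]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["planted_irs"] = [PlantedIR(**ir) for ir in d.get("planted_irs", [])]
    if "disorder" in d and isinstance(d["disorder"], dict):
        d["disorder"] = DisorderParams(**d["disorder"])
    return SimulationConfig(**d)
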