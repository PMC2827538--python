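# Methods

## The screen being modelled

An IVV/mRNA-display interaction screen couples each translated prey protein
to its encoding mRNA, so affinity selection against an immobilized bait
followed by RT-PCR and sequencing yields *interaction sequence tags* (ISTs):
fragments of prey proteins, biased toward the bait-binding interface
because the prey library is randomly primed and selection enriches binders.
A baitless mock selection run in parallel captures the technical
false-positive background (matrix binders, PCR artifacts). The computation
downstream of sequencing is what this package implements.

## Evidence model

**Filters.** An alignment is a positive match when E ≤ 10⁻⁵ and the match
spans ≥ 30 nt; frameshifted reads are excluded. Both thresholds are
inclusive. Nucleotide CDS intervals [s, e] convert to amino-acid intervals
[⌈s/3⌉, ⌊e/3⌋] — only fully covered codons count, and a record whose
interval comes out empty is dropped with a logged count. Multiple hits per
query resolve to the lowest E-value, ties to the longest match, then the
lexicographically smallest subject id.

**Classes.** Overlap always means ≥ 1 shared residue on the same prey gene.
Mock exclusion is applied first: an IST overlapping any mock fragment is
class 3 regardless of other evidence, and class-3 fragments do not serve as
class-1 partners. Among the survivors, an IST is class 1 when some other
IST from the same bait *parent gene* (full-length and domain constructs of
one protein are pooled) overlaps it on the same prey; otherwise class 2.
The classification is symmetric and idempotent, and adding mock evidence
can only move ISTs toward class 3 (a property test asserts this
monotonicity). The *core* set is classes 1 ∪ 2.

**Clusters and IRs.** Within a (prey gene, bait parent gene) group, a
cluster is a maximal set of ISTs whose common intersection — the *minimum
region*, the innermost interval under nesting — spans at least
`min_region_len_aa` residues (default 3 aa). Maximal sets are found by
sweeping right-shrunk intervals ([s, e − w + 1] share a point exactly when
the originals share w residues); a test proves the sweep equivalent to
exhaustive subset enumeration. When several maximal sets compete for an
IST, it is assigned to the one with the longest common intersection, ties
broken by leftmost then smallest minimum region, then member order — so
every core IST belongs to exactly one cluster. A transitive overlap chain
without a common region deliberately splits: a cluster must genuinely share
residues. Lone ISTs (and ISTs whose overlaps are shorter than the minimum)
form singleton clusters. Each cluster's lateral span (*maximum region*) is
emitted as one interacting region; an IR's class is the best class among
its members.

**Networks.** One PPI per distinct (bait gene, prey gene) pair with core
evidence. On each prey, IRs merge into an IR node when the shorter shares
≥ 50% of its residues with the other (connected components of that
relation); the alternative reading — sharing ≥ 50% of bait *targets* — is
available behind `MergeParams(criterion="targets")` for sensitivity
analysis. The IR-level graph gives every IR node exactly one intra-protein
edge (host linkage) and one inter-protein edge per supporting bait, so
#intra edges ≡ #IR nodes by construction; the run report asserts it anyway.
Multiplicity: a node with ≥ 2 distinct bait partners is a multiple-partner
interface. The literature-curated union treats edges as undirected at the
parent-gene level and reports raw counts plus both defensible "percent more
nodes than LC" readings rather than asserting one. The degree summary fits
a least-squares slope to log-binned log–log degree counts — adequate for an
"approximately power-law" statement; maximum-likelihood exponents are out
of scope.

**Structure agreement.** Contact residues are those possessing atoms within
4.0 Å (inclusive) of the other chain. The atom set defaults to main-chain
(N, CA, C, O) with an all-atom mode, because the usual verbal definition is
ambiguous between the two; both are exposed rather than silently resolved.
IST density is the per-residue count of covering fragments (display scale
capped at a top ">5" bin). "Agreement" between dense regions and contacts
is quantified — as this package's own operationalization — by
precision/recall of residues with coverage ≥ a threshold against the
contact set, plus an exact hypergeometric enrichment p. Structure residue
numbering follows the coordinate file; an `offset` maps it onto reference
coordinates.

**Disorder and partner statistics.** Disorder tracks are parsed from
DISOPRED2-style text (the predictor's default 5% false-positive-rate call
decides the mark). Dataset proportions are residue-pooled: disordered
residues over total residues across all regions. The null is n = 10,000
random regions re-drawn from the proteome with the IR set's empirical
length distribution (gene uniform among those long enough, start uniform).
Comparisons use Fisher's exact test on the pooled 2×2 table, two-sided by
summing all tables at most as probable as the observed one. Residue pooling
ignores within-region correlation and is therefore anti-conservative; a
per-region permutation p (`n_bootstrap`) is reported alongside as a clearly
labelled extension, and the analysis drivers quote it. Partner-count
contrasts use the two-sided Wilcoxon rank-sum test: exact enumeration when
both groups are ≤ 10 without ties, otherwise the normal approximation with
tie correction.

## The synthetic generator

The generator emulates the *final composition* of a selected library, not
the chemistry: per-bait fragment draws mix planted-interface fragments and
background fragments, with planted draws up-weighted by
`enrichment_factor ** n_rounds` (default 2⁶ — six selection rounds, the
standard protocol) relative to a `background_fraction` (default 0.3). Mock
fragments are pure background. Fragment nucleotide lengths are lognormal
(median 300 nt ≈ 100 aa) — a documented default for a quantity real
protocols rarely report, exposed in the config rather than asserted.
Reference protein lengths are lognormal with median e⁶ ≈ 403 aa, clipped at
50 aa. Each fragment carries a synthetic alignment record (E-value below
the threshold except for a `weak_alignment_rate` fraction, match length
3×aa length, Bernoulli frameshift flag) so the mapping filters are
exercised end to end. Defaults yield class proportions in the vicinity of a
real screen's (class 3 a few to ~15 percent); the mock library defaults to
50 fragments over 200 genes for that reason.

Planted fragments have two placement modes. **envelope** (default): start
uniform in [IR.start − L + 1, IR.end], guaranteeing ≥ 1 residue of overlap —
the staggered picture random priming produces, under which a planted
interface typically resolves into a few clusters that all cover it.
**straddle**: every fragment fully covers the planted interval with total
flanking ≤ the interval length, which guarantees recovery as exactly one
cluster whose minimum region has Jaccard ≥ 0.5 with truth (the minimum
region contains the interval and is at most twice its length). Recovery
acceptance checks use straddle; the envelope behaviour is reported
descriptively in the analysis drivers.

Disorder tracks are a two-state Markov chain per residue, started from
stationarity, with stationary disordered fraction = `coverage` (default
0.35, a typical eukaryotic proteome-scale figure) and mean disordered run
length `mean_block_len` (default 30 aa, domain-linker scale). Because
disorder comes in runs, the SE of the realized fraction is inflated by
roughly √(2·mean_block_len) over the Bernoulli SE; recovery tests use that
adjusted SE. Expression matrices are standard normal across tissues with
planted pairs at correlation ρ; tissue-specific sets take a gene's peak
tissue when the peak is ≥ 2 SD above the mean of the remaining tissues.
Toy complexes place one CA atom per residue so contact geometry is exact
and analytic (including the 4.0 Å boundary case); they are synthetic
fixtures, labelled as such.

What the generator does *not* model — sequencing error, chimeric reads,
isoform ambiguity, real cDNA composition bias, genuine disorder/interface
association — bounds what passing tests show: they establish algorithmic
correctness and recovery under the stated generative model, not performance
on real libraries.

## Numerical and interface choices

- All coordinates are 1-based inclusive at interfaces; region strings parse
  both `38..63` and the dotted `124.176` dialect.
- Determinism: every stochastic routine takes a seed and uses an
  independent `numpy` generator; identical config + seed reproduces outputs
  byte for byte, and the pipeline writes a SHA-256 manifest (no timestamps).
- Degenerate inputs: empty IST tables flow through to an all-zero report;
  zero-margin 2×2 tables return p = 1 with a flag; all-zero density
  profiles report undefined precision with a flag; constant expression
  profiles are skipped with a count; tissues with empty gene sets are
  omitted (their proportion is undefined).
- The cluster-assignment tie-break (longest intersection, then leftmost) is
  a choice the underlying definition leaves open; it is deterministic,
  documented, and the enumeration oracle in the tests encodes the same rule
  independently.

## Known limitations

Cluster assignment is unique: an IST bridging two disjoint cluster cores
supports only one of them, which can undercount shared evidence relative to
a duplicating convention. The power-law slope from binned least squares is
descriptive, not inferential. The residue-pooled Fisher test inherits
pseudo-replication from its standard formulation (see above). Contact
detection treats hetero-atoms and waters as absent and does not compute
solvent accessibility. mmCIF structures and isoform-aware coordinate
lifting are unsupported.
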