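# Methods

This note documents the models and procedures implemented in `hetavar`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Distances and alignment

Subfamily structure is defined on the **gap-excluded p-distance**: after a
global alignment of two sequences, the distance is the fraction of
mismatched columns among columns where both sequences carry an unambiguous
base (`A/C/G/T`). Columns containing a gap or an `N` are excluded from both
numerator and denominator; `N` is Sanger ambiguity and should not inflate
divergence, and the classification threshold is phrased as a raw percentage
of nucleotide changes, so no substitution-model correction is applied. Two
consequences are deliberate: the distance is symmetric and bounded in
[0, 1], but it need **not** satisfy the triangle inequality (different pairs
exclude different columns), and it is undefined (NaN) for pairs sharing no
comparable column.

Pairwise alignments are optimal affine-gap global alignments (Gotoh
three-state DP, numba-compiled). Default scoring is +1 match, −1 mismatch,
−4 gap open, −1 gap extend — a gap of length L costs `open + (L−1)·extend` —
chosen to favour the long co-linear blocks expected between copies that are
~90–99% identical; all parameters are configurable. `N` scores 0 against
everything. Traceback ties are broken deterministically: diagonal, then up
(gap in the second sequence), then left. The aligner is verified in the test
suite against exhaustive enumeration of alignment paths (short sequences)
and against an independent library implementation (longer random pairs).

Distance matrices are computed in **pairwise mode** by default (each entry
from a fresh alignment, matching the pairwise phrasing of the subfamily
definition); **MSA mode** (pairwise-deletion distances over shared columns
of a multiple alignment) exists for consensus/profile work and bootstrap
resampling. Whether a 10% threshold should be evaluated pairwise or on MSA
columns is genuinely open; pairwise is the default because the rule is
stated for sequence pairs.

The multiple aligner is a classic progressive scheme: average-linkage guide
tree on pairwise distances (rows pre-sorted by record id so input order
cannot change the result), profile-profile merges with the same affine DP,
column scores averaged over all row pairs. An externally computed MSA (e.g.
from MAFFT) can be imported from aligned FASTA instead. Per-column identity
profiles report the modal non-gap residue (ties broken alphabetically) and
its share of non-gap residues; the ungapped consensus keeps columns with at
least 50% non-gap coverage.

## Subfamily classification

A subfamily is a set of copies in which **every** pair is within the
threshold (default 0.10) — a diameter rule. Complete-linkage agglomerative
clustering, merging in ascending complete-linkage distance and stopping at
the threshold, provably emits exactly such clusters; single or average
linkage would not. Undefined distances are treated as above-threshold. Merge
ties are resolved on the lexicographically smallest pair of member ids, so
the partition depends only on the distances, not on input order; the
diameter property is re-asserted on every partition as a post-condition.
Labels are letters (A, B, C, ...) by descending member count.

Queries (transcripts, or genomic copies from another strain) are assigned to
the subfamily minimizing the complete-linkage (max-to-any-member) distance
among subfamilies where that distance is within the threshold, ties broken
by mean distance then label order. Queries fitting no subfamily are reported
as **unassigned** rather than forced to the nearest cluster — real libraries
contain isolated intermediate copies, and forcing them would silently
distort abundance tables. Abundance tables count records per subfamily
within each (strain × region × material × strand) stratum, with explicit
zero rows for subfamilies absent from a stratum and proportions summing to 1
within each non-empty stratum.

Raising the threshold can only merge clusters, never split them (verified as
a property test). An optional gap-inclusive distance mode supports
sensitivity analysis, since excluding gaps understates divergence between
indel-rich copies.

## Trees

Trees are neighbor-joining trees on the same distances (negative branch
estimates clamped to zero). NJ is exact on additive matrices — the property
the tests verify against randomly generated additive trees — and adequate
for the topological questions asked here (do subfamilies form clades; does a
distant ortholog fall outside the ingroup). Maximum-likelihood inference
adds machinery without changing those answers; the Newick export (bootstrap
supports as internal-node labels) feeds external ML tools when wanted.
Bootstrap support resamples MSA columns with replacement, rebuilds the
distance matrix and NJ tree per replicate, and reports the percentage of
replicates containing each internal bipartition of the full-data tree. The
default is 1000 replicates; the tests use 10–100 for speed, which is
sufficient for the near-certain splits they assert. An all-identical input
yields a degenerate tree, flagged rather than erroring.

## Antisense splice analysis

Intron detection aligns a transcript to a reference consensus with a
**four-state affine DP**: the usual three Gotoh states plus a "long
deletion" state whose opening penalty equals the cost an ordinary gap
accumulates by `min_intron_length` bases and whose per-base extension is
near zero. The switch point between indel polymorphism and splicing is
therefore exactly `min_intron_length`, default **40 nt** — small enough to
catch short introns, large enough that geometric-length indels (mean 2 nt)
essentially never reach it. Every reference-side deletion of at least that
length becomes an intron call (0-based half-open coordinates on the
consensus, transcript orientation). Because flanking mismatches make the
boundary placement ambiguous, both boundaries are slid jointly (length
preserved) by up to 5 nt toward canonical `GT..AG`; the smallest canonical
shift wins and the canonical status is recorded. Discovery of non-canonical
splice sites is out of scope.

Variant classification groups transcripts by their ordered junction sets,
equal up to ±3 nt per boundary (`position_tolerance`, sized to absorb
alignment jitter across diverged subfamily members); grouping is greedy
centroid merging in descending group size, and variants are named SV1, SV2,
... by descending frequency (ties by leftmost donor). "unspliced" is a
reserved label for transcripts without calls.

The pipeline calls introns against the **global genomic consensus** of the
region (all genomic copies), not per-subfamily consensi, because variant
classification needs one shared coordinate system; per-subfamily references
remain available through the API for targeted re-analysis.

Splice-site strength is scored by a position weight matrix: per-position
log2-odds of the base frequencies in the canonical calls' junction windows
(donor −3..+6, acceptor −14..+3 around the junction, pseudocount 0.5)
against the background composition of the consensus. This is a deliberate
replacement for neural-network splice-site predictors; scores are
comparable within a run, not across tools. Usage tables report, per strain,
the spliced fraction and each variant's share — with **both** denominators
(all antisense transcripts, and spliced transcripts only), since published
variant shares are ambiguous in this respect; the all-antisense denominator
is the primary one.

All sequences are stored and analyzed in a single orientation, which for the
splicing stage equals transcript orientation; antisense cDNA reads of real
data are reverse-complemented on ingest (`attach_metadata(...,
orient_antisense=True)`) and flagged.

## qPCR and controls

Relative copy number uses the ΔΔCt model: per strain, ΔCt = mean Ct(element)
− mean Ct(reference gene); the ratio of strain *s* to the baseline strain is
`E^(ΔCt_base − ΔCt_s)` with amplification efficiency fixed at `E = 2`
(exact doubling per cycle). Without standard-curve data an efficiency
calibration is not possible, so `E` is exposed as a parameter for
sensitivity analysis instead. The estimate is invariant under adding any
constant to all Ct values. The coverage ratio is simply (sequences
analyzed) / (estimated copy number). The polymerase-fidelity control aligns
re-sequenced clones of a known template to their reference and counts
substitutions per compared nucleotide; indels are tallied separately and
only folded in on request, since a Sanger-consensus error count normally
means substitutions.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with ground
truth. Genomic copies follow a **star topology**: a uniform-random root
sequence, per-subfamily consensi mutated from the root at rate
`inter_divergence/2`, members mutated from their consensus at rate
`intra_divergence/2`, so that expected member-member distances are
approximately `intra_divergence` within and `inter_divergence` between
subfamilies. A star rather than a coalescent is the right tool because the
quantity under study is a distance threshold, not a genealogy, and the star
gives direct control of expected distances. Substitutions are uniform over
the three alternative bases; indels are geometric-length (p = 0.5)
single-event insertions/deletions at a per-site rate (default 0.002),
producing the amplicon size polymorphism real gels show. "Intermediate"
records — mid-point recombinants of two consensi — emulate the isolated
between-subfamily copies real libraries contain.

Default study conditions: subfamily divergences 4% within / 30% between
(comfortably straddling the 10% threshold, as in the real libraries),
region length 500 nt (the published work does not state the amplicon
lengths; ~350–900 nt is the plausible range, and 500/600 nt for 3'UTR/gag
are configurable defaults), transcript error rate 0.001/nt emulating
RT-PCR/cloning noise (set to 0 for exact-recovery experiments). A
`recoverable` flag asserts `intra < threshold < inter` so that
parameter-recovery scenarios are well-posed by construction.

Transcripts are copies of randomly chosen genomic members of their assigned
subfamily. Variant mixtures are realized as **exact largest-remainder
counts** over the pool (then seeded shuffling), not multinomial draws,
because the recovery experiments assert exact percentages. Sense calls must
use the mixture `{unspliced: 1.0}` — the contract that sense transcripts
are never spliced is enforced at generation time and verified at analysis
time. Planted splice junctions carry canonical `GT..AG`; the junction
neighbourhood is conserved across all copies (no substitutions within ±8 nt
of a boundary, no indels within ±30 nt), emulating the observation that
real splice sites are conserved well beyond the dinucleotides while the
surrounding sequence diverges — and reflecting that an indel abutting a
junction is analytically indistinguishable from an alternative splice form.
Each member's consensus→member coordinate map is retained so that intron
excision from indel-bearing members is exact; this underwrites the
invariant that excising the truth introns from the parent reproduces each
clean transcript byte for byte.

What the generator does **not** emulate: telomeric array geometry, terminal
erosion and transposition dynamics; chimeric PCR artifacts; strand-specific
RT errors; non-canonical splice sites; small-RNA biology. Passing recovery
tests therefore demonstrate correctness of the analysis under the stated
statistical structure, not robustness to every artifact of real libraries.

## Numerical and determinism notes

Every stochastic step takes an explicit seed (NumPy `default_rng`); given
(inputs, config, seed) the pipeline is byte-deterministic, and the run
manifest records a SHA-256 hash of the configuration. Alignment DP ties,
clustering merge ties, consensus ties and variant-ranking ties all have
documented deterministic tie-breaks. Distances NaN out only when a pair
shares zero comparable columns; NJ refuses such matrices and instructs
re-alignment. Problem sizes in the test and acceptance runs (tens of
records, hundreds of nucleotides, ≤ 100 bootstrap replicates) are the
package's desk-scale defaults; all sizes scale up linearly in sequence
count squared for the distance stage.

## Known limitations

* Complete-linkage partitions are sensitive to single outlier members near
  the threshold; the diameter rule is exact but not robust.
* The progressive MSA has no iterative refinement; deeply diverged sets
  (> ~40%) may align poorly. Import of an external MSA is supported.
* PWM scores are not calibrated across runs or against other tools.
* Cross-region subfamily letters (gag vs 3'UTR) are harmonized only through
  user-supplied full-length reference sequences that co-cluster in both
  regions; there is no automatic cross-region matching.
* ΔΔCt with fixed efficiency 2 biases ratios when true amplification
  efficiencies differ between targets.
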