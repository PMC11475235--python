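# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `rnapscreen`. Everything quantitative stated here is
computed by the test suite or the examples; nothing is asserted that the
code does not reproduce.

## Pairwise alignment and percent identity

Every downstream quantity in the screen is a percent identity, so alignment
uses identity-oriented unit scoring rather than a substitution matrix:

* global (Needleman–Wunsch, linear gaps): match +1, mismatch 0, gap −1;
* local (Smith–Waterman, linear gaps): match +2, mismatch −1, gap −2.

Both are configurable (`AlignmentScoring`), but BLOSUM-style weighting would
change none of the threshold semantics while complicating the enumeration
oracle used in tests.

Identity denominators differ deliberately between the two modes:

* **global**: matches / all alignment columns, *including terminal gaps* —
  the conservative, Clustal-style percent-identity convention; a sequence
  padded with unrelated residues loses identity;
* **local**: matches / aligned columns only, with coverage of each sequence
  (aligned residues / length) reported separately, mirroring how
  identity-plus-coverage clustering tools report local similarity.

Traceback prefers diagonal, then up, then left. To make identity a
symmetric function despite tie-breaking, the dynamic programme always runs
on the pair in lexicographic order and swaps the result back; symmetry is
property-tested. The DP is row-vectorised in numpy (the linear-gap
left-neighbour recurrence collapses to a running maximum), and its scores
are tested against exhaustive enumeration of all alignments on short
strings and against Biopython's `PairwiseAligner` on longer ones.

Alphabets: proteins are the 20 residues plus X; other ambiguity codes are
rejected because identity on ambiguous residues is ill-defined. A string
consisting solely of A/C/G/T letters is classified as nucleotide; aligning
it against a protein raises an alphabet mismatch. (A real protein whose
entire sequence uses only those four letters would be misclassified — an
accepted edge for realistic sequence lengths.)

## Two-stage clustering and representatives

Stage 1 groups enzymes whose global identity strictly exceeds 85%, as
connected components of the thresholded identity graph. Single linkage is
the only linkage expressible as a pure graph threshold, which makes the
result order-independent; the strict inequality is unit-tested at the
boundary. Stage 2 merges stage-1 clusters whose representatives align
locally at identity ≥ 85% (inclusive) with both coverages ≥ 70%, iterated
to transitive closure; comparing representatives only costs O(k²) rather
than all cross pairs, and the result is by construction a coarsening of
stage 1 and idempotent.

The family representative minimises the sum of its identity-matrix row over
all *other* library members. Library-wide scope (rather than within-cluster)
is the default because the screen's goal is a maximally sequence-diverse
panel; a `scope="cluster"` switch restricts the sum. Ties break to the
lexicographically smallest accession.

Recovery behaviour: on synthetic libraries with 5% within-family and 40%
between-family divergence, expected pairwise identity within a family is
≈ 90.5% (see the closed form below) and between families ≈ 37%, so the 85%
threshold separates them with a wide margin; stage-1 clustering attains
adjusted Rand index 1.0 across 20 seeds in the acceptance suite.

## Conserved-string promoter discovery

The search interprets the classic phage regulatory-element screen: string
length L = 20, window W = 30, degeneracy d = 4, both strands. Details the
original tool leaves unspecified were fixed as follows and are exposed as
`MotifSearchParams`:

* **Window semantics.** Occurrences of a family must originate from
  distinct W-sized loci, encoded as pairwise start separation ≥ W (forward
  coordinates, either strand). This preserves the parameter's role — locus
  granularity — without reverse-engineering the original implementation.
* **Minimum recurrence m = 3.** The smallest count that distinguishes a
  conserved element from a simple repeat pair.
* **Greedy seeding in genome order.** Every L-mer is a potential seed;
  members of a reported family cannot seed later families (they may still
  join them). No randomness anywhere: output is a pure function of genome
  and parameters, which the determinism tests exploit.
* **Degeneracy enforcement.** Membership requires Hamming distance ≤ d
  from the seed and from the family's majority core. A consensus column is
  written as a degenerate IUPAC code only when the majority base falls
  below a 75% supermajority; families are pruned (farthest member first,
  ties to the latest position) until at most d columns are degenerate.
  The supermajority rule lets a family of four copies each carrying up to
  two scattered substitutions keep all its members — strict non-unanimity
  would count up to eight degenerate columns and reject genuine planted
  families — while chance triples of mutually ~4-mismatch strings, whose
  dissent fraction is ≥ 1/3 per divergent column, still exceed the limit
  and are discarded.
* **Consensus trimming.** Terminal columns with information content
  < 0.5 bits (uniform background) are stripped from the reported
  consensus, so reported promoter lengths may differ from L, as real
  predicted promoters do (11–27 nt in the tested library fixture). This
  trimming rule is a documented guess; interior columns are never removed.

The scan itself indexes all windows by d+1 exact chunks (pigeonhole: a
window within distance d shares at least one chunk with the seed), and the
greedy driver runs as a numba-compiled kernel with a pure-numpy/Python
fallback of identical semantics; a brute-force full Hamming scan serves as
the test oracle on small genomes.

## Intergenic filtering and verification

Promoters are regulatory elements, so an occurrence is discarded when it
lies wholly inside an ORF on its own strand unless it also sits within the
upstream margin (default 150 nt) 5′ of some same-strand ORF start; families
dropping below m occurrences are removed. Genomes without ORF annotations
skip the filter with a warning.

The published screen verified candidates with a trained ML classifier;
reimplementing that model is out of scope, and the verification stage here
is a deliberately transparent stand-in with the same interface semantics
(probability, 0.5 threshold). Probability is a logistic function of three
family features:

    z = −3.5 + 1.0·(count − m) + 1.0·(IC − 25)/10 + 2.5·upstream_fraction

where IC is the family's information content in bits against the genome's
0-order base composition and upstream_fraction is the share of occurrences
in the upstream margin of same-strand ORF starts (defined as 0 when the
genome has no annotations: absent evidence is not positive evidence). The
weights were chosen from the feature geometry of the synthetic suite:
a planted family (≥ 4 copies, IC ≈ 33–40 bits, all upstream) scores
z ≈ +0.8 to +2 (p ≥ 0.69), while the strongest chance families in random
or dinucleotide-shuffled sequence (3–4 copies, no upstream evidence) score
z ≤ −1 (p ≤ 0.27). The acceptance suite verifies the resulting operating
point: ≥ 95% planted-motif recovery (site-level overlap of the top accepted
family with ≥ 3 planted sites) and ≤ 5% acceptance on dinucleotide-shuffled
genomes, across 20 seeds each.

## Triage thresholds and partition

Per-enzyme attributes: DNA-binding-domain identity to the reference
(identity over the global-alignment columns whose reference residue index
falls in a configured 0-based half-open interval; insertion columns are
excluded, and a query aligning only gaps there is flagged
`domain_deleted` with identity 0), and overall identity — the maximum
global identity against the characterized-plus-validated set. The
reference's domain boundaries are a structural annotation the screen cannot
derive, so the interval is configuration, and all binding-domain numbers
are conditional on it. The packaged reference-free fixtures instead carry
manifest-supplied identity columns.

Classification precedence: characterized → validated_novel →
excluded_low_binding (binding < 30) → redundant_high_identity
(overall > 75) → promoter_unpredictable → candidate. Known enzymes are
classed before the filters because the published partition treats them
outside the exclusion sets; the binding filter precedes the redundancy
filter, matching the partition's nesting (the 75 redundant enzymes are
counted among the 225 survivors of the binding cut). Both cutoffs are
strict inequalities; values exactly at a cutoff stay in the pool.

Partition bookkeeping: candidate_total = candidates + validated;
additional_targets = candidate_total − validated. The packaged 351-row
manifest reproduces the published class counts (126 excluded — derived as
351 − 225 from the printed "remaining 225" — 75 redundant, 8 validated,
142 candidates); its per-row identity values are synthetic placeholders
consistent with those counts, as the per-enzyme values were published only
graphically.

## Diversity tree

Neighbor joining on d = 100 − identity. The tree's purpose is diversity
visualisation, not divergence-time estimation, so no −log identity
correction is applied. Standard Q-criterion agglomeration; negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling branch; pair-choice ties break lexicographically by each node's
smallest descendant label, making the tree invariant to input order. On
additive matrices NJ is exact: the acceptance suite checks 4–6-taxon
additive matrices to 1e-9, with dendropy's NJ as an independent
cross-check and Newick round-trips parsed by dendropy.

## Synthetic data: what it emulates and what it does not

Protein libraries: one ancestor per family mutated from a common root at
the between-family rate, members mutated from their ancestor at the
within-family rate; substitutions are i.i.d. per site to a uniformly chosen
different residue, and indels are off by default so identity levels have a
closed form — two sequences mutated at rate r from one ancestor match at a
site with probability (1−r)² + r²/19, tested within 3σ at length 1000.
Default test conditions (within 4–5%, between 40–45%, family sizes of a
few members, sequence length 120–300) mirror the clustering regime the
screen assumes: families well inside the 85% threshold, far from other
families. Sequence length 300 keeps the all-vs-all DP suite fast; the
identity statistics are length-independent beyond sampling noise.

Genomes: i.i.d. background at a given GC, equal-width slots each holding a
forward-strand ORF preceded by an intergenic gap, and motif copies planted
in the upstream margins of distinct ORFs with at most `max_mismatches`
substitutions each — the placement the intergenic filter assumes of real
phage promoters. The standard recovery condition (40 kb, 30 ORFs, 4 copies,
≤ 2 mismatches) matches a typical small phage genome.

Not emulated: realistic gene content or codon usage, overlapping or
reverse-strand genes, phylogenetically correlated divergence, promoter
architecture beyond a conserved string, or indel divergence (available
behind a flag-free generator extension only; planted identity would lose
its closed form). Passing the synthetic suites therefore demonstrates that
the algorithms meet their stated operating characteristics under the
screen's assumptions, not that those assumptions hold for any particular
real genome.

Null genomes for the false-positive control are produced by an exact
dinucleotide-preserving shuffle (random Eulerian walk on the de Bruijn
multigraph with first and last base fixed), so local composition biases
that inflate chance string recurrence are retained under the null.

## Determinism and numerics

All generators are pure functions of their integer seed (numpy
`default_rng`); the discovery, clustering, triage and tree stages contain
no randomness, so `run_screen` output is byte-reproducible, which
`emit_reports` supports by rendering all file content before writing and
excluding timestamps from provenance. Floating-point comparisons in
traceback use a 1e-9 tolerance; identity-matrix symmetry is validated to
1e-9; NJ tie-breaks never compare floats across different label pairs
without the deterministic lexicographic fallback.

## Known limitations

* The verifier is a calibrated heuristic, not a trained promoter model; its
  probabilities are comparable within a genome, not across tools.
* Binding-domain identity is conditional on a user-supplied domain
  interval; no structural alignment is attempted.
* The clustering counts of the original database snapshot (93 stage-1
  clusters, 44 families from 351 sequences) depend on that snapshot and on
  the exact identity definitions of the external tools used then; they are
  packaged as bookkeeping fixtures rather than recomputed.
* Alignment is O(nm) per pair without banding; all-vs-all on thousands of
  full-length polymerases would need the optional k-mer prefilter or an
  external clustering tool.
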