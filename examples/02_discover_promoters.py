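"""Find a planted promoter in a synthetic phage genome.

Plants four slightly corrupted copies of the T7 promoter upstream of
distinct ORFs in a 30 kb random genome, then runs the conserved-string
search (L=20, W=30, d=4), the intergenic filter, and the logistic verifier.
"""

from rnapscreen import promoter, synthetic

T7 = "TAATACGACTCACTATAGGG"
genome, truth = synthetic.generate_phage_genome_with_promoters(
    length=30000, gc=0.5, n_orfs=20, motif=T7, copies=4, max_mismatches=1,
    rng_seed=11,
)
candidates = promoter.discover_conserved_strings(genome)
candidates = promoter.filter_intergenic(candidates, genome)
candidates = promoter.verify_candidates(candidates, genome)
best = promoter.best_accepted(candidates)

print(f"planted motif : {truth.planted_motif}")
print(f"planted sites : {[p[1] for p in truth.planted_positions]}")
print(f"families found: {len(candidates)}")
print(f"best consensus: {best.consensus}  (p={best.probability:.3f})")
print(f"best sites    : {best.positions()}")
# The accepted family's consensus should equal (or sit within a couple of
# IUPAC-degenerate positions of) the planted motif, and its occurrence
# positions should coincide with the planted upstream sites.  The
# probability is the logistic verifier's confidence that the family is a
# genuine regulatory element rather than a chance repeat.
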