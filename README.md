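# rnapscreen

In-silico screening of single-subunit phage RNA polymerases (RNAPs) as
biocatalysts for in vitro transcription (IVT) mRNA manufacture.

All synthetic mRNA is currently produced with a handful of characterized
single-subunit phage RNAPs (T7 above all), yet hundreds of putative RNAPs
with potentially superior processivity or impurity profiles sit untested in
sequence databases. The practical bottlenecks are (i) redundancy — many
database entries are near-identical — and (ii) promoter stringency: each
enzyme initiates only from its own cognate promoter, where even a single
nucleotide change can abolish transcription, so an enzyme is only testable
if its promoter can be predicted. `rnapscreen` implements the in-silico half
of a screening platform that addresses both:

1. **Library clustering.** All-vs-all pairwise percent identity; enzymes
   sharing global identity > 85% are grouped (single linkage), and clusters
   are merged into families when their representatives align locally at
   identity ≥ 85% with bidirectional coverage ≥ 70%. Each family is
   represented by its most divergent member — the one minimizing
   Σ<sub>j≠i</sub> identity(i, j) over the library.
2. **Cognate promoter discovery.** A PHIRE-style degenerate conserved-string
   search over a phage genome: all L-mers (default L = 20) on both strands,
   families of strings within Hamming distance d = 4 of a seed recurring at
   ≥ 3 distinct loci (pairwise start separation ≥ W = 30), filtered to
   occurrences compatible with a regulatory role (not buried inside a
   same-strand gene), and verified by a transparent logistic scorer over
   (occurrence count, information content, upstream fraction) with the
   conventional 0.5 acceptance probability.
3. **Solution-space triage.** Each enzyme is classified by DNA-binding-domain
   identity to T7 (< 30% ⇒ promoter prediction, and hence activity, is
   unlikely), overall identity to characterized enzymes (> 75% ⇒ redundant
   phenotype), and promoter status. The partition arithmetic reproduces the
   published 351 → 225 → 150 enzyme bookkeeping with 142 additional targets.
4. **Diversity cladogram.** Neighbor joining on d = 100 − identity, to
   visualise that the selected panel spans sequence space.

A first-class synthetic-data module generates ground-truthed protein
libraries (controlled within/between-family divergence) and genomes with
planted, partially corrupted promoter motifs, so every stage is testable
without any sequence download.

## Worked example

Partition the packaged 351-enzyme theoretical solution space
(`examples/03_triage_solution_space.py`):

```
total enzymes               : 351
excluded (binding < 30%)    : 126
remaining after that filter : 225
redundant (overall > 75%)   : 75
validated in this screen    : 8
candidate total             : 150
additional future targets   : 142
```

126 enzymes fall below the 30% binding-domain identity cut (their promoters
are effectively unpredictable with current tools); of the 225 that remain,
75 are likely T7-redundant, leaving 150 enzymes predicted to be both active
and phenotypically novel — 8 already validated, 142 promising targets.

Recover a planted promoter from a synthetic 30 kb genome
(`examples/02_discover_promoters.py`):

```
planted motif : TAATACGACTCACTATAGGG
planted sites : [4561, 13594, 21130, 24070]
families found: 22
best consensus: TAATACGACTCACTATAGGG  (p=0.779)
best sites    : [4561, 13594, 21130, 24070]
```

The top accepted family is exactly the planted T7 promoter at exactly the
planted upstream positions; `p` is the verifier's acceptance probability.

The other examples cover clustering/representative selection, the NJ
diversity tree, and the full `run_screen` pipeline. A thin CLI mirrors the
stages (`rnapscreen simulate|cluster|represent|promoters|triage|tree|screen`).

## Layout

```
src/rnapscreen/
  seqio.py      FASTA/BED/TSV I/O, domain types, packaged fixtures
  align.py      global + local alignment, identity and coverage
  cluster.py    two-stage clustering, representative selection
  promoter.py   conserved-string discovery, intergenic filter, verifier
  triage.py     binding-domain identity, classification, partition
  phylo.py      neighbor joining, Newick output
  synthetic.py  ground-truthed library and genome generators
  pipeline.py   run_screen / emit_reports orchestration
  cli.py        thin command-line wrapper
```

See `docs/methods.md` for the model, parameter and calibration details.
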