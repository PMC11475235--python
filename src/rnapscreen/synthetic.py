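"""Ground-truthed synthetic inputs with the statistical structure the screen assumes.

Two generators: protein libraries with controlled within/between-family
divergence (i.i.d. substitution from family ancestors that themselves
diverged from a common root), and phage-like genomes with a promoter motif
planted, slightly corrupted, upstream of distinct ORFs.  Substitution-only
divergence is the default so planted identity levels have closed forms: two
sequences independently mutated at rate ``r`` from one ancestor match at a
site with probability ``(1-r)^2 + r^2/19``.

Every generator is a pure function of its seed: the same seed yields
byte-identical output.  What these data do *not* emulate: real phage gene
content, codon usage, phylogenetically correlated divergence, or promoter
architecture beyond a conserved string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import EnzymeRecord, GenomeRecord, write_bed, write_fasta

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass
class GroundTruth:
    """What was planted: family labels, motif copies, generation parameters."""

    family_label: dict[str, int] = field(default_factory=dict)
    planted_motif: Optional[str] = None
    planted_positions: list[tuple[str, int, str, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "family_label": self.family_label,
                "planted_motif": self.planted_motif,
                "planted_positions": self.planted_positions,
                "params": self.params,
            },
            indent=2,
            sort_keys=True,
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_protein(length: int, rng_seed) -> str:
    rng = _rng(rng_seed)
    return "".join(rng.choice(list(_AA), size=length))


def mutate_protein(seed_seq: str, sub_rate: float, rng_seed) -> str:
    """I.i.d. per-site substitution to a uniformly chosen *different* residue."""
    if not 0 <= sub_rate < 1:
        raise ValueError("substitution rate must lie in [0, 1)")
    rng = _rng(rng_seed)
    arr = list(seed_seq)
    hits = np.flatnonzero(rng.random(len(arr)) < sub_rate)
    for i in hits:
        alternatives = [a for a in _AA if a != arr[i]]
        arr[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(arr)


def expected_pairwise_identity(rate: float) -> float:
    """Closed-form expected % identity of two sequences mutated at ``rate``
    from a common ancestor (20-letter alphabet, uniform substitution)."""
    p = (1 - rate) ** 2 + rate**2 / 19
    return 100.0 * p


def generate_rnap_library(
    n_families: int,
    sizes: Sequence[int],
    within_div: float,
    between_div: float,
    rng_seed,
    seq_length: int = 300,
) -> tuple[list[EnzymeRecord], GroundTruth]:
    """A protein library of ``n_families`` families with known labels.

    One ancestor per family is mutated from a common root at ``between_div``;
    members are mutated from their family ancestor at ``within_div``.
    """
    if len(sizes) != n_families:
        raise ValueError(
            f"sizes has {len(sizes)} entries for {n_families} families"
        )
    if not within_div < between_div:
        raise ValueError("within-family divergence must be below between-family")
    rng = _rng(rng_seed)
    root = random_protein(seq_length, rng)
    records: list[EnzymeRecord] = []
    truth = GroundTruth(
        params={
            "n_families": n_families,
            "sizes": list(sizes),
            "within_div": within_div,
            "between_div": between_div,
            "seq_length": seq_length,
        }
    )
    counter = 0
    for fam, size in enumerate(sizes):
        ancestor = mutate_protein(root, between_div, rng)
        for _ in range(size):
            counter += 1
            acc = f"SYN{counter:04d}"
            seq = mutate_protein(ancestor, within_div, rng)
            records.append(EnzymeRecord(accession=acc, protein_seq=seq))
            truth.family_label[acc] = fam
    return records, truth


def random_genome(length: int, gc: float, rng_seed) -> str:
    rng = _rng(rng_seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_NT), size=length, p=p))


def generate_phage_genome_with_promoters(
    length: int,
    gc: float,
    n_orfs: int,
    motif: str,
    copies: int,
    max_mismatches: int,
    rng_seed,
    genome_id: str = "synthetic_phage",
    upstream_margin: int = 150,
    min_separation: int = 30,
) -> tuple[GenomeRecord, GroundTruth]:
    """A random-background genome with ORFs and planted promoter copies.

    The genome is split into ``n_orfs`` equal slots; each slot holds one
    forward-strand ORF preceded by an intergenic gap.  Motif copies (each
    carrying at most ``max_mismatches`` random substitutions) are planted in
    the upstream margin of the first ``copies`` ORFs, guaranteeing pairwise
    start separation of at least ``min_separation``.
    """
    if max_mismatches > len(motif):
        raise ValueError("max_mismatches cannot exceed motif length")
    if copies > n_orfs:
        raise ValueError(
            f"cannot plant {copies} copies upstream of {n_orfs} distinct ORFs"
        )
    slot = length // max(n_orfs, 1)
    gap = upstream_margin + len(motif) + 20
    if n_orfs and slot < gap + 60:
        raise ValueError(
            "infeasible packing: slots too small for upstream margin plus ORF"
        )
    rng = _rng(rng_seed)
    seq = list(random_genome(length, gc, rng))
    orfs = []
    for k in range(n_orfs):
        s = k * slot + gap
        e = min((k + 1) * slot - 10, length)
        orfs.append((s, e, "+"))
    truth = GroundTruth(
        planted_motif=motif,
        params={
            "length": length,
            "gc": gc,
            "n_orfs": n_orfs,
            "copies": copies,
            "max_mismatches": max_mismatches,
        },
    )
    chosen = sorted(rng.choice(n_orfs, size=copies, replace=False)) if copies else []
    for k in chosen:
        orf_start = orfs[k][0]
        offset = int(rng.integers(len(motif), upstream_margin - 5))
        pos = orf_start - offset
        copy = list(motif)
        n_mut = int(rng.integers(0, max_mismatches + 1))
        sites = rng.choice(len(motif), size=n_mut, replace=False)
        for s_i in sites:
            alternatives = [b for b in _NT if b != copy[s_i]]
            copy[s_i] = alternatives[rng.integers(3)]
        seq[pos : pos + len(motif)] = copy
        truth.planted_positions.append((genome_id, pos, "+", n_mut))
    genome = GenomeRecord(genome_id=genome_id, nt_seq="".join(seq), orfs=orfs)
    _check_separation(truth.planted_positions, min_separation)
    return genome, truth


def _check_separation(positions, min_separation: int) -> None:
    starts = sorted(p[1] for p in positions)
    for a, b in zip(starts, starts[1:]):
        if b - a < min_separation:
            raise ValueError("planted copies violate the separation window")


def dinucleotide_shuffle(seq: str, rng_seed) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Builds the multigraph of adjacent-base transitions and walks a uniformly
    chosen Eulerian path with the original first and last base fixed.  Used
    as the null model for promoter-discovery false-positive controls.
    """
    if len(seq) < 3:
        return seq
    rng = _rng(rng_seed)
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | {seq[-1]})
    sink = seq[-1]
    # choose random last-edges forming an in-tree to the sink
    while True:
        last_edge = {}
        for v in vertices:
            if v == sink or v not in edges:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != sink:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    walk_lists: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        walk_lists[v] = rest
    out = [seq[0]]
    pos = {v: 0 for v in walk_lists}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_lists[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def write_library_dataset(
    records: Sequence[EnzymeRecord], truth: GroundTruth, outdir
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.accession, r.protein_seq or "") for r in records], out / "library.fasta")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")


def write_genome_dataset(genome: GenomeRecord, truth: GroundTruth, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(genome.genome_id, genome.nt_seq)], out / "genome.fasta")
    write_bed(genome.orfs, genome.genome_id, out / "orfs.bed")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
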