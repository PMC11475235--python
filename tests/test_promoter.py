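"""Conserved-string discovery, intergenic filtering, and the logistic verifier."""

import warnings

import numpy as np
import pytest

from rnapscreen import promoter, synthetic
from rnapscreen.promoter import MotifSearchParams
from rnapscreen.seqio import GenomeRecord

T7_PROMOTER = "TAATACGACTCACTATAGGG"


def brute_force_families(seq, L, d, W, m, both_strands=True):
    """Exhaustive oracle: all seeds, full Hamming scan, same greedy thinning."""
    arr = promoter._encode_seq(seq)
    n = len(arr)
    wins = [arr[i : i + L] for i in range(n - L + 1)]
    entries = [(i, "+", wins[i]) for i in range(len(wins))]
    if both_strands:
        rc = (3 - arr)[::-1]
        rwins = [rc[j : j + L] for j in range(n - L + 1)]
        entries += [(n - L - j, "-", rwins[j]) for j in range(len(rwins))]
    entries.sort(key=lambda e: (e[0], e[1]))
    consumed = [False] * len(entries)
    families = []
    for si, (start, strand, w) in enumerate(entries):
        if consumed[si]:
            continue
        members = [
            mi
            for mi, (_, _, w2) in enumerate(entries)
            if int((w != w2).sum()) <= d
        ]
        members.sort(key=lambda mi: (entries[mi][0], entries[mi][1]))
        sel = []
        last = -(10**9)
        for mi in members:
            if entries[mi][0] >= last + W:
                sel.append(mi)
                last = entries[mi][0]
        if len(sel) >= m:
            families.append([(entries[mi][0], entries[mi][1]) for mi in sel])
            for mi in sel:
                consumed[mi] = True
    return families


def plant(seq, motif, positions, subs_per_copy=0, rng=None):
    s = list(seq)
    for k, p in enumerate(positions):
        copy = list(motif)
        if subs_per_copy and rng is not None:
            for site in rng.choice(len(motif), size=subs_per_copy, replace=False):
                copy[site] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[site]]
        s[p : p + len(motif)] = copy
    return "".join(s)


class TestDiscovery:
    def test_exact_planted_motif_recovered(self):
        background = synthetic.random_genome(10000, 0.5, 42)
        positions = [500, 2500, 5500, 8500]
        seq = plant(background, T7_PROMOTER, positions)
        genome = GenomeRecord(genome_id="g", nt_seq=seq)
        cands = promoter.discover_conserved_strings(genome)
        assert cands, "planted family not found"
        top = cands[0]
        assert top.occurrence_count == 4
        assert top.consensus == T7_PROMOTER
        assert top.degenerate_positions == 0
        assert sorted(o.position for o in top.occurrences if o.strand == "+") == positions

    def test_matches_brute_force_oracle_on_small_genome(self):
        rng = np.random.default_rng(9)
        seq = plant(synthetic.random_genome(1500, 0.5, 9), "ACGTACGTAC",
                    [100, 600, 1100], subs_per_copy=1, rng=rng)
        params = MotifSearchParams(string_len=10, window=30, degeneracy=2,
                                   min_occurrences=3)
        genome = GenomeRecord(genome_id="g", nt_seq=seq)
        got = promoter.discover_conserved_strings(genome, params)
        oracle = brute_force_families(seq, 10, 2, 30, 3)
        got_sites = [{(o.position, o.strand) for o in c.occurrences} for c in got]
        # every oracle family is discovered up to the degeneracy refinement,
        # which can only drop members, never invent them
        assert len(oracle) >= len(got_sites)
        for sites in got_sites:
            assert any(sites <= set(fam) for fam in oracle)

    def test_repeat_free_genome_yields_nothing(self):
        # oracle-verified absence: no 20-mer family of >=3 members at d<=4
        seq = synthetic.random_genome(3000, 0.5, 7)
        assert brute_force_families(seq, 20, 4, 30, 3) == []
        genome = GenomeRecord(genome_id="g", nt_seq=seq)
        assert promoter.discover_conserved_strings(genome) == []

    def test_mutated_copies_consensus_close_to_planted(self):
        rng = np.random.default_rng(5)
        background = synthetic.random_genome(12000, 0.5, 11)
        positions = [700, 3700, 6700, 9700]
        seq = plant(background, T7_PROMOTER, positions, subs_per_copy=2, rng=rng)
        genome = GenomeRecord(genome_id="g", nt_seq=seq)
        top = promoter.discover_conserved_strings(genome)[0]
        assert top.occurrence_count >= 3
        dist = sum(1 for x, y in zip(top.core, T7_PROMOTER) if x != y)
        assert dist <= 2

    def test_occurrences_are_verbatim_genome_substrings(self):
        seq = plant(synthetic.random_genome(8000, 0.45, 3), T7_PROMOTER,
                    [400, 2400, 4400, 6400])
        genome = GenomeRecord(genome_id="g", nt_seq=seq)
        rc = str.maketrans("ACGT", "TGCA")
        for cand in promoter.discover_conserved_strings(genome):
            for occ in cand.occurrences:
                window = seq[occ.position : occ.position + len(occ.observed)]
                if occ.strand == "+":
                    assert occ.observed == window
                else:
                    assert occ.observed == window.translate(rc)[::-1]
                assert occ.mismatches <= 4

    def test_deterministic_output(self):
        seq = plant(synthetic.random_genome(6000, 0.5, 21), T7_PROMOTER,
                    [300, 2300, 4300])
        genome = GenomeRecord(genome_id="g", nt_seq=seq)
        a = promoter.discover_conserved_strings(genome)
        b = promoter.discover_conserved_strings(genome)
        assert [(c.consensus, c.positions()) for c in a] == [
            (c.consensus, c.positions()) for c in b
        ]

    def test_genome_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            promoter.discover_conserved_strings(
                GenomeRecord(genome_id="g", nt_seq="ACGTACGT")
            )

    def test_param_validation(self):
        with pytest.raises(ValueError):
            MotifSearchParams(string_len=40, window=30)
        with pytest.raises(ValueError):
            MotifSearchParams(degeneracy=25)
        with pytest.raises(ValueError):
            MotifSearchParams(min_occurrences=1)


def _mini_candidate(positions, strands, observed):
    occs = [
        promoter.Occurrence(position=p, strand=s, observed=o, mismatches=0)
        for p, s, o in zip(positions, strands, observed)
    ]
    return promoter.PromoterCandidate(
        consensus=observed[0],
        occurrences=occs,
        degenerate_positions=0,
        occurrence_count=len(occs),
        core=observed[0],
    )


class TestIntergenicFilter:
    GENOME = GenomeRecord(
        genome_id="g",
        nt_seq=synthetic.random_genome(2000, 0.5, 1),
        orfs=[(300, 900, "+"), (1200, 1800, "-")],
    )

    def test_occurrence_inside_same_strand_orf_removed(self):
        cand = _mini_candidate([400, 500, 600], "+++", ["ACGTACGTAC"] * 3)
        assert promoter.filter_intergenic([cand], self.GENOME) == []

    def test_upstream_occurrences_kept(self):
        # all three sit in the 150 nt window 5' of the + ORF starting at 300
        cand = _mini_candidate([250, 270, 290], "+++", ["ACGTACGTAC"] * 3)
        kept = promoter.filter_intergenic([cand], self.GENOME)
        assert len(kept) == 1 and kept[0].occurrence_count == 3

    def test_opposite_strand_occurrence_survives(self):
        cand = _mini_candidate([400, 500, 600], "---", ["ACGTACGTAC"] * 3)
        kept = promoter.filter_intergenic([cand], self.GENOME)
        assert len(kept) == 1 and kept[0].occurrence_count == 3

    def test_family_dropping_below_minimum_removed(self):
        cand = _mini_candidate([250, 400, 500], "+++", ["ACGTACGTAC"] * 3)
        assert promoter.filter_intergenic([cand], self.GENOME) == []

    def test_no_orfs_warns_and_passes_through(self):
        bare = GenomeRecord(genome_id="g2", nt_seq="ACGT" * 200)
        cand = _mini_candidate([10, 50, 90], "+++", ["ACGTACGTAC"] * 3)
        with pytest.warns(UserWarning, match="no ORF"):
            assert promoter.filter_intergenic([cand], bare) == [cand]


class TestVerifier:
    def test_planted_family_accepted(self):
        genome, _ = synthetic.generate_phage_genome_with_promoters(
            40000, 0.5, 30, T7_PROMOTER, 5, 0, 77
        )
        cands = promoter.discover_conserved_strings(genome)
        cands = promoter.filter_intergenic(cands, genome)
        cands = promoter.verify_candidates(cands, genome)
        best = promoter.best_accepted(cands)
        assert best is not None
        assert best.probability > 0.5
        assert best.score_features[0] >= 5

    def test_shuffled_genome_best_family_rejected(self):
        genome, _ = synthetic.generate_phage_genome_with_promoters(
            40000, 0.5, 30, T7_PROMOTER, 4, 2, 13
        )
        shuffled = GenomeRecord(
            genome_id="shuf",
            nt_seq=synthetic.dinucleotide_shuffle(genome.nt_seq, 13),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cands = promoter.discover_conserved_strings(shuffled)
            cands = promoter.filter_intergenic(cands, shuffled)
            cands = promoter.verify_candidates(cands, shuffled)
        assert promoter.best_accepted(cands) is None

    def test_empty_input_gives_empty_output(self):
        genome = GenomeRecord(genome_id="g", nt_seq="ACGT" * 100)
        assert promoter.verify_candidates([], genome) == []
        assert promoter.best_accepted([]) is None

    def test_acceptance_matches_threshold_rule(self):
        genome, _ = synthetic.generate_phage_genome_with_promoters(
            30000, 0.5, 20, T7_PROMOTER, 4, 1, 3
        )
        cands = promoter.discover_conserved_strings(genome)
        cands = promoter.filter_intergenic(cands, genome)
        for c in promoter.verify_candidates(cands, genome, threshold=0.5):
            assert c.accepted == (c.probability >= 0.5)
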