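"""Conserved degenerate-string discovery in phage genomes.

Single-subunit RNAPs transcribe from short, highly conserved promoter
elements that recur upstream of phage genes.  This module finds them the way
PHIRE-style screens do: enumerate every L-mer of the genome (both strands),
greedily seed families of L-mers lying within Hamming distance ``d`` of the
seed whose start positions are pairwise at least a window ``W`` apart
(distinct loci), and keep families recurring at least ``m`` times.  Families
are filtered against ORF annotations (a promoter should not sit wholly
inside a gene on its own strand unless it is in the upstream margin of
another) and then scored by a transparent logistic verifier over occurrence
count, information content, and upstream placement — a deliberately simple,
fully documented stand-in for ML promoter classifiers, sharing their 0.5
acceptance-probability semantics.

The Hamming-ball scan uses an exact-chunk (pigeonhole) index and is compiled
with numba when available; a semantically identical numpy path backs it up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .seqio import GenomeRecord

_BASES = "ACGT"
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

#: A consensus column is written as a degenerate IUPAC code when the majority
#: base falls below this fraction of occurrences; stronger majorities absorb
#: sporadic mismatches (which are still counted per occurrence).
SUPERMAJORITY = 0.75


@dataclass(frozen=True)
class MotifSearchParams:
    """Knobs of the conserved-string search.

    ``string_len`` (L), ``window`` (W) and ``degeneracy`` (d) default to the
    published screen settings (20 / 30 / 4).  ``min_occurrences`` is the
    smallest recurrence count distinguishing a conserved element from a
    simple repeat pair; ``upstream_margin`` is how far 5' of an ORF start an
    occurrence still counts as upstream.
    """

    string_len: int = 20
    window: int = 30
    degeneracy: int = 4
    min_occurrences: int = 3
    upstream_margin: int = 150
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.string_len > self.window:
            raise ValueError("string length must not exceed window size")
        if self.degeneracy >= self.string_len:
            raise ValueError("degeneracy must be below string length")
        if self.min_occurrences < 2:
            raise ValueError("min_occurrences must be at least 2")


@dataclass(frozen=True)
class Occurrence:
    """One genomic instance of a family: forward-strand start, strand,
    the verbatim genome substring as read on that strand, and its mismatch
    count against the family's consensus core."""

    position: int
    strand: str
    observed: str
    mismatches: int


@dataclass
class PromoterCandidate:
    """A recurrent degenerate string family, possibly accepted as a promoter."""

    consensus: str
    occurrences: list[Occurrence]
    degenerate_positions: int
    occurrence_count: int
    score_features: Optional[tuple[float, float, float]] = None
    probability: Optional[float] = None
    accepted: bool = False
    core: str = ""  # majority-base consensus at full string length

    def positions(self) -> list[int]:
        return [o.position for o in self.occurrences]


@dataclass(frozen=True)
class VerifierWeights:
    """Logistic verifier coefficients (see docs for the calibration rationale).

    z = bias + w_count*(n_occ - min_occurrences) + w_ic*(IC - ic_center)/ic_scale
        + w_upstream*upstream_fraction
    """

    bias: float = -3.5
    w_count: float = 1.0
    w_ic: float = 1.0
    ic_center: float = 25.0
    ic_scale: float = 10.0
    w_upstream: float = 2.5


DEFAULT_WEIGHTS = VerifierWeights()

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i


def _encode_seq(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("genome contains characters outside A/C/G/T")
    return arr


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[int(x)] for x in arr)


# ---------------------------------------------------------------------------
# Hamming-ball scan and greedy family driver


def _scan_py(seed, wins, codes, sorted_codes, sorted_order, d, buf):
    """Hamming-ball members of one seed via the exact-chunk index.

    A window within distance d of the seed shares at least one exact chunk
    (pigeonhole over d+1 chunks); each hit is processed only in its first
    matching chunk, which dedups for free.  Writes member indices into
    ``buf`` and returns their count.
    """
    n_chunks = codes.shape[0]
    L = wins.shape[1]
    k = 0
    for c in range(n_chunks):
        code = codes[c, seed]
        lo = np.searchsorted(sorted_codes[c], code, side="left")
        hi = np.searchsorted(sorted_codes[c], code, side="right")
        for j in range(lo, hi):
            idx = sorted_order[c, j]
            dup = False
            for cc in range(c):
                if codes[cc, idx] == codes[cc, seed]:
                    dup = True
                    break
            if dup:
                continue
            mism = 0
            ok = True
            for t in range(L):
                if wins[idx, t] != wins[seed, t]:
                    mism += 1
                    if mism > d:
                        ok = False
                        break
            if ok:
                buf[k] = idx
                k += 1
    return k


def _drive_py(wins, codes, sorted_codes, sorted_order, starts, strands,
              seed_order, d, m, W):
    """Greedy seeding pass over all windows in genome order.

    For each unconsumed seed, gathers its Hamming ball, thins occurrences to
    pairwise start separation >= W (left to right), and records families of
    at least ``m`` members, whose members are then barred from seeding.
    Returns the selected window indices flattened plus family offsets.
    """
    N = wins.shape[0]
    consumed = np.zeros(N, dtype=np.uint8)
    buf = np.empty(N, dtype=np.int64)
    order_buf = np.empty(N, dtype=np.int64)
    flat = np.empty(N, dtype=np.int64)
    offs = np.empty(N + 1, dtype=np.int64)
    offs[0] = 0
    nfam = 0
    total = 0
    for si in range(seed_order.shape[0]):
        seed = seed_order[si]
        if consumed[seed] == 1:
            continue
        k = _scan(seed, wins, codes, sorted_codes, sorted_order, d, buf)
        if k < m:
            continue
        # insertion sort members by (start, strand); k is tiny
        for a in range(k):
            order_buf[a] = buf[a]
        for a in range(1, k):
            key = order_buf[a]
            kv = starts[key] * 2 + strands[key]
            b = a - 1
            while b >= 0 and starts[order_buf[b]] * 2 + strands[order_buf[b]] > kv:
                order_buf[b + 1] = order_buf[b]
                b -= 1
            order_buf[b + 1] = key
        nsel = 0
        last = -(1 << 40)
        for a in range(k):
            idx = order_buf[a]
            s = starts[idx]
            if s >= last + W:
                flat[total + nsel] = idx
                nsel += 1
                last = s
        if nsel < m:
            continue
        for a in range(nsel):
            consumed[flat[total + a]] = 1
        total += nsel
        nfam += 1
        offs[nfam] = total
    return flat[:total], offs[: nfam + 1]


_scan = _scan_py  # rebound to the jitted version on first use
_drive = None


def _engine():
    """Return the greedy driver, numba-compiled when numba is importable."""
    global _scan, _drive
    if _drive is not None:
        return _drive
    try:
        from numba import njit

        _scan = njit(cache=True, nogil=True)(_scan_py)
        _drive = njit(nogil=True)(_drive_py)
    except Exception:  # pragma: no cover - numba present in supported envs
        _scan = _scan_py
        _drive = _drive_py
    return _drive


def discover_conserved_strings(
    genome: GenomeRecord, params: MotifSearchParams = MotifSearchParams()
) -> list[PromoterCandidate]:
    """Greedy family discovery over all L-mers of the genome.

    L-mers are visited in genome order (forward strand before reverse at the
    same start).  Families reaching ``min_occurrences`` distinct loci are
    reported ranked by occurrence count then information content.  The
    algorithm is deterministic: no randomness, and no order dependence beyond
    the documented genome order.
    """
    L, W, d, m = (
        params.string_len,
        params.window,
        params.degeneracy,
        params.min_occurrences,
    )
    n = len(genome.nt_seq)
    if n < W:
        raise ValueError(f"genome {genome.genome_id} shorter than window ({n} < {W})")

    fwd = _encode_seq(genome.nt_seq)
    views = [np.lib.stride_tricks.sliding_window_view(fwd, L)]
    nf = n - L + 1
    starts = [np.arange(nf, dtype=np.int64)]
    strands = [np.zeros(nf, dtype=np.int64)]
    if params.both_strands:
        rc = (3 - fwd)[::-1].copy()
        views.append(np.lib.stride_tricks.sliding_window_view(rc, L))
        starts.append(n - L - np.arange(nf, dtype=np.int64))
        strands.append(np.ones(nf, dtype=np.int64))
    wins = np.ascontiguousarray(np.vstack(views))
    start_arr = np.concatenate(starts)
    strand_arr = np.concatenate(strands)
    N = wins.shape[0]

    # pigeonhole chunk index: within Hamming distance d, at least one of the
    # d+1 chunks matches exactly
    bounds = np.linspace(0, L, d + 2).astype(int)
    n_chunks = d + 1
    codes = np.empty((n_chunks, N), dtype=np.int64)
    sorted_codes = np.empty((n_chunks, N), dtype=np.int64)
    sorted_order = np.empty((n_chunks, N), dtype=np.int64)
    for c in range(n_chunks):
        sl = slice(bounds[c], bounds[c + 1])
        width = bounds[c + 1] - bounds[c]
        pw = (4 ** np.arange(width)).astype(np.int64)
        codes[c] = wins[:, sl].astype(np.int64) @ pw
        order = np.argsort(codes[c], kind="stable")
        sorted_order[c] = order
        sorted_codes[c] = codes[c][order]

    seed_order = np.lexsort((strand_arr, start_arr))
    drive = _engine()
    flat, offs = drive(
        wins, codes, sorted_codes, sorted_order, start_arr, strand_arr,
        seed_order, d, m, W,
    )

    candidates: list[PromoterCandidate] = []
    for f in range(len(offs) - 1):
        selected = [int(x) for x in flat[offs[f] : offs[f + 1]]]
        built = _build_candidate(wins, start_arr, strand_arr, selected, d, m)
        if built is not None:
            candidates.append(built)
    candidates.sort(
        key=lambda c: (
            -c.occurrence_count,
            -_information_content_profile(c),
            c.occurrences[0].position if c.occurrences else 0,
        )
    )
    return candidates


# ---------------------------------------------------------------------------
# Consensus building


def _majority(block: np.ndarray) -> np.ndarray:
    counts = np.stack([(block == b).sum(axis=0) for b in range(4)])
    return counts.argmax(axis=0).astype(np.uint8)  # ties -> A<C<G<T


def _degenerate_mask(block: np.ndarray) -> np.ndarray:
    """Columns whose majority base is below the supermajority fraction."""
    counts = np.stack([(block == b).sum(axis=0) for b in range(4)])
    return counts.max(axis=0) / block.shape[0] < SUPERMAJORITY


def _consensus_strings(block: np.ndarray) -> tuple[str, str, np.ndarray]:
    """(majority core, IUPAC consensus, degenerate-column mask)."""
    core = _majority(block)
    mask = _degenerate_mask(block)
    cols = []
    for j in range(block.shape[1]):
        if mask[j]:
            bases = frozenset(_BASES[int(b)] for b in np.unique(block[:, j]))
            cols.append(_IUPAC[bases])
        else:
            cols.append(_BASES[int(core[j])])
    return _decode(core), "".join(cols), mask


def _build_candidate(
    wins: np.ndarray,
    start_arr: np.ndarray,
    strand_arr: np.ndarray,
    selected: list[int],
    d: int,
    m: int,
) -> Optional[PromoterCandidate]:
    """Consensus building with degeneracy enforcement.

    Iteratively drops the member farthest from the majority core until every
    member is within ``d`` mismatches of the core and at most ``d`` columns
    are degenerate (sub-supermajority); gives up (returns None) if that would
    leave fewer than ``m`` members.
    """
    members = list(selected)
    while True:
        block = wins[members]
        core = _majority(block)
        mism = (block != core).sum(axis=1)
        deg = int(_degenerate_mask(block).sum())
        if mism.max() > d or deg > d:
            if len(members) <= m:
                return None
            # drop the farthest member; ties resolve to the latest position
            worst = max(
                range(len(members)),
                key=lambda k: (mism[k], start_arr[members[k]]),
            )
            members.pop(worst)
            continue
        break
    block = wins[members]
    occurrences = []
    for k, idx in enumerate(members):
        occurrences.append(
            Occurrence(
                position=int(start_arr[idx]),
                strand="+" if strand_arr[idx] == 0 else "-",
                observed=_decode(wins[idx]),
                mismatches=int(mism[k]),
            )
        )
    occurrences.sort(key=lambda o: (o.position, o.strand))
    core_str, consensus_full, _ = _consensus_strings(block)
    consensus = _trim_consensus(consensus_full, block)
    return PromoterCandidate(
        consensus=consensus,
        occurrences=occurrences,
        degenerate_positions=sum(1 for ch in consensus if ch not in _BASES),
        occurrence_count=len(occurrences),
        core=core_str,
    )


def _column_ic(block: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-column information content in bits against background q."""
    n = block.shape[0]
    ic = np.zeros(block.shape[1])
    for b in range(4):
        p = (block == b).sum(axis=0) / n
        nz = p > 0
        ic[nz] += p[nz] * np.log2(p[nz] / q[b])
    return ic


def _trim_consensus(consensus: str, block: np.ndarray) -> str:
    """Strip terminal columns carrying < 0.5 bits against a uniform background.

    Mirrors the observation that reported promoters vary in length around the
    search string length; interior columns are never removed.
    """
    ic = _column_ic(block, np.full(4, 0.25))
    lo, hi = 0, len(consensus)
    while lo < hi and ic[lo] < 0.5:
        lo += 1
    while hi > lo and ic[hi - 1] < 0.5:
        hi -= 1
    return consensus[lo:hi]


def _information_content_profile(cand: PromoterCandidate) -> float:
    block = np.stack([_encode_seq(o.observed) for o in cand.occurrences])
    return float(_column_ic(block, np.full(4, 0.25)).sum())


# ---------------------------------------------------------------------------
# Intergenic filtering


def _is_upstream(pos: int, length: int, strand: str, orfs, margin: int) -> bool:
    end = pos + length
    for s, e, ostrand in orfs:
        if ostrand != strand:
            continue
        if strand == "+" and s - margin <= pos and end <= s:
            return True
        if strand == "-" and e <= pos and end <= e + margin:
            return True
    return False


def _inside_orf(pos: int, length: int, strand: str, orfs) -> bool:
    end = pos + length
    return any(s <= pos and end <= e and ostrand == strand for s, e, ostrand in orfs)


def filter_intergenic(
    candidates: Sequence[PromoterCandidate],
    genome: GenomeRecord,
    upstream_margin: int = 150,
    min_occurrences: int = 3,
) -> list[PromoterCandidate]:
    """Drop occurrences buried inside same-strand genes.

    An occurrence survives if it is not wholly inside an ORF on its own
    strand, or if it sits within the upstream margin 5' of some same-strand
    ORF start.  Families falling below ``min_occurrences`` are removed.
    Without ORF annotations this is a no-op (with a warning).
    """
    if not genome.orfs:
        warnings.warn(
            f"genome {genome.genome_id} has no ORF annotations; "
            "intergenic filter skipped",
            stacklevel=2,
        )
        return list(candidates)
    out: list[PromoterCandidate] = []
    for cand in candidates:
        kept = [
            o
            for o in cand.occurrences
            if (not _inside_orf(o.position, len(o.observed), o.strand, genome.orfs))
            or _is_upstream(
                o.position, len(o.observed), o.strand, genome.orfs, upstream_margin
            )
        ]
        if len(kept) < min_occurrences:
            continue
        if len(kept) == len(cand.occurrences):
            out.append(cand)
        else:
            out.append(_rebuild_from_occurrences(kept))
    return out


def _rebuild_from_occurrences(kept: list[Occurrence]) -> PromoterCandidate:
    block = np.stack([_encode_seq(o.observed) for o in kept])
    core = _majority(block)
    mism = (block != core).sum(axis=1)
    occurrences = [replace(o, mismatches=int(mm)) for o, mm in zip(kept, mism)]
    core_str, consensus_full, _ = _consensus_strings(block)
    consensus = _trim_consensus(consensus_full, block)
    return PromoterCandidate(
        consensus=consensus,
        occurrences=occurrences,
        degenerate_positions=sum(1 for ch in consensus if ch not in _BASES),
        occurrence_count=len(occurrences),
        core=core_str,
    )


# ---------------------------------------------------------------------------
# Verification


def _background(genome: GenomeRecord) -> np.ndarray:
    arr = _encode_seq(genome.nt_seq)
    q = np.array([(arr == b).mean() for b in range(4)])
    return np.maximum(q, 1e-6)


def verify_candidates(
    candidates: Sequence[PromoterCandidate],
    genome: GenomeRecord,
    threshold: float = 0.5,
    weights: VerifierWeights = DEFAULT_WEIGHTS,
    upstream_margin: int = 150,
    min_occurrences: int = 3,
) -> list[PromoterCandidate]:
    """Score families with the logistic verifier and mark acceptances.

    Features per family: occurrence count, consensus information content in
    bits against the genome's 0-order base composition, and the fraction of
    occurrences upstream of same-strand ORF starts (0 when the genome has no
    annotations: absent evidence is not positive evidence).  The returned
    list is sorted by probability, highest first; the genome's predicted
    promoter is the first accepted entry, if any.
    """
    if not candidates:
        return []
    q = _background(genome)
    out = []
    for cand in candidates:
        block = np.stack([_encode_seq(o.observed) for o in cand.occurrences])
        ic = float(_column_ic(block, q).sum())
        if genome.orfs:
            up = sum(
                _is_upstream(
                    o.position, len(o.observed), o.strand, genome.orfs, upstream_margin
                )
                for o in cand.occurrences
            )
            upfrac = up / len(cand.occurrences)
        else:
            upfrac = 0.0
        z = (
            weights.bias
            + weights.w_count * (cand.occurrence_count - min_occurrences)
            + weights.w_ic * (ic - weights.ic_center) / weights.ic_scale
            + weights.w_upstream * upfrac
        )
        prob = 1.0 / (1.0 + math.exp(-z))
        scored = replace(
            cand,
            score_features=(float(cand.occurrence_count), ic, float(upfrac)),
            probability=prob,
            accepted=prob >= threshold,
        )
        out.append(scored)
    out.sort(
        key=lambda c: (
            -(c.probability or 0.0),
            -c.occurrence_count,
            c.occurrences[0].position,
        )
    )
    return out


def best_accepted(candidates: Sequence[PromoterCandidate]) -> Optional[PromoterCandidate]:
    """Highest-probability accepted family, or None (promoter unpredictable)."""
    accepted = [c for c in candidates if c.accepted]
    if not accepted:
        return None
    return max(
        accepted,
        key=lambda c: (c.probability, c.occurrence_count, -c.occurrences[0].position),
    )
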