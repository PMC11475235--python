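"""Pairwise global and local alignment with percent identity and coverage.

This is the primitive underneath library clustering, solution-space triage
and the diversity cladogram: every downstream quantity is a percent identity,
so the scoring is identity-oriented unit scoring rather than a substitution
matrix (match/mismatch/gap only, linear gaps).  Global identity is computed
over *all* alignment columns including terminal gaps (the conservative,
Clustal-style percent-identity convention); local identity is computed over
the aligned columns only, with per-sequence coverage reported alongside.

Traceback tie-breaking is deterministic (diagonal, then up, then left) and is
applied to the pair in lexicographic order, so ``identity(a, b)`` and
``identity(b, a)`` agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGT")

GAP = "-"


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap scoring constants for the dynamic programme."""

    match: float
    mismatch: float
    gap: float


#: Default global scoring: identity-counting (match +1, mismatch 0, gap -1).
GLOBAL_SCORING = AlignmentScoring(match=1.0, mismatch=0.0, gap=-1.0)

#: Default local scoring: Smith-Waterman-style (+2 / -1 / -2).
LOCAL_SCORING = AlignmentScoring(match=2.0, mismatch=-1.0, gap=-2.0)


@dataclass
class AlignmentResult:
    """One pairwise alignment with identity and coverage percentages.

    ``identity_pct`` is 100 * matches / columns, where ``columns`` counts
    every column of the (global or local) alignment including gap columns.
    ``cov_a`` / ``cov_b`` are the percent of each input's residues that fall
    inside the aligned region (always 100 for global alignments).
    """

    aligned_a: str
    aligned_b: str
    matches: int
    columns: int
    identity_pct: float
    cov_a: float
    cov_b: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def _alphabet_of(seq: str) -> str:
    letters = set(seq)
    if letters <= DNA_ALPHABET:
        return "dna"
    if letters <= PROTEIN_ALPHABET:
        return "protein"
    bad = sorted(letters - PROTEIN_ALPHABET)
    raise ValueError(f"sequence contains unsupported characters: {bad}")


def _check_pair(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    kind_a, kind_b = _alphabet_of(a), _alphabet_of(b)
    # ACGT-only strings classify as DNA; a protein partner is a hard conflict.
    if kind_a != kind_b:
        raise ValueError(f"alphabet mismatch: {kind_a} vs {kind_b}")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _fill_global(a: np.ndarray, b: np.ndarray, sc: AlignmentScoring) -> np.ndarray:
    """Needleman-Wunsch score matrix, row-vectorised over the second sequence.

    With linear gaps the left-neighbour recurrence inside a row collapses to a
    running maximum: H[i,j] = gap*j + max_{k<=j} (C[k] - gap*k) where C merges
    the diagonal/up candidates and the row's first cell.
    """
    n, m = len(a), len(b)
    g = sc.gap
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    idx = np.arange(m + 1, dtype=np.float64)
    H[0] = g * idx
    sub = np.where(b[None, :] == a[:, None], sc.match, sc.mismatch)
    for i in range(1, n + 1):
        cand = np.empty(m + 1, dtype=np.float64)
        cand[0] = H[i - 1, 0] + g  # opening the row with a gap in b
        cand[1:] = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + g)
        H[i] = np.maximum.accumulate(cand - g * idx) + g * idx
    return H


def _traceback_global(
    a: str, b: str, H: np.ndarray, sc: AlignmentScoring
) -> tuple[str, str]:
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    tol = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) <= tol:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(H[i, j] - (H[i - 1, j] + sc.gap)) <= tol:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _count_matches(al_a: str, al_b: str) -> int:
    return sum(1 for x, y in zip(al_a, al_b) if x == y and x != GAP)


def global_identity(
    a: str, b: str, scoring: AlignmentScoring = GLOBAL_SCORING
) -> AlignmentResult:
    """Optimal global alignment and percent identity of two sequences.

    Identity is matches over all alignment columns, terminal gap columns
    included, so appending unrelated sequence to one input lowers identity.
    Coverage is 100 for both sequences by construction.
    """
    _check_pair(a, b)
    swapped = a > b
    x, y = (b, a) if swapped else (a, b)
    H = _fill_global(_encode(x), _encode(y), scoring)
    al_x, al_y = _traceback_global(x, y, H, scoring)
    if swapped:
        al_x, al_y = al_y, al_x
    matches = _count_matches(al_x, al_y)
    columns = len(al_x)
    return AlignmentResult(
        aligned_a=al_x,
        aligned_b=al_y,
        matches=matches,
        columns=columns,
        identity_pct=100.0 * matches / columns,
        cov_a=100.0,
        cov_b=100.0,
        score=float(H[-1, -1]),
    )


def _fill_local(a: np.ndarray, b: np.ndarray, sc: AlignmentScoring) -> np.ndarray:
    n, m = len(a), len(b)
    g = sc.gap
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    idx = np.arange(1, m + 1, dtype=np.float64)
    sub = np.where(b[None, :] == a[:, None], sc.match, sc.mismatch)
    for i in range(1, n + 1):
        cand = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + g)
        row = np.maximum.accumulate(cand - g * idx) + g * idx
        H[i, 1:] = np.maximum(row, 0.0)
    return H


def local_identity_coverage(
    a: str, b: str, scoring: AlignmentScoring = LOCAL_SCORING
) -> AlignmentResult:
    """Optimal local alignment with identity over aligned columns and coverage.

    When no positive-scoring alignment exists the result is the empty
    alignment with identity 0 and coverage 0 (not an error): totally
    dissimilar sequences simply share nothing alignable.
    """
    _check_pair(a, b)
    swapped = a > b
    x, y = (b, a) if swapped else (a, b)
    H = _fill_local(_encode(x), _encode(y), scoring)
    best = float(H.max())
    if best <= 0.0:
        return AlignmentResult("", "", 0, 0, 0.0, 0.0, 0.0, 0.0)
    # deterministic end cell: smallest row, then smallest column
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    out_x: list[str] = []
    out_y: list[str] = []
    tol = 1e-9
    i, j = int(i), int(j)
    while i > 0 and j > 0 and H[i, j] > tol:
        s = scoring.match if x[i - 1] == y[j - 1] else scoring.mismatch
        if abs(H[i, j] - (H[i - 1, j - 1] + s)) <= tol:
            out_x.append(x[i - 1])
            out_y.append(y[j - 1])
            i -= 1
            j -= 1
        elif abs(H[i, j] - (H[i - 1, j] + scoring.gap)) <= tol:
            out_x.append(x[i - 1])
            out_y.append(GAP)
            i -= 1
        else:
            out_x.append(GAP)
            out_y.append(y[j - 1])
            j -= 1
    al_x = "".join(reversed(out_x))
    al_y = "".join(reversed(out_y))
    if swapped:
        al_x, al_y = al_y, al_x
        len_a, len_b = len(y), len(x)
    else:
        len_a, len_b = len(x), len(y)
    matches = _count_matches(al_x, al_y)
    columns = len(al_x)
    res_a = sum(1 for c in al_x if c != GAP)
    res_b = sum(1 for c in al_y if c != GAP)
    return AlignmentResult(
        aligned_a=al_x,
        aligned_b=al_y,
        matches=matches,
        columns=columns,
        identity_pct=100.0 * matches / columns if columns else 0.0,
        cov_a=100.0 * res_a / len_a,
        cov_b=100.0 * res_b / len_b,
        score=best,
    )


def shared_kmer_count(a: str, b: str, k: int = 5) -> int:
    """Number of distinct k-mers present in both sequences.

    Optional prefilter for all-vs-all mode: pairs sharing no k-mers cannot
    reach high identity and may be skipped.  Off by default upstream;
    correctness-neutral when off.
    """
    if len(a) < k or len(b) < k:
        return 0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)
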