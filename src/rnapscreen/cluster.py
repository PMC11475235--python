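"""Two-stage clustering of an RNAP library and representative selection.

Stage 1 groups enzymes whose *global* percent identity strictly exceeds a
threshold (default 85%), as connected components of the identity graph —
single linkage, the unique linkage expressible as a pure graph threshold and
therefore order-independent.  Stage 2 coarsens the stage-1 partition by
merging clusters whose representatives align *locally* at >= 85% identity
with >= 70% bidirectional coverage, iterated to a fixed point.  Each final
family is represented by its most sequence-divergent member: the one with
the smallest total identity to all other library members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import align
from .seqio import EnzymeRecord


@dataclass
class IdentityMatrix:
    """Symmetric all-vs-all percent-identity matrix over an accession set."""

    ids: list[str]
    values: np.ndarray
    kind: Literal["global", "local"]

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate accessions in identity matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("identity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 100.0, atol=1e-9):
            raise ValueError("identity matrix diagonal must be 100")
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")

    def index(self, accession: str) -> int:
        try:
            return self.ids.index(accession)
        except ValueError:
            raise KeyError(f"accession {accession!r} not in matrix") from None

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


@dataclass
class ClusterSet:
    """A disjoint partition of the library with one representative per cluster."""

    clusters: list[frozenset[str]]
    representative: dict[int, str] = field(default_factory=dict)
    stage: int = 1

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c
        for k, rep in self.representative.items():
            if rep not in self.clusters[k]:
                raise ValueError(f"representative {rep!r} not in its cluster")

    @property
    def members(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def labels(self) -> dict[str, int]:
        return {acc: k for k, c in enumerate(self.clusters) for acc in c}

    def __len__(self) -> int:
        return len(self.clusters)


def build_identity_matrix(
    records: Sequence[EnzymeRecord],
    kind: Literal["global", "local"] = "global",
    kmer_prefilter: Optional[int] = None,
) -> IdentityMatrix:
    """All-vs-all percent identity over a record list, in input order.

    ``kmer_prefilter``, when set, skips pairs sharing fewer than that many
    5-mers (their identity is recorded as 0); off by default.
    """
    if not records:
        raise ValueError("empty library: need at least one record")
    ids = [r.accession for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate accessions in library")
    seqs = []
    for r in records:
        if not r.protein_seq:
            raise ValueError(f"record {r.accession} has no sequence")
        seqs.append(r.protein_seq)
    n = len(seqs)
    values = np.full((n, n), 100.0)
    fn = align.global_identity if kind == "global" else align.local_identity_coverage
    for i in range(n):
        for j in range(i + 1, n):
            if (
                kmer_prefilter is not None
                and align.shared_kmer_count(seqs[i], seqs[j]) < kmer_prefilter
            ):
                values[i, j] = values[j, i] = 0.0
                continue
            res = fn(seqs[i], seqs[j])
            values[i, j] = values[j, i] = res.identity_pct
    return IdentityMatrix(ids=ids, values=values, kind=kind)


def cluster_stage1(matrix: IdentityMatrix, threshold_pct: float = 85.0) -> ClusterSet:
    """Single-linkage clusters: components of the identity > threshold graph.

    The threshold is strict: a pair at exactly the threshold identity is not
    linked.
    """
    if matrix.kind != "global":
        raise ValueError("stage-1 clustering requires a global identity matrix")
    adj = matrix.values > threshold_pct
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [
        frozenset(matrix.ids[i] for i in np.flatnonzero(labels == k))
        for k in range(n_comp)
    ]
    # deterministic order: by smallest member index
    order = sorted(
        range(n_comp), key=lambda k: min(matrix.index(a) for a in clusters[k])
    )
    cs = ClusterSet(clusters=[clusters[k] for k in order], stage=1)
    _assign_representatives(cs, matrix)
    return cs


def cluster_stage2(
    stage1: ClusterSet,
    records: Sequence[EnzymeRecord],
    id_threshold_pct: float = 85.0,
    cov_threshold_pct: float = 70.0,
    matrix: Optional[IdentityMatrix] = None,
) -> ClusterSet:
    """Merge stage-1 clusters by local similarity of their representatives.

    Clusters merge when their representatives' local alignment reaches the
    identity threshold (inclusive) with both coverages at or above the
    coverage threshold; merging is transitively closed, so the result is a
    coarsening of the stage-1 partition and applying the operation again
    changes nothing.
    """
    seq_by_acc = {r.accession: r.protein_seq for r in records}
    reps = [stage1.representative[k] for k in range(len(stage1))]
    k = len(reps)
    linked = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(linked, True)
    for i in range(k):
        for j in range(i + 1, k):
            res = align.local_identity_coverage(seq_by_acc[reps[i]], seq_by_acc[reps[j]])
            if (
                res.identity_pct >= id_threshold_pct
                and res.cov_a >= cov_threshold_pct
                and res.cov_b >= cov_threshold_pct
            ):
                linked[i, j] = linked[j, i] = True
    n_comp, labels = connected_components(csr_matrix(linked), directed=False)
    merged: list[set[str]] = [set() for _ in range(n_comp)]
    for ci, lab in enumerate(labels):
        merged[lab] |= stage1.clusters[ci]
    clusters = [frozenset(c) for c in merged if c]
    order = sorted(
        range(len(clusters)),
        key=lambda kk: min(sorted(clusters[kk])),
    )
    cs = ClusterSet(clusters=[clusters[kk] for kk in order], stage=2)
    if matrix is not None:
        _assign_representatives(cs, matrix)
    return cs


def select_representative(
    cluster: frozenset[str] | set[str],
    matrix: IdentityMatrix,
    scope: Literal["library", "cluster"] = "library",
) -> str:
    """The cluster member most divergent from everything else.

    Divergence is measured by the total of the member's identity-matrix row
    over all *other* sequences — library-wide by default, which maximises
    panel diversity; ``scope='cluster'`` restricts the sum to co-members.
    Ties break to the lexicographically smallest accession.
    """
    if not cluster:
        raise ValueError("cannot pick a representative of an empty cluster")
    best: tuple[float, str] | None = None
    for acc in sorted(cluster):
        i = matrix.index(acc)
        if scope == "library":
            total = float(matrix.values[i].sum() - matrix.values[i, i])
        else:
            others = [matrix.index(b) for b in cluster if b != acc]
            total = float(matrix.values[i, others].sum()) if others else 0.0
        if best is None or total < best[0] - 1e-12:
            best = (total, acc)
    assert best is not None
    return best[1]


def _assign_representatives(cs: ClusterSet, matrix: IdentityMatrix) -> None:
    cs.representative = {
        k: select_representative(c, matrix) for k, c in enumerate(cs.clusters)
    }


def cluster_report(stage1: ClusterSet, stage2: ClusterSet) -> "pandas.DataFrame":
    """Flat per-accession table: stage-1 cluster, family, representative flag."""
    import pandas as pd

    s1 = stage1.labels()
    s2 = stage2.labels()
    reps = set(stage2.representative.values())
    rows = [
        {
            "accession": acc,
            "stage1_cluster": s1[acc],
            "family": s2[acc],
            "is_representative": acc in reps,
        }
        for acc in sorted(s1)
    ]
    return pd.DataFrame(rows)
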