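"""Solution-space triage: classify every putative RNAP and count the partition.

The screen's central observation is that promoter prediction — and hence
observed enzyme activity — tracks DNA-binding-domain identity to T7: enzymes
below ~30% domain identity were uniformly non-functional in cell-free tests,
while enzymes above ~75% *overall* identity to an already characterized
polymerase are unlikely to offer new bioproduction phenotypes.  Applying
those two cuts to the full theoretical solution space of putative
single-subunit phage RNAPs yields the partition into excluded, redundant and
candidate enzymes, and the count of promising additional targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import align
from .promoter import MotifSearchParams
from .seqio import EnzymeRecord, Manifest

CLASSES = (
    "characterized",
    "validated_novel",
    "excluded_low_binding",
    "redundant_high_identity",
    "promoter_unpredictable",
    "candidate",
)


@dataclass
class ScreenConfig:
    """Every numeric threshold of the screen, with the published defaults.

    ``reference_domain_interval`` is the DNA-binding/promoter-recognition
    region on the reference polymerase, as a 0-based half-open residue
    interval; it must be supplied by configuration because domain boundaries
    are a structural annotation, not something the screen derives.
    """

    stage1_identity_pct: float = 85.0
    stage2_identity_pct: float = 85.0
    stage2_coverage_pct: float = 70.0
    motif: MotifSearchParams = field(default_factory=MotifSearchParams)
    verify_threshold: float = 0.5
    binding_domain_cutoff_pct: float = 30.0
    redundancy_cutoff_pct: float = 75.0
    reference_id: str = "T7"
    reference_domain_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for name in (
            "stage1_identity_pct",
            "stage2_identity_pct",
            "stage2_coverage_pct",
            "binding_domain_cutoff_pct",
            "redundancy_cutoff_pct",
        ):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if not 0 <= self.verify_threshold <= 1:
            raise ValueError("verify_threshold must lie in [0, 1]")
        if self.reference_domain_interval is not None:
            a, b = self.reference_domain_interval
            if not 0 <= a < b:
                raise ValueError("reference_domain_interval must satisfy 0 <= start < end")


@dataclass
class TriageReport:
    """Per-enzyme classes plus the solution-space partition arithmetic."""

    classes: dict[str, str]
    counts: dict[str, int]
    total: int
    remaining_after_binding_filter: int
    candidate_total: int
    additional_targets: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.classes.items()), columns=["accession", "class"]
        )

    def summary(self) -> dict:
        return {
            "total": self.total,
            "counts": dict(self.counts),
            "remaining_after_binding_filter": self.remaining_after_binding_filter,
            "candidate_total": self.candidate_total,
            "additional_targets": self.additional_targets,
        }


def binding_domain_identity(
    query: EnzymeRecord,
    reference: EnzymeRecord,
    interval: tuple[int, int],
) -> tuple[float, bool]:
    """Percent identity of the query over the reference's domain interval.

    The two proteins are aligned globally; identity is counted over the
    alignment columns whose *reference* residue index falls inside the
    0-based half-open interval (insertion columns carry no reference index
    and are excluded).  Returns ``(identity_pct, domain_deleted)`` where the
    flag marks a query that aligns only gaps across the whole interval.
    """
    if query.protein_seq is None or reference.protein_seq is None:
        raise ValueError("both records need sequences for domain identity")
    lo, hi = interval
    if not (0 <= lo < hi <= len(reference.protein_seq)):
        raise ValueError(
            f"interval ({lo},{hi}) invalid on reference of length "
            f"{len(reference.protein_seq)}"
        )
    res = align.global_identity(query.protein_seq, reference.protein_seq)
    ref_idx = -1
    columns = 0
    matches = 0
    query_residues = 0
    for qa, ra in zip(res.aligned_a, res.aligned_b):
        if ra != align.GAP:
            ref_idx += 1
            if lo <= ref_idx < hi:
                columns += 1
                if qa == ra:
                    matches += 1
                if qa != align.GAP:
                    query_residues += 1
    if columns == 0 or query_residues == 0:
        return 0.0, True
    return 100.0 * matches / columns, False


def overall_identity_max(
    query: EnzymeRecord, reference_set: list[EnzymeRecord]
) -> float:
    """Maximum global identity of the query against a set of known enzymes."""
    best = 0.0
    for ref in reference_set:
        if ref.accession == query.accession:
            continue
        best = max(best, align.global_identity(query.protein_seq, ref.protein_seq).identity_pct)
    return best


def classify_enzyme(row: dict, config: ScreenConfig) -> str:
    """Assign one of the six triage classes to an enzyme's attribute row.

    Precedence: known enzymes (characterized, then validated in this screen)
    are classed first; then the binding-domain exclusion, the redundancy
    filter, promoter unpredictability, and finally candidate status.
    """
    if row.get("characterized"):
        return "characterized"
    if row.get("validated"):
        return "validated_novel"
    binding = row.get("binding_domain_identity")
    overall = row.get("overall_identity_max")
    acc = row.get("accession", "<unknown>")
    if binding is None or pd.isna(binding):
        raise ValueError(f"enzyme {acc}: binding_domain_identity missing")
    if float(binding) < config.binding_domain_cutoff_pct:
        return "excluded_low_binding"
    if overall is None or pd.isna(overall):
        raise ValueError(f"enzyme {acc}: overall_identity_max missing")
    if float(overall) > config.redundancy_cutoff_pct:
        return "redundant_high_identity"
    if row.get("promoter_status", "predicted") != "predicted":
        return "promoter_unpredictable"
    return "candidate"


def partition_solution_space(
    manifest: Manifest, config: ScreenConfig = ScreenConfig()
) -> TriageReport:
    """Classify every manifest row and compute the partition bookkeeping.

    ``candidate_total`` counts enzymes predicted to be both active and
    non-redundant (candidates plus the enzymes this screen validated);
    ``additional_targets`` removes the already-validated ones from that
    count.
    """
    classes: dict[str, str] = {}
    for _, row in manifest.df.iterrows():
        rd = row.to_dict()
        rd["characterized"] = _truthy(rd.get("characterized"))
        rd["validated"] = _truthy(rd.get("validated"))
        classes[str(row["accession"])] = classify_enzyme(rd, config)
    counts = {c: 0 for c in CLASSES}
    for cls in classes.values():
        counts[cls] += 1
    total = len(classes)
    candidate_total = counts["candidate"] + counts["validated_novel"]
    return TriageReport(
        classes=classes,
        counts=counts,
        total=total,
        remaining_after_binding_filter=total - counts["excluded_low_binding"],
        candidate_total=candidate_total,
        additional_targets=candidate_total - counts["validated_novel"],
    )


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return False
    return bool(v)
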