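"""End-to-end orchestration of the in-silico RNAP screen.

``run_screen`` wires the stages together in the workflow's order: global
identity matrix -> stage-1 clustering -> stage-2 family merging ->
representative selection -> per-family promoter discovery, intergenic
filtering and verification -> triage -> diversity tree.  Everything is a
pure function of (inputs, config), so two runs on the same inputs emit
byte-identical reports.  Missing pieces (a family whose representative has
no genome, a triage that cannot run without a configured reference domain)
are carried as explicit flags, never dropped silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    ClusterSet,
    IdentityMatrix,
    build_identity_matrix,
    cluster_report,
    cluster_stage1,
    cluster_stage2,
)
from .phylo import Tree, nj_tree, write_newick
from .promoter import (
    PromoterCandidate,
    best_accepted,
    discover_conserved_strings,
    filter_intergenic,
    verify_candidates,
)
from .seqio import EnzymeRecord, GenomeRecord, Manifest, write_fasta
from .triage import (
    ScreenConfig,
    TriageReport,
    binding_domain_identity,
    partition_solution_space,
)


@dataclass
class ScreenResult:
    """Everything one screen run produced, plus provenance for reruns."""

    stage1: ClusterSet
    stage2: ClusterSet
    matrix: IdentityMatrix
    representatives: dict[int, str]
    promoters: dict[int, Optional[PromoterCandidate]]
    promoter_status: dict[int, str]  # family -> predicted | failed
    triage: Optional[TriageReport]
    tree: Tree
    attributes: Manifest
    provenance: dict = field(default_factory=dict)


def run_screen(
    records: Sequence[EnzymeRecord],
    genomes: Mapping[str, GenomeRecord],
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Run the full in-silico screen on a protein library and its genomes.

    ``genomes`` maps a representative's accession to its phage genome;
    families whose representative has no genome are flagged
    ``promoter_status='failed'`` and triage as promoter-unpredictable.
    Triage additionally needs a reference enzyme (``config.reference_id``
    present in the library) with a configured domain interval; without one
    the triage report is None and the gap is recorded in provenance.
    """
    matrix = build_identity_matrix(records, kind="global")
    stage1 = cluster_stage1(matrix, config.stage1_identity_pct)
    stage2 = cluster_stage2(
        stage1,
        records,
        id_threshold_pct=config.stage2_identity_pct,
        cov_threshold_pct=config.stage2_coverage_pct,
        matrix=matrix,
    )
    representatives = dict(stage2.representative)

    promoters: dict[int, Optional[PromoterCandidate]] = {}
    status: dict[int, str] = {}
    for fam, rep in representatives.items():
        genome = genomes.get(rep)
        if genome is None:
            promoters[fam] = None
            status[fam] = "failed"
            continue
        cands = discover_conserved_strings(genome, config.motif)
        cands = filter_intergenic(
            cands,
            genome,
            upstream_margin=config.motif.upstream_margin,
            min_occurrences=config.motif.min_occurrences,
        )
        cands = verify_candidates(
            cands,
            genome,
            threshold=config.verify_threshold,
            upstream_margin=config.motif.upstream_margin,
            min_occurrences=config.motif.min_occurrences,
        )
        best = best_accepted(cands)
        promoters[fam] = best
        status[fam] = "predicted" if best is not None else "failed"

    by_acc = {r.accession: r for r in records}
    reference = by_acc.get(config.reference_id)
    fam_of = stage2.labels()
    known = [r for r in records if r.characterized or r.validated]
    rows = []
    can_triage = reference is not None and config.reference_domain_interval is not None
    for r in records:
        row: dict = {
            "accession": r.accession,
            "characterized": r.characterized,
            "validated": r.validated,
            "promoter_status": status[fam_of[r.accession]],
        }
        if can_triage:
            ident, deleted = binding_domain_identity(
                r, reference, config.reference_domain_interval
            )
            row["binding_domain_identity"] = ident
            row["domain_deleted"] = deleted
            row["overall_identity_max"] = _overall_from_matrix(r, known, matrix)
        rows.append(row)
    attributes = Manifest(pd.DataFrame(rows))
    triage = partition_solution_space(attributes, config) if can_triage else None

    provenance = {
        "package_version": __version__,
        "config": _config_dict(config),
        "n_records": len(records),
        "n_genomes": len(genomes),
        "triage_skipped": None
        if can_triage
        else "reference enzyme or domain interval not configured",
    }
    return ScreenResult(
        stage1=stage1,
        stage2=stage2,
        matrix=matrix,
        representatives=representatives,
        promoters=promoters,
        promoter_status=status,
        triage=triage,
        tree=nj_tree(matrix),
        attributes=attributes,
        provenance=provenance,
    )


def _overall_from_matrix(
    record: EnzymeRecord, known: Sequence[EnzymeRecord], matrix: IdentityMatrix
) -> float:
    others = [k.accession for k in known if k.accession != record.accession]
    if not others:
        return 0.0
    i = matrix.index(record.accession)
    cols = [matrix.index(a) for a in others]
    return float(np.max(matrix.values[i, cols]))


def _config_dict(config: ScreenConfig) -> dict:
    d = {
        "stage1_identity_pct": config.stage1_identity_pct,
        "stage2_identity_pct": config.stage2_identity_pct,
        "stage2_coverage_pct": config.stage2_coverage_pct,
        "verify_threshold": config.verify_threshold,
        "binding_domain_cutoff_pct": config.binding_domain_cutoff_pct,
        "redundancy_cutoff_pct": config.redundancy_cutoff_pct,
        "reference_id": config.reference_id,
        "reference_domain_interval": list(config.reference_domain_interval)
        if config.reference_domain_interval
        else None,
        "motif": {
            "string_len": config.motif.string_len,
            "window": config.motif.window,
            "degeneracy": config.motif.degeneracy,
            "min_occurrences": config.motif.min_occurrences,
            "upstream_margin": config.motif.upstream_margin,
            "both_strands": config.motif.both_strands,
        },
    }
    return d


def load_config(path) -> ScreenConfig:
    """Build a ScreenConfig from a flat YAML mapping (keys = config fields;
    motif parameters nested under ``motif``)."""
    import yaml

    from .promoter import MotifSearchParams

    raw = yaml.safe_load(Path(path).read_text()) or {}
    motif_raw = raw.pop("motif", {})
    interval = raw.pop("reference_domain_interval", None)
    cfg = ScreenConfig(
        **raw,
        motif=MotifSearchParams(**motif_raw),
        reference_domain_interval=tuple(interval) if interval else None,
    )
    return cfg


def emit_reports(result: ScreenResult, outdir) -> list[Path]:
    """Write the run's TSV/FASTA/JSON/Newick reports under ``outdir``.

    All content is rendered before any file is opened, so an unwritable
    directory fails before a partial write.
    """
    out = Path(outdir)
    files: dict[str, str] = {}

    files["clusters.tsv"] = cluster_report(result.stage1, result.stage2).to_csv(
        sep="\t", index=False
    )

    prom_rows = []
    accepted_fastas = []
    for fam in sorted(result.representatives):
        rep = result.representatives[fam]
        cand = result.promoters.get(fam)
        prom_rows.append(
            {
                "family": fam,
                "representative": rep,
                "status": result.promoter_status[fam],
                "consensus": cand.consensus if cand else "",
                "n_occurrences": cand.occurrence_count if cand else 0,
                "probability": round(cand.probability, 6)
                if cand and cand.probability is not None
                else "",
                "best_position": cand.occurrences[0].position if cand else "",
                "strand": cand.occurrences[0].strand if cand else "",
            }
        )
        if cand is not None:
            accepted_fastas.append((f"family{fam}_{rep}", cand.consensus))
    files["promoters.tsv"] = pd.DataFrame(prom_rows).to_csv(sep="\t", index=False)
    files["promoters.fasta"] = (
        write_fasta(accepted_fastas) if accepted_fastas else ""
    )

    files["triage.tsv"] = (
        result.triage.to_frame().to_csv(sep="\t", index=False)
        if result.triage
        else "accession\tclass\n"
    )
    files["partition.json"] = (
        json.dumps(result.triage.summary(), indent=2, sort_keys=True) + "\n"
        if result.triage
        else json.dumps({"skipped": result.provenance.get("triage_skipped")}) + "\n"
    )
    files["tree.nwk"] = write_newick(result.tree) + "\n"
    files["run_manifest.json"] = (
        json.dumps(result.provenance, indent=2, sort_keys=True) + "\n"
    )

    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, content in files.items():
        p = out / name
        p.write_text(content)
        written.append(p)
    return written
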