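"""Input/output for the formats the screen touches, plus packaged fixtures.

Protein and genome sequences travel as FASTA (parsed with Biopython), ORF
annotations as 6-column BED (0-based half-open, strand in column 6), enzyme
manifests as TSV with a required ``accession`` column, and reports as
TSV/JSON.  Packaged fixtures transcribe the printed 26-enzyme test library
(with its predicted promoters and cell-free activity outcomes) and the
theoretical solution-space bookkeeping; per-row identity *values* in the
synthetic-labelled fixtures are constructed, only their class structure
follows the published counts.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import DNA_ALPHABET, PROTEIN_ALPHABET

PathOrText = Union[str, Path]

ORF = tuple[int, int, str]  # start, end (0-based half-open), strand '+'/'-'

#: Manifest columns holding percentages; validated to [0, 100] on load.
PERCENT_COLUMNS = ("binding_domain_identity", "overall_identity_max")


@dataclass
class EnzymeRecord:
    """One putative single-subunit phage RNA polymerase.

    ``characterized`` marks one of the six enzymes previously available for
    mRNA manufacture; ``validated`` marks an enzyme whose activity this screen
    confirmed in cell-free testing.  ``promoter_seq`` is the predicted cognate
    promoter, when prediction succeeded.
    """

    accession: str
    protein_seq: Optional[str] = None
    phage_name: str = ""
    characterized: bool = False
    validated: bool = False
    temp_optimum: Optional[str] = None
    promoter_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.protein_seq is not None:
            validate_protein(self.protein_seq, name=self.accession)
        if self.promoter_seq is not None:
            validate_dna(self.promoter_seq, name=f"{self.accession} promoter")


@dataclass
class GenomeRecord:
    """A phage genome with optional ORF annotations (BED convention)."""

    genome_id: str
    nt_seq: str
    orfs: list[ORF] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_dna(self.nt_seq, name=self.genome_id)
        n = len(self.nt_seq)
        for start, end, strand in self.orfs:
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"{self.genome_id}: ORF ({start},{end}) outside [0,{n})"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{self.genome_id}: bad strand {strand!r}")


@dataclass
class Manifest:
    """An enzyme table: one row per accession plus optional attribute columns.

    Wraps a DataFrame so downstream triage can consume either computed or
    manifest-supplied identity percentages.  Unknown columns are passed
    through untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "accession" not in self.df.columns:
            raise ValueError("manifest requires an 'accession' column")
        dup = self.df["accession"][self.df["accession"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate accessions in manifest: {sorted(set(dup))}")
        for col in PERCENT_COLUMNS:
            if col in self.df.columns:
                vals = pd.to_numeric(self.df[col], errors="coerce").dropna()
                bad = vals[(vals < 0) | (vals > 100)]
                if len(bad):
                    raise ValueError(
                        f"column {col!r} outside [0,100]: {bad.tolist()[:5]}"
                    )

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[EnzymeRecord]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                EnzymeRecord(
                    accession=str(row["accession"]),
                    protein_seq=_opt_str(row.get("protein_seq")),
                    phage_name=str(row.get("phage_name", "") or ""),
                    characterized=_as_bool(row.get("characterized", False)),
                    validated=_as_bool(row.get("validated", False)),
                    temp_optimum=_opt_str(row.get("temp_optimum")),
                    promoter_seq=_opt_str(row.get("promoter_seq")),
                )
            )
        return out


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v)
    return s if s and s.lower() != "nan" else None


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def validate_protein(seq: str, name: str = "sequence") -> str:
    """Uppercase amino-acid string over the 20 residues plus X.

    Other ambiguity codes (B, Z, J, U, O) are rejected: percent identity on
    ambiguous residues would be ill-defined.
    """
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    if seq != seq.upper():
        raise ValueError(f"{name}: protein sequence must be uppercase")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{name}: unsupported residues {sorted(bad)}")
    return seq


def validate_dna(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name}: empty nucleotide sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name}: characters outside A/C/G/T: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path_or_text: PathOrText) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercased sequence) pairs, order preserved.

    Accepts a path or raw FASTA text.  Rejects files with content before the
    first '>' header, empty inputs, and duplicate record ids.
    """
    text = _read_text(path_or_text)
    stripped = text.strip()
    if not stripped:
        raise ValueError("no records: FASTA input is empty")
    if not stripped.startswith(">"):
        raise ValueError("malformed FASTA: content before first '>' header")
    records = [
        (rec.id, str(rec.seq).upper().replace(" ", ""))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise ValueError("no records: FASTA input contains no sequences")
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise ValueError(f"duplicate FASTA id: {rid!r}")
        seen.add(rid)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: Optional[PathOrText] = None) -> str:
    """Serialize (id, sequence) pairs to FASTA text; also writes ``path`` if given."""
    seqs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in records]
    buf = io.StringIO()
    SeqIO.write(seqs, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _read_text(path_or_text: PathOrText) -> str:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    s = str(path_or_text)
    if s.lstrip().startswith(">") or "\n" in s:
        return s
    return Path(s).read_text()


# ---------------------------------------------------------------------------
# BED


def read_orf_annotations(path: PathOrText) -> list[ORF]:
    """Read 6-column BED (chrom, start, end, name, score, strand) as ORF intervals."""
    text = _bed_text(path)
    if not text.strip():
        return []
    df = pd.read_csv(io.StringIO(text), sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"BED requires 6 columns, got {df.shape[1]}")
    out: list[ORF] = []
    for _, row in df.iterrows():
        start, end, strand = int(row[1]), int(row[2]), str(row[5])
        if start >= end:
            raise ValueError(f"BED interval start >= end: ({start}, {end})")
        if strand not in ("+", "-"):
            raise ValueError(f"BED strand must be '+' or '-', got {strand!r}")
        out.append((start, end, strand))
    return out


def _bed_text(path_or_text: PathOrText) -> str:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    s = str(path_or_text)
    if "\t" in s or "\n" in s:
        return s
    return Path(s).read_text()


def write_bed(orfs: Sequence[ORF], genome_id: str, path: Optional[PathOrText] = None) -> str:
    lines = [
        f"{genome_id}\t{start}\t{end}\torf{i + 1}\t0\t{strand}"
        for i, (start, end, strand) in enumerate(orfs)
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Manifests


def load_manifest(path: PathOrText, fasta: Optional[PathOrText] = None) -> Manifest:
    """Load a TSV manifest, optionally joining protein sequences from FASTA.

    Accessions present in only one of the two inputs are reported as an
    error rather than silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    manifest = Manifest(df)
    if fasta is not None:
        seqs = dict(read_fasta(fasta))
        tsv_ids = set(df["accession"])
        only_fasta = sorted(set(seqs) - tsv_ids)
        only_tsv = sorted(tsv_ids - set(seqs))
        if only_fasta or only_tsv:
            raise ValueError(
                "manifest/FASTA accession mismatch: "
                f"FASTA-only={only_fasta[:5]}, TSV-only={only_tsv[:5]}"
            )
        df = df.copy()
        df["protein_seq"] = df["accession"].map(seqs)
        manifest = Manifest(df)
    return manifest


def write_manifest(manifest: Manifest, path: PathOrText) -> None:
    manifest.df.to_csv(path, sep="\t", index=False)


def temp_optimum_midpoint(text: Optional[str]) -> Optional[float]:
    """Midpoint of a textual temperature range ('25-30' -> 27.5), else None.

    Ranges are stored verbatim because the printed values mix single numbers,
    ranges, and 'Not found'.
    """
    if not text:
        return None
    parts = text.replace("–", "-").split("-")
    try:
        nums = [float(p) for p in parts]
    except ValueError:
        return None
    return sum(nums) / len(nums)


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str):
    return resources.files("rnapscreen.data").joinpath(name)


def load_tested_library() -> Manifest:
    """The 26-enzyme test library: promoters, temperature optima, activity.

    Activity flags record the cell-free screen outcome (8 of 26 active); the
    ``validated`` column mirrors them.
    """
    with resources.as_file(_data_path("tested_library.tsv")) as p:
        return load_manifest(p)


def load_domain_identity_fixture() -> Manifest:
    """Synthetic per-enzyme DNA-binding-domain identities for the 26 tested RNAPs.

    Values are constructed (the source figure is categorical): 10 enzymes
    above 30% identity to T7 of which the 8 actives, 16 below 30% all
    inactive.
    """
    with resources.as_file(
        _data_path("tested_domain_identity_synthetic.tsv")
    ) as p:
        return load_manifest(p)


def load_solution_space() -> Manifest:
    """Synthetic 351-enzyme manifest matching the published class counts.

    126 rows below the 30% binding-domain cutoff, 75 above it but over 75%
    overall identity to characterized enzymes, 8 validated actives, 142
    remaining candidates.  Identity values are deterministic placeholders.
    """
    with resources.as_file(_data_path("solution_space_synthetic.tsv")) as p:
        return load_manifest(p)


def load_characterized() -> pd.DataFrame:
    """The six previously characterized single-subunit RNAPs."""
    with resources.as_file(_data_path("characterized_rnaps.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_library_counts() -> dict:
    """Published library bookkeeping (snapshot-level counts, not recomputable)."""
    with resources.as_file(_data_path("library_counts.json")) as p:
        return json.loads(Path(p).read_text())
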