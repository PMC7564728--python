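"""Readers and writers for the external formats the pipeline touches.

All tabular inputs are TSV; lines starting with ``#`` are comments.  FASTA
handling follows common tooling: the first whitespace-delimited token of a
header is the identifier, the remainder (if any) is a free-text description.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: the residue alphabet records may carry: the 20 standard letters plus X
ALLOWED_AA = STANDARD_AA | {"X"}
#: ambiguity/rare letters accepted only under the permissive flag, mapped to X
AMBIGUOUS_AA = set("BZJUO")

logger = logging.getLogger("tlpkit")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclasses.dataclass(frozen=True)
class Config:
    """Run-wide configuration, loadable from a JSON file.

    Attributes
    ----------
    evalue_threshold : float
        Homology-hit cutoff; hits with e-value <= threshold are retained.
    adjacency_threshold_bp : int
        Maximum genomic distance between consecutive same-chromosome genes
        for them to be reported as candidate tandem duplicates.
    log2_pseudocount : float
        Pseudo-count added inside the log2 transform of FPKM values.
    seed : int
        Root seed for every stochastic operation.
    """

    evalue_threshold: float = 1e-10
    adjacency_threshold_bp: int = 1_000_000
    log2_pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

_LOCUS_SUFFIX = re.compile(r"\.\d+$")


def default_locus(protein_id: str) -> str:
    """Derive a locus identifier by stripping a trailing ``.<n>`` isoform
    suffix (``HORVU7Hr1G122120.1`` -> ``HORVU7Hr1G122120``)."""
    return _LOCUS_SUFFIX.sub("", protein_id)


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence anchored to a transcript and locus identity."""

    protein_id: str
    sequence: str
    locus_id: str = ""
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)}"
            )
        if not self.locus_id:
            object.__setattr__(self, "locus_id", default_locus(self.protein_id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class HitRecord:
    """One homology-search hit: query, subject and e-value."""

    query_id: str
    subject_id: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )


@dataclasses.dataclass(frozen=True)
class AnnotationRecord:
    """External per-protein annotations (localization, signal peptide,
    transmembrane-helix count) consumed as input, never predicted here."""

    protein_id: str
    localization_label: str = "unknown"
    signal_peptide: str = "unknown"
    tm_count: int = 0

    def __post_init__(self) -> None:
        if self.tm_count < 0:
            raise ValueError(f"{self.protein_id}: negative tm_count")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    species_tag: str = "",
    permissive: bool = False,
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are upper-cased and a single trailing ``*`` stop symbol is
    stripped.  Ambiguity letters beyond X (B, Z, J, U, O) are rejected
    unless ``permissive`` is set, in which case they are mapped to X.

    Raises
    ------
    ValueError
        On an empty file, duplicate identifiers, an entry with an empty
        sequence, or illegal characters (the offending record is named).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate identifier {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"entry {pid!r} in {path} has an empty sequence")
        if permissive:
            seq = "".join("X" if c in AMBIGUOUS_AA else c for c in seq)
        bad = set(seq) - ALLOWED_AA
        if bad:
            raise ValueError(
                f"entry {pid!r} in {path}: illegal character(s) {sorted(bad)}"
            )
        records.append(
            ProteinRecord(protein_id=pid, sequence=seq, species_tag=species_tag)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write protein records as FASTA (identifier-only headers)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a tab-separated homology-hit table (query, subject, e-value).

    Extra columns beyond the third are ignored; scientific notation in any
    case ("1e-10", "1.0E-10") is accepted.  An empty table yields an empty
    list.
    """
    hits: list[HitRecord] = []
    for lineno, cols in _tsv_rows(path):
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns")
        try:
            e_value = float(cols[2])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: unparseable e-value {cols[2]!r}"
            ) from exc
        if e_value < 0:
            raise ValueError(f"{path}:{lineno}: negative e-value {cols[2]}")
        hits.append(HitRecord(cols[0], cols[1], e_value))
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# query\tsubject\te_value\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.e_value:g}\n")


_ANNOT_COLS = ("protein_id", "localization", "signal_peptide", "tm_count")


def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read a TSV of external annotations, keyed by protein identifier.

    The first non-comment row is a header.  Missing optional fields default
    to "unknown" (labels) or 0 (TM count).  Duplicate protein identifiers
    are an error.
    """
    out: dict[str, AnnotationRecord] = {}
    rows = iter(_tsv_rows(path))
    try:
        next(rows)  # header
    except StopIteration:
        return out
    for lineno, cols in rows:
        pid = cols[0]
        if pid in out:
            raise ValueError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
        loc = cols[1] if len(cols) > 1 and cols[1] else "unknown"
        sp = cols[2] if len(cols) > 2 and cols[2] else "unknown"
        tm = int(cols[3]) if len(cols) > 3 and cols[3] else 0
        out[pid] = AnnotationRecord(pid, loc, sp, tm)
    return out


def write_annotation_table(records: Iterable[AnnotationRecord],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLS) + "\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.localization_label}\t"
                     f"{r.signal_peptide}\t{r.tm_count}\n")


def read_aligned_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned protein FASTA (MSA): names and equal-length rows.

    Rows are upper-cased; ``-`` is the gap character.  Unequal row lengths
    or duplicate names are errors.
    """
    names: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValueError(f"duplicate identifier {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - ALLOWED_AA - {"-"}
        if bad:
            raise ValueError(f"{rec.id}: illegal character(s) {sorted(bad)}")
        names.append(rec.id)
        rows.append(seq)
    if not names:
        raise ValueError(f"no FASTA records found in {path}")
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"alignment rows in {path} differ in length")
    return names, rows


def read_locus_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein/transcript id -> locus id."""
    out: dict[str, str] = {}
    for lineno, cols in _tsv_rows(path):
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        out[cols[0]] = cols[1]
    return out
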