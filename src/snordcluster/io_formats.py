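"""File formats and run configuration.

Sequences travel as FASTA (read through Biopython, uppercased, U mapped to T
so everything downstream is DNA), genomic intervals as BED6 with 0-based
half-open coordinates, and alignments as aligned FASTA or Clustal.  The run
configuration is a flat TOML file whose defaults reproduce the published
analysis settings (90% consensus inclusion, 10% in/del and ambiguity floor,
95% Group-I identity, 80% residual identity).
"""

from __future__ import annotations

import gzip
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import GAP
from .msa import AlignScoring, Alignment

_ALLOWED = frozenset("ACGTN")
_STRANDS = frozenset("+-")


@dataclass(frozen=True)
class SequenceRecord:
    """A single DNA sequence with identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class LocusRow:
    """A BED-style genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.name}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_sequence(raw: str, record_id: str) -> str:
    """Uppercase, map U->T, and reject non-nucleotide characters."""
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _ALLOWED:
            raise ValueError(
                f"record {record_id!r}: non-nucleotide character {ch!r} "
                f"at position {pos}"
            )
    return seq


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records (order preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(rec.id, normalize_sequence(str(rec.seq), rec.id), desc)
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


def read_locus_table(path) -> list[LocusRow]:
    """Read a BED6-like tab-separated table of loci."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such locus table: {path}")
    rows: list[LocusRow] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                row = LocusRow(chrom, int(start), int(end), name, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rows.append(row)
    if not rows:
        raise ValueError(f"no rows found in {path}")
    return rows


def write_locus_table(rows: Iterable[LocusRow], path) -> None:
    with open(path, "w") as out:
        for r in rows:
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


_ALN_FORMATS = {"aligned-fasta": "fasta", "clustal": "clustal"}


def read_alignment(path, format: str = "aligned-fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an Alignment.

    Gap characters '.' are normalized to '-'; rows must be rectangular.
    """
    if format not in _ALN_FORMATS:
        raise ValueError(
            f"unknown alignment format {format!r} (expected one of "
            f"{sorted(_ALN_FORMATS)})"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such alignment file: {path}")
    ids: list[str] = []
    rows: list[str] = []
    if format == "aligned-fasta":
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                ids.append(rec.id)
                rows.append(str(rec.seq).upper().replace(".", GAP))
    else:
        with _open_text(path) as handle:
            msa = AlignIO.read(handle, "clustal")
        for rec in msa:
            ids.append(rec.id)
            rows.append(str(rec.seq).upper().replace(".", GAP))
    if not rows:
        raise ValueError(f"no alignment rows found in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        detail = ", ".join(f"{i} ({len(r)} columns)" for i, r in zip(ids, rows))
        raise ValueError(f"ragged alignment in {path}: {detail}")
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path, format: str = "aligned-fasta") -> None:
    if format not in _ALN_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        _BioRecord(Seq(row), id=rid, description="")
        for rid, row in zip(aln.row_ids, aln.rows)
    )
    with open(path, "w") as out:
        AlignIO.write(msa, out, _ALN_FORMATS[format])


@dataclass(frozen=True)
class RunConfig:
    """All tunable analysis parameters with the published defaults."""

    consensus_threshold: float = 0.90
    ambiguity_floor: float = 0.10
    indel_threshold: float = 0.10
    group1_identity: float = 0.95
    residual_identity: float = 0.80
    column_drop_gap_fraction: float = 0.50
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "consensus_threshold",
            "ambiguity_floor",
            "indel_threshold",
            "group1_identity",
            "residual_identity",
            "column_drop_gap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.consensus_threshold <= self.ambiguity_floor:
            raise ValueError(
                "consensus_threshold must exceed ambiguity_floor "
                f"({self.consensus_threshold} <= {self.ambiguity_floor})"
            )

    @property
    def scoring(self) -> AlignScoring:
        return AlignScoring(self.match, self.mismatch, self.gap_open, self.gap_extend)


def load_config(path=None) -> RunConfig:
    """Load a flat TOML config; missing keys fall back to the defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path, "rb") as handle:
        data = tomllib.load(handle)
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {unknown}")
    return RunConfig(**data)
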