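"""Strict and non-strict homology statistics between consensus sequences.

Two consensus sites are *strictly* homologous when they carry the identical
symbol (so W vs W counts; W vs T does not).  They are *non-strictly*
homologous when their IUPAC base sets intersect (T under a W = {A, T} site
counts).  A gap matches nothing in either mode.

``compare_consensus`` globally aligns two IUPAC consensus strings (non-strict
compatibility scored as a match) and classifies every reference nucleotide
site; counts are reported against the reference consensus length, matching
the convention of publishing "k of n reference nucleotides (pct)".
``cross_species_conservation`` does the multi-way analogue over a progressive
alignment of several consensus sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alphabet import GAP, IUPAC_ALPHABET, symbols_compatible
from .consensus import ConsensusSequence
from .msa import DEFAULT_SCORING, AlignScoring, Alignment, needleman_wunsch, progressive_align

SITE_CLASSES = ("perfect", "nonstrict_only", "mismatch", "gap")


def site_homology(x: str, y: str, mode: str) -> bool:
    """Homology of one aligned site pair under ``strict`` or ``nonstrict`` rules."""
    if mode not in ("strict", "nonstrict"):
        raise ValueError(f"unknown homology mode {mode!r}")
    for ch in (x, y):
        if ch != GAP and ch not in IUPAC_ALPHABET:
            raise ValueError(f"not an IUPAC symbol or gap: {ch!r}")
    if x == GAP or y == GAP:
        return False
    if mode == "strict":
        return x == y
    return symbols_compatible(x, y)


def classify_site(reference: str, query: str) -> str:
    """One of perfect / nonstrict_only / mismatch / gap for a reference site."""
    if query == GAP or reference == GAP:
        return "gap"
    if reference == query:
        return "perfect"
    if symbols_compatible(reference, query):
        return "nonstrict_only"
    return "mismatch"


@dataclass(frozen=True)
class HomologyReport:
    """Per-site classification and counts for one query vs one reference."""

    reference_label: str
    query_label: str
    aligned_reference: str
    aligned_query: str
    site_classes: tuple[str, ...]  # one per reference nucleotide site
    n_reference_nucleotides: int
    strict_count: int
    nonstrict_count: int
    source: str = "internal"

    def __post_init__(self) -> None:
        if self.nonstrict_count < self.strict_count:
            raise ValueError("nonstrict count below strict count")
        if self.nonstrict_count > self.n_reference_nucleotides:
            raise ValueError("counts exceed the reference length")

    @property
    def strict_pct(self) -> float:
        return self.strict_count / self.n_reference_nucleotides

    @property
    def nonstrict_pct(self) -> float:
        return self.nonstrict_count / self.n_reference_nucleotides


def compare_consensus(
    query: ConsensusSequence,
    reference: ConsensusSequence,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> HomologyReport:
    """Align two consensus sequences and tally strict/non-strict homology
    over the reference's nucleotide sites."""
    if not query.symbols or not reference.symbols:
        raise ValueError("cannot compare an empty consensus")
    aln = needleman_wunsch(reference.symbols, query.symbols, scoring, mode="iupac")
    classes: list[str] = []
    strict = nonstrict = 0
    for r, q in zip(aln.gapped_a, aln.gapped_b):
        if r == GAP:
            continue  # query insertions add no reference sites
        cls = classify_site(r, q)
        classes.append(cls)
        if cls == "perfect":
            strict += 1
            nonstrict += 1
        elif cls == "nonstrict_only":
            nonstrict += 1
    return HomologyReport(
        reference_label=reference.label,
        query_label=query.label,
        aligned_reference=aln.gapped_a,
        aligned_query=aln.gapped_b,
        site_classes=tuple(classes),
        n_reference_nucleotides=reference.n_nucleotides,
        strict_count=strict,
        nonstrict_count=nonstrict,
    )


@dataclass(frozen=True)
class ConservationSummary:
    """Cross-species conserved-site counts against one reference consensus."""

    reference_label: str
    labels: tuple[str, ...]
    alignment: Alignment
    conserved_strict: tuple[bool, ...]  # per alignment column
    conserved_nonstrict: tuple[bool, ...]
    strict_count: int
    nonstrict_count: int
    n_reference_nucleotides: int

    @property
    def strict_pct(self) -> float:
        return self.strict_count / self.n_reference_nucleotides

    @property
    def nonstrict_pct(self) -> float:
        return self.nonstrict_count / self.n_reference_nucleotides


def cross_species_conservation(
    consensuses: Sequence[ConsensusSequence],
    reference_label: str,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> ConservationSummary:
    """Progressively align consensus sequences and count columns conserved in
    every species, strictly (all identical, no gap) and non-strictly (every
    symbol compatible with the reference symbol)."""
    if len(consensuses) < 2:
        raise ValueError("need at least two consensus sequences")
    labels = [c.label for c in consensuses]
    if reference_label not in labels:
        raise ValueError(f"reference {reference_label!r} not among {labels}")
    reference = consensuses[labels.index(reference_label)]
    aln = progressive_align(
        [(c.label, c.symbols) for c in consensuses], scoring, mode="iupac"
    )
    ref_row = aln.row(reference_label)
    strict_cols: list[bool] = []
    nonstrict_cols: list[bool] = []
    strict = nonstrict = 0
    for j in range(aln.n_columns):
        col = aln.column(j)
        ref = ref_row[j]
        s = ref != GAP and all(c == ref for c in col)
        ns = ref != GAP and all(
            site_homology(c, ref, "nonstrict") for c in col
        )
        strict_cols.append(s)
        nonstrict_cols.append(ns)
        strict += s
        nonstrict += ns
    return ConservationSummary(
        reference_label=reference_label,
        labels=tuple(labels),
        alignment=aln,
        conserved_strict=tuple(strict_cols),
        conserved_nonstrict=tuple(nonstrict_cols),
        strict_count=strict,
        nonstrict_count=nonstrict,
        n_reference_nucleotides=reference.n_nucleotides,
    )


def homology_table(
    queries: Sequence[ConsensusSequence],
    references: Sequence[ConsensusSequence],
    scoring: AlignScoring = DEFAULT_SCORING,
) -> str:
    """TSV matrix shaped like the published homology comparison: one row per
    query consensus, non-strict then strict columns per reference, cells
    ``count (pct%)`` with the reference nucleotide count as denominator."""
    header = ["query"]
    for mode in ("nonstrict", "strict"):
        for ref in references:
            header.append(f"{ref.label}[{ref.n_nucleotides}nt]_{mode}")
    lines = ["\t".join(header)]
    for q in queries:
        reports = [compare_consensus(q, ref, scoring) for ref in references]
        cells = [q.label]
        for rep in reports:
            cells.append(f"{rep.nonstrict_count} ({rep.nonstrict_pct:.1%})")
        for rep in reports:
            cells.append(f"{rep.strict_count} ({rep.strict_pct:.1%})")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
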