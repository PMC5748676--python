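"""Anchor-ordered cluster assembly and positional transcript numbering.

A tandem snoRNA cluster is modeled relative to an anchor gene (the
SNURF/SNRPN transcription site in the published locus): "downstream" means
the anchor's direction of transcription, and transcripts are numbered 1, 2,
3, ... starting from the copy closest to the anchor.  On the minus strand all
sequences are reverse-complemented into sense-of-transcription orientation,
so downstream analyses are strand-agnostic.

Distances are measured edge-to-edge, from the anchor's 3' end to the
transcript's proximal edge.  Transcripts upstream of the anchor are tolerated
(logged) and numbered after all downstream transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .alphabet import reverse_complement
from .io_formats import LocusRow, SequenceRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transcript:
    """One snoRNA gene copy, in sense-of-transcription orientation."""

    id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    distance_to_anchor: int
    upstream: bool = False
    number: int | None = None


@dataclass(frozen=True)
class LocusCluster:
    """An ordered, strand-normalized set of transcripts around an anchor."""

    species: str
    anchor: LocusRow
    transcripts: tuple[Transcript, ...]
    strand: str

    @property
    def span_bp(self) -> int:
        return max(t.end for t in self.transcripts) - min(
            t.start for t in self.transcripts
        )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(f"no transcript {transcript_id!r} in cluster")

    def sequences(self) -> list[tuple[str, str]]:
        return [(t.id, t.sequence) for t in self.transcripts]


def build_cluster(
    records: Sequence[SequenceRecord],
    rows: Sequence[LocusRow],
    anchor_name: str,
    species: str = "synthetic",
) -> LocusCluster:
    """Assemble sequence records and locus rows into an anchor-ordered cluster.

    Input sequences are genome-forward; on a minus-strand cluster each is
    reverse-complemented so stored sequences read in the direction of
    transcription.  Transcripts are sorted by increasing distance from the
    anchor's 3' end (downstream first, upstream flagged and appended).
    """
    anchors = [r for r in rows if r.name == anchor_name]
    if not anchors:
        raise ValueError(f"anchor {anchor_name!r} not found in locus table")
    if len(anchors) > 1:
        raise ValueError(f"anchor {anchor_name!r} appears {len(anchors)} times")
    anchor = anchors[0]
    sno_rows = [r for r in rows if r.name != anchor_name]
    if not sno_rows:
        raise ValueError("locus table contains no transcripts besides the anchor")
    strands = {r.strand for r in sno_rows} | {anchor.strand}
    if len(strands) > 1:
        raise ValueError(f"mixed strands in cluster: {sorted(strands)}")
    strand = anchor.strand
    chroms = {r.chrom for r in rows}
    if len(chroms) > 1:
        raise ValueError(f"cluster spans multiple chromosomes: {sorted(chroms)}")
    by_id = {rec.id: rec for rec in records}
    orphans = sorted(r.name for r in sno_rows if r.name not in by_id)
    if orphans:
        raise ValueError(f"locus rows without sequences: {orphans}")

    transcripts = []
    for row in sno_rows:
        if strand == "+":
            offset = row.start - anchor.end  # anchor 3' end to proximal edge
        else:
            offset = anchor.start - row.end
        upstream = offset < 0
        seq = by_id[row.name].sequence
        if strand == "-":
            seq = reverse_complement(seq)
        transcripts.append(
            Transcript(
                id=row.name,
                sequence=seq,
                chrom=row.chrom,
                start=row.start,
                end=row.end,
                strand=strand,
                distance_to_anchor=abs(offset),
                upstream=upstream,
            )
        )
    upstreams = [t for t in transcripts if t.upstream]
    if upstreams:
        log.warning(
            "%d transcript(s) upstream of anchor %s: %s",
            len(upstreams), anchor_name, [t.id for t in upstreams],
        )
    ordered = sorted(
        transcripts, key=lambda t: (t.upstream, t.distance_to_anchor, t.id)
    )
    return LocusCluster(species, anchor, tuple(ordered), strand)


def number_transcripts(cluster: LocusCluster, prefix: str = "") -> LocusCluster:
    """Assign positional numbers 1..n in anchor-distance order.

    The transcript nearest the anchor becomes number 1 (named
    ``<prefix>-1`` style in reports when a prefix is given).
    """
    numbered = tuple(
        replace(t, number=i) for i, t in enumerate(cluster.transcripts, start=1)
    )
    return replace(cluster, transcripts=numbered)


def cluster_manifest(cluster: LocusCluster, prefix: str = "") -> str:
    """TSV manifest: id, number, positional name, chrom, start, end, strand,
    distance to anchor (1-based display coordinates)."""
    lines = ["id\tnumber\tname\tchrom\tstart\tend\tstrand\tdistance_bp\tupstream"]
    for t in cluster.transcripts:
        name = f"{prefix}-{t.number}" if prefix and t.number else str(t.number or "")
        lines.append(
            f"{t.id}\t{t.number or ''}\t{name}\t{t.chrom}\t{t.start + 1}\t{t.end}"
            f"\t{t.strand}\t{t.distance_to_anchor}\t{int(t.upstream)}"
        )
    return "\n".join(lines) + "\n"
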