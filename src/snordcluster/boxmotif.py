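"""C/C'/D/D' box annotation for C/D-box snoRNA transcripts.

The canonical motifs (DNA alphabet) are RTGATGA for the C and C' boxes and
CTGA for the D and D' boxes, searched within positional windows: the C box in
the 5' third, the D box in the 3' sixth, and the internal D'/C' copies in the
interior, in the order C < D' < C' < D along the transcript.  Detection takes
the fewest-mismatch hit in each window (leftmost on ties, bounded by a
per-box mismatch allowance); hits violating the box ordering are discarded.

"Perfectly homologous" boxes are operationalized within a cluster: a
transcript counts as perfect when all four boxes are present and exactly
equal the cluster's modal (most frequent) sequence for that box.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .alphabet import iupac_set
from .locus_model import LocusCluster

BOX_ORDER = ("C", "D_prime", "C_prime", "D")

DEFAULT_MOTIFS: dict[str, str] = {
    "C": "RTGATGA",
    "D_prime": "CTGA",
    "C_prime": "RTGATGA",
    "D": "CTGA",
}

# Windows as (start, end) fractions of sequence length; a hit must lie
# entirely inside its window.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "C": (0.0, 1 / 3),
    "D_prime": (0.25, 0.60),
    "C_prime": (0.45, 0.85),
    "D": (5 / 6, 1.0),
}

DEFAULT_MAX_MISMATCHES: dict[str, int] = {
    "C": 2,
    "D_prime": 1,
    "C_prime": 2,
    "D": 1,
}


@dataclass(frozen=True)
class BoxHit:
    name: str
    start: int  # 0-based half-open within the sequence
    end: int
    matched: str
    n_mismatches: int


@dataclass(frozen=True)
class BoxAnnotation:
    """Per-box hits for one transcript (absent boxes map to None)."""

    boxes: dict[str, BoxHit | None]

    def hit(self, name: str) -> BoxHit | None:
        return self.boxes[name]

    @property
    def all_present(self) -> bool:
        return all(self.boxes.get(name) is not None for name in BOX_ORDER)


def _pattern_mismatches(window: str, pattern: str) -> int:
    count = 0
    for ch, pat in zip(window, pattern):
        if ch not in iupac_set(pat):
            count += 1
    return count


def find_boxes(
    seq: str,
    motifs: Mapping[str, str] = DEFAULT_MOTIFS,
    windows: Mapping[str, tuple[float, float]] = DEFAULT_WINDOWS,
    max_mismatches: Mapping[str, int] = DEFAULT_MAX_MISMATCHES,
) -> BoxAnnotation:
    """Best window-constrained hit per box; ordering violations discarded."""
    L = len(seq)
    hits: dict[str, BoxHit | None] = {}
    for name in BOX_ORDER:
        pattern = motifs[name]
        for ch in pattern:
            iupac_set(ch)  # raises on malformed patterns
        lo_f, hi_f = windows[name]
        lo, hi = int(lo_f * L), int(hi_f * L)
        best: BoxHit | None = None
        for start in range(lo, min(hi, L) - len(pattern) + 1):
            mm = _pattern_mismatches(seq[start:start + len(pattern)], pattern)
            if mm <= max_mismatches[name] and (best is None or mm < best.n_mismatches):
                best = BoxHit(name, start, start + len(pattern),
                              seq[start:start + len(pattern)], mm)
                if mm == 0:
                    break  # leftmost perfect hit cannot be beaten
        hits[name] = best
    # Enforce C < D' < C' < D, non-overlapping; offenders become absent.
    last_end = -1
    for name in BOX_ORDER:
        hit = hits[name]
        if hit is None:
            continue
        if hit.start < last_end:
            hits[name] = None
        else:
            last_end = hit.end
    return BoxAnnotation(hits)


def annotate_cluster(
    cluster: LocusCluster,
    motifs: Mapping[str, str] = DEFAULT_MOTIFS,
    windows: Mapping[str, tuple[float, float]] = DEFAULT_WINDOWS,
    max_mismatches: Mapping[str, int] = DEFAULT_MAX_MISMATCHES,
) -> dict[str, BoxAnnotation]:
    return {
        t.id: find_boxes(t.sequence, motifs, windows, max_mismatches)
        for t in cluster.transcripts
    }


def modal_box_sequences(
    annotations: Mapping[str, BoxAnnotation],
) -> dict[str, str | None]:
    """Most frequent matched text per box across the cluster (lexicographic
    tie-break for determinism)."""
    modal: dict[str, str | None] = {}
    for name in BOX_ORDER:
        texts = [
            ann.boxes[name].matched
            for ann in annotations.values()
            if ann.boxes.get(name) is not None
        ]
        if not texts:
            modal[name] = None
            continue
        counts = Counter(texts)
        top = max(counts.values())
        modal[name] = min(t for t, c in counts.items() if c == top)
    return modal


def count_perfect_box_transcripts(
    cluster: LocusCluster,
    annotations: Mapping[str, BoxAnnotation],
) -> int:
    """Number of transcripts whose four boxes all equal the cluster's modal
    box sequences exactly."""
    if not cluster.transcripts:
        raise ValueError("empty cluster")
    missing = [t.id for t in cluster.transcripts if t.id not in annotations]
    if missing:
        raise ValueError(f"transcripts without box annotations: {missing}")
    modal = modal_box_sequences(annotations)
    count = 0
    for t in cluster.transcripts:
        ann = annotations[t.id]
        ok = True
        for name in BOX_ORDER:
            hit = ann.boxes.get(name)
            if hit is None or modal[name] is None or hit.matched != modal[name]:
                ok = False
                break
        count += ok
    return count


def box_table(
    cluster: LocusCluster,
    annotations: Mapping[str, BoxAnnotation],
) -> str:
    """TSV of per-transcript box coordinates (1-based display), matched text
    and perfection flags."""
    modal = modal_box_sequences(annotations)
    header = ["id", "number"]
    for name in BOX_ORDER:
        header += [f"{name}_start", f"{name}_end", f"{name}_seq", f"{name}_perfect"]
    header.append("all_perfect")
    lines = ["\t".join(header)]
    for t in cluster.transcripts:
        ann = annotations[t.id]
        cells = [t.id, str(t.number or "")]
        all_perfect = True
        for name in BOX_ORDER:
            hit = ann.boxes.get(name)
            if hit is None:
                cells += ["", "", "", "0"]
                all_perfect = False
            else:
                perfect = modal[name] is not None and hit.matched == modal[name]
                all_perfect &= perfect
                cells += [str(hit.start + 1), str(hit.end), hit.matched,
                          str(int(perfect))]
        cells.append(str(int(all_perfect)))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
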