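"""Plain-text comparison displays for aligned consensus sequences.

The display follows the dot/tilde/asterisk convention: the reference row is
printed in full; in each query row a site shows ``.`` when it is
non-strictly homologous to the reference symbol, ``~`` when the query has a
gap, and the query's own symbol otherwise; a footer row carries ``*`` at
every column where all rows are strictly identical and non-gap.  Box spans
can be marked beneath the ruler as bracketed column ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alphabet import GAP
from .homology_stats import site_homology
from .msa import Alignment

DOT = "."
TILDE = "~"
STAR = "*"


@dataclass(frozen=True)
class ComparisonDisplay:
    reference_id: str
    row_ids: tuple[str, ...]  # reference first
    display_rows: tuple[str, ...]  # reference row is its full symbols
    footer: str

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.display_rows} | {len(self.footer)}
        if len(lengths) != 1:
            raise ValueError("display rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.footer)


def build_comparison(alignment: Alignment, reference_id: str) -> ComparisonDisplay:
    """Derive the display characters from an alignment of consensus rows."""
    ref_row = alignment.row(reference_id)
    ids = [reference_id] + [i for i in alignment.row_ids if i != reference_id]
    rows: list[str] = [ref_row]
    for rid in ids[1:]:
        row = alignment.row(rid)
        chars = []
        for r, q in zip(ref_row, row):
            if q == GAP:
                chars.append(TILDE)
            elif r != GAP and site_homology(q, r, "nonstrict"):
                chars.append(DOT)
            else:
                chars.append(q)
        rows.append("".join(chars))
    footer_chars = []
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        footer_chars.append(
            STAR if col[0] != GAP and all(c == col[0] for c in col) else " "
        )
    return ComparisonDisplay(reference_id, tuple(ids), tuple(rows),
                             "".join(footer_chars))


def _ruler(start: int, width: int) -> str:
    """Column ruler with a tick every 10 columns (1-based numbering)."""
    chars = [" "] * width
    for offset in range(width):
        col = start + offset + 1
        if col % 10 == 0:
            label = str(col)
            pos = offset - len(label) + 1
            if pos >= 0:
                for k, ch in enumerate(label):
                    chars[pos + k] = ch
    return "".join(chars)


def render_comparison(
    alignment: Alignment,
    reference_id: str,
    boxes: Sequence[tuple[str, int, int]] | None = None,
    width: int = 60,
) -> str:
    """Render the comparison display as wrapped fixed-width text.

    `boxes` are optional (label, start_column, end_column) spans in 0-based
    alignment coordinates, drawn as bracketed ranges beneath the ruler.
    """
    display = build_comparison(alignment, reference_id)
    label_w = max(len(i) for i in display.row_ids) + 2
    blocks: list[str] = []
    for start in range(0, display.n_columns, width):
        stop = min(start + width, display.n_columns)
        lines = [" " * label_w + _ruler(start, stop - start)]
        if boxes:
            marker = [" "] * (stop - start)
            for name, b0, b1 in boxes:
                for col in range(max(b0, start), min(b1, stop)):
                    marker[col - start] = "="
                if start <= b0 < stop:
                    marker[b0 - start] = "["
                if start < b1 <= stop:
                    marker[b1 - 1 - start] = "]"
            lines.append(" " * label_w + "".join(marker))
        for rid, row in zip(display.row_ids, display.display_rows):
            lines.append(rid.ljust(label_w) + row[start:stop])
        lines.append(" " * label_w + display.footer[start:stop])
        blocks.append("\n".join(lines))
    legend = (
        f"reference: {reference_id}   .=non-strict homology   ~=gap   "
        "*=perfect homology in all rows"
    )
    return "\n\n".join(blocks) + "\n\n" + legend + "\n"
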