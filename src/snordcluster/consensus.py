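"""IUPAC threshold consensus of a multiple alignment.

Per column (gaps counted in the denominator):

* if the gap fraction exceeds ``column_drop_gap_fraction`` (default 50%) the
  column is dropped from the consensus entirely;
* else if the most frequent base reaches ``consensus_threshold`` (default
  90%, inclusive) the consensus symbol is that base;
* otherwise the symbol is the IUPAC code of every base at frequency >=
  ``ambiguity_floor`` (default 10%; falls back to all observed bases when
  none reaches the floor);
* independently, a column whose gap fraction reaches ``indel_threshold``
  (default 10%, inclusive) is flagged as an in/del site.

Retained columns keep a pointer to their source alignment column so box
annotations and ancestor comparisons can be mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import BASES, GAP, iupac_code, iupac_set
from .io_formats import RunConfig
from .msa import Alignment


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-column IUPAC symbols with frequencies and in/del flags."""

    label: str
    symbols: str
    frequencies: tuple[dict[str, float], ...]  # per retained column: A,C,G,T,-
    indel_flags: tuple[bool, ...]
    column_index: tuple[int, ...]  # retained column -> source alignment column
    dropped_columns: tuple[int, ...] = ()
    source: str = "internal"

    def __post_init__(self) -> None:
        n = len(self.symbols)
        if not (len(self.frequencies) == len(self.indel_flags)
                == len(self.column_index) == n):
            raise ValueError("consensus per-column tables are inconsistent")

    @property
    def n_nucleotides(self) -> int:
        return len(self.symbols)

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for s in self.symbols if s not in BASES)

    @property
    def n_indel(self) -> int:
        return sum(self.indel_flags)


def consensus_from_alignment(
    aln: Alignment,
    config: RunConfig | None = None,
    label: str = "consensus",
    source: str = "internal",
) -> ConsensusSequence:
    """Apply the threshold/ambiguity/in-del rules column by column."""
    config = config or RunConfig()
    if aln.n_columns == 0:
        raise ValueError("alignment has zero columns")
    if aln.n_rows < 2:
        raise ValueError("consensus needs at least 2 alignment rows")
    n_rows = aln.n_rows
    symbols: list[str] = []
    freqs: list[dict[str, float]] = []
    flags: list[bool] = []
    kept: list[int] = []
    dropped: list[int] = []
    for j in range(aln.n_columns):
        col = aln.column(j)
        counts = {b: 0 for b in BASES}
        gaps = 0
        for ch in col:
            if ch == GAP:
                gaps += 1
            elif ch in counts:
                counts[ch] += 1
            else:
                # Ambiguous input base (e.g. N): counts in the denominator
                # but toward no concrete base.
                pass
        gap_frac = gaps / n_rows
        if gap_frac > config.column_drop_gap_fraction:
            dropped.append(j)
            continue
        freq = {b: counts[b] / n_rows for b in BASES}
        freq[GAP] = gap_frac
        top = max(BASES, key=lambda b: (freq[b], -BASES.index(b)))
        if freq[top] >= config.consensus_threshold:
            sym = top
        else:
            qualifying = {b for b in BASES if freq[b] >= config.ambiguity_floor}
            if not qualifying:
                qualifying = {b for b in BASES if counts[b] > 0}
            sym = iupac_code(qualifying)
        symbols.append(sym)
        freqs.append(freq)
        flags.append(gap_frac >= config.indel_threshold)
        kept.append(j)
    if not symbols:
        raise ValueError("every alignment column was dropped by the gap rule")
    return ConsensusSequence(
        label=label,
        symbols="".join(symbols),
        frequencies=tuple(freqs),
        indel_flags=tuple(flags),
        column_index=tuple(kept),
        dropped_columns=tuple(dropped),
        source=source,
    )


def consensus_report(cons: ConsensusSequence, boxes=None) -> dict:
    """Summary counts: retained nucleotides, ambiguity-coded sites, in/del
    flagged sites, plus optional box annotations."""
    report = {
        "label": cons.label,
        "n_nucleotides": cons.n_nucleotides,
        "n_ambiguous": cons.n_ambiguous,
        "n_indel": cons.n_indel,
        "n_dropped_columns": len(cons.dropped_columns),
        "source": cons.source,
    }
    if boxes is not None:
        report["boxes"] = {
            name: (None if hit is None else {"start": hit.start, "end": hit.end,
                                             "matched": hit.matched})
            for name, hit in boxes.items()
        }
    return report


def consensus_report_text(report: dict) -> str:
    lines = [
        f"consensus\t{report['label']}",
        f"n_nucleotides\t{report['n_nucleotides']}",
        f"n_ambiguous\t{report['n_ambiguous']}",
        f"n_indel\t{report['n_indel']}",
        f"n_dropped_columns\t{report['n_dropped_columns']}",
        f"source\t{report['source']}",
    ]
    return "\n".join(lines) + "\n"


def consensus_column_table(cons: ConsensusSequence) -> str:
    """Per-column TSV: position (1-based), source column, symbol, base set,
    frequencies, in/del flag."""
    lines = ["pos\tsource_column\tsymbol\tbase_set\tA\tC\tG\tT\tgap\tindel"]
    for k, sym in enumerate(cons.symbols):
        f = cons.frequencies[k]
        base_set = "".join(sorted(iupac_set(sym)))
        lines.append(
            f"{k + 1}\t{cons.column_index[k] + 1}\t{sym}\t{base_set}\t"
            f"{f['A']:.3f}\t{f['C']:.3f}\t{f['G']:.3f}\t{f['T']:.3f}\t"
            f"{f[GAP]:.3f}\t{int(cons.indel_flags[k])}"
        )
    return "\n".join(lines) + "\n"
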