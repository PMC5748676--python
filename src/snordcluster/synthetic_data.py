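"""Synthetic tandem snoRNA loci with known ground truth.

The generator emulates the structure of sequenced SNORD116-like clusters:
17-71 tandem, highly similar ~98-nt C/D-box snoRNA copies downstream of an
anchor gene, organized into 1-3 divergence groups, on either strand, with
embedded C/D'/C'/D boxes that are perfect in most but not all copies.

The evolutionary model is deliberately simple: a random root ancestor with
planted boxes; per-group ancestors derived by substitution at the
between-group rate; copies within each group drawn star-wise from the group
ancestor at the within-group rate.  Substitutions are uniform over the three
alternative bases; indels initiate per site with geometric lengths and are
kept out of box spans so the planted box truth stays contiguous.  Box sites
mutate at their own (typically lower) rate.  Everything is reproducible from
the seed, and a minus-strand locus is the exact mirror of the plus-strand
one: same sense-space sequences and layout, mirrored genome coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .alphabet import BASES, iupac_set, reverse_complement
from .boxmotif import BOX_ORDER, DEFAULT_MOTIFS, BoxAnnotation, BoxHit, _pattern_mismatches
from .grouping import GroupAssignment
from .io_formats import LocusRow, SequenceRecord, write_fasta, write_locus_table
from .locus_model import LocusCluster, build_cluster, number_transcripts

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the defaults mirror the human-like cluster shape
    (30 copies in positional groups of 9/15/6, ~98 nt)."""

    group_sizes: tuple[int, ...] = (9, 15, 6)
    ancestor_length: int = 98
    within_group_sub_rate: float = 0.02
    between_group_sub_rate: float = 0.15
    indel_rate: float = 0.002
    indel_length_geometric_p: float = 0.5
    box_mutation_rate: float = 0.01
    n_outliers: int = 0
    outlier_sub_rate: float = 0.35
    intergenic_spacer_bp: tuple[int, int] = (800, 2000)
    anchor_length: int = 200
    strand: str = "+"
    chrom: str = "chrSim"
    anchor_name: str = "anchor"
    label: str = "synthetic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_group_sub_rate", "between_group_sub_rate",
                     "indel_rate", "box_mutation_rate", "outlier_sub_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.indel_length_geometric_p <= 1.0:
            raise ValueError("indel_length_geometric_p must be in (0, 1]")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.ancestor_length < 40:
            raise ValueError("ancestor too short to carry all four boxes")
        lo, hi = self.intergenic_spacer_bp
        if lo < 1 or hi < lo:
            raise ValueError("bad intergenic spacer range")


@dataclass(frozen=True)
class SimulatedLocus:
    """A generated cluster plus the truth tables the analysis should recover."""

    params: SimulationParams
    records: tuple[SequenceRecord, ...]  # genome-forward FASTA records
    rows: tuple[LocusRow, ...]  # BED rows (anchor included)
    cluster: LocusCluster  # built, strand-normalized, numbered
    truth_groups: GroupAssignment
    truth_boxes: dict[str, BoxAnnotation]  # sense-orientation coordinates
    root_ancestor: str
    group_ancestors: tuple[str, ...]


def _box_layout(length: int) -> dict[str, int]:
    """Planted box start positions (C < D' < C' < D) for a given length."""
    return {
        "C": 4,
        "D_prime": int(0.36 * length),
        "C_prime": int(0.56 * length),
        "D": length - 8,
    }


def _realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(iupac_set(ch))[rng.integers(len(iupac_set(ch)))] for ch in pattern
    )


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    indel_length_geometric_p: float = 0.5,
) -> str:
    """Substitute and indel a sequence site-by-site (uniform replacement
    bases, geometric indel lengths); deterministic under a fixed rng state."""
    out, _ = _mutate_tracked(
        seq,
        np.full(len(seq), float(sub_rate)),
        np.full(len(seq), float(indel_rate)),
        indel_length_geometric_p,
        rng,
    )
    return out


def _mutate_tracked(
    seq: str,
    sub_rates: np.ndarray,
    indel_rates: np.ndarray,
    p_geom: float,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
):
    """Mutate with a position map (old index -> new index or None).

    `protected` spans never receive indels and deletions truncate at their
    boundaries, so protected blocks stay contiguous in the output.
    """
    L = len(seq)
    in_protected = np.zeros(L, dtype=bool)
    for s, e in protected or []:
        in_protected[s:e] = True
    out: list[str] = []
    pos_map: list[int | None] = [None] * L
    i = 0
    while i < L:
        if not in_protected[i] and indel_rates[i] > 0 and rng.random() < indel_rates[i]:
            length = int(rng.geometric(p_geom))
            if rng.random() < 0.5:  # insertion before site i
                out.append(_random_bases(length, rng))
            else:  # deletion of sites i.. (stops at protected spans)
                removed = 0
                while i < L and removed < length and not in_protected[i]:
                    pos_map[i] = None
                    i += 1
                    removed += 1
                continue
        base = seq[i]
        if rng.random() < sub_rates[i]:
            alternatives = [b for b in BASES if b != base]
            base = alternatives[rng.integers(3)]
        pos_map[i] = sum(len(s) for s in out)
        out.append(base)
        i += 1
    return "".join(out), pos_map


def _plant_boxes(background: str, realized: dict[str, str],
                 layout: dict[str, int]) -> str:
    seq = list(background)
    for name, start in layout.items():
        box = realized[name]
        seq[start:start + len(box)] = box
    return "".join(seq)


def _has_spurious_hit(seq: str, realized: dict[str, str],
                      layout: dict[str, int]) -> bool:
    """A perfect off-position motif occurrence that could out-compete a
    planted box under the leftmost-tie rule."""
    from .boxmotif import DEFAULT_WINDOWS  # local to avoid cycle at import

    L = len(seq)
    for name in BOX_ORDER:
        pattern = DEFAULT_MOTIFS[name]
        lo = int(DEFAULT_WINDOWS[name][0] * L)
        planted = layout[name]
        for start in range(lo, planted):
            window = seq[start:start + len(pattern)]
            if len(window) == len(pattern) and _pattern_mismatches(window, pattern) == 0:
                if window != realized[name]:
                    return True
    return False


def simulate_locus(params: SimulationParams) -> SimulatedLocus:
    """Generate a full synthetic locus (FASTA/BED records, built cluster,
    and truth tables) from the parameter set's seed."""
    rng = np.random.default_rng(params.rng_seed)
    L = params.ancestor_length
    layout = _box_layout(L)
    spans = [(layout[n], layout[n] + len(DEFAULT_MOTIFS[n])) for n in BOX_ORDER]
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if e1 > s2:
            raise ValueError("ancestor too short: planted boxes overlap")
    realized = {n: _realize_pattern(DEFAULT_MOTIFS[n], rng) for n in BOX_ORDER}
    for _ in range(200):
        root = _plant_boxes(_random_bases(L, rng), realized, layout)
        if not _has_spurious_hit(root, realized, layout):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not generate a clean root ancestor")

    in_box = np.zeros(L, dtype=bool)
    for s, e in spans:
        in_box[s:e] = True

    def rates(base_rate: float) -> np.ndarray:
        r = np.full(L, base_rate)
        r[in_box] = params.box_mutation_rate
        return r

    no_indel = np.zeros(L)
    group_ancestors = []
    for _ in params.group_sizes:
        anc, _ = _mutate_tracked(
            root, rates(params.between_group_sub_rate), no_indel,
            params.indel_length_geometric_p, rng, protected=spans,
        )
        group_ancestors.append(anc)

    indel_rates = np.full(L, params.indel_rate)
    sense_seqs: list[str] = []
    truth_labels: list[str] = []
    truth_boxes_list: list[BoxAnnotation] = []
    for g, size in enumerate(params.group_sizes):
        for _ in range(size):
            seq, pos_map = _mutate_tracked(
                group_ancestors[g], rates(params.within_group_sub_rate),
                indel_rates, params.indel_length_geometric_p, rng,
                protected=spans,
            )
            sense_seqs.append(seq)
            truth_labels.append(_ROMAN[g])
            boxes: dict[str, BoxHit | None] = {}
            for name in BOX_ORDER:
                start = pos_map[layout[name]]
                width = len(DEFAULT_MOTIFS[name])
                matched = seq[start:start + width]
                boxes[name] = BoxHit(
                    name, start, start + width, matched,
                    _pattern_mismatches(matched, DEFAULT_MOTIFS[name]),
                )
            truth_boxes_list.append(BoxAnnotation(boxes))
    for _ in range(params.n_outliers):
        seq, pos_map = _mutate_tracked(
            root, rates(params.outlier_sub_rate), indel_rates,
            params.indel_length_geometric_p, rng, protected=spans,
        )
        sense_seqs.append(seq)
        truth_labels.append("ungrouped")
        boxes = {}
        for name in BOX_ORDER:
            start = pos_map[layout[name]]
            width = len(DEFAULT_MOTIFS[name])
            matched = seq[start:start + width]
            boxes[name] = BoxHit(name, start, start + width, matched,
                                 _pattern_mismatches(matched, DEFAULT_MOTIFS[name]))
        truth_boxes_list.append(BoxAnnotation(boxes))

    # Sense-space layout: anchor then tandem copies separated by spacers.
    lo, hi = params.intergenic_spacer_bp
    anchor_start = 1000
    anchor_end = anchor_start + params.anchor_length
    cursor = anchor_end
    sense_intervals: list[tuple[int, int]] = []
    for seq in sense_seqs:
        start = cursor + int(rng.integers(lo, hi + 1))
        sense_intervals.append((start, start + len(seq)))
        cursor = start + len(seq)
    total = cursor + 1000

    ids = [f"sno{k + 1:03d}" for k in range(len(sense_seqs))]
    rows: list[LocusRow] = []
    records: list[SequenceRecord] = []
    if params.strand == "+":
        rows.append(LocusRow(params.chrom, anchor_start, anchor_end,
                             params.anchor_name, "+"))
        for tid, (s, e), seq in zip(ids, sense_intervals, sense_seqs):
            rows.append(LocusRow(params.chrom, s, e, tid, "+"))
            records.append(SequenceRecord(tid, seq))
    else:
        rows.append(LocusRow(params.chrom, total - anchor_end,
                             total - anchor_start, params.anchor_name, "-"))
        for tid, (s, e), seq in zip(ids, sense_intervals, sense_seqs):
            rows.append(LocusRow(params.chrom, total - e, total - s, tid, "-"))
            records.append(SequenceRecord(tid, reverse_complement(seq)))

    cluster = number_transcripts(
        build_cluster(records, rows, params.anchor_name, species=params.label)
    )
    truth_groups = GroupAssignment(
        labels=dict(zip(ids, truth_labels)),
        template_ids={
            _ROMAN[g]: ids[sum(params.group_sizes[:g])]
            for g in range(len(params.group_sizes))
        },
        thresholds={},
        strategy="planted",
    )
    return SimulatedLocus(
        params=params,
        records=tuple(records),
        rows=tuple(rows),
        cluster=cluster,
        truth_groups=truth_groups,
        truth_boxes=dict(zip(ids, truth_boxes_list)),
        root_ancestor=root,
        group_ancestors=tuple(group_ancestors),
    )


def human_like_params(seed: int = 0, strand: str = "+") -> SimulationParams:
    """Human-shaped locus: 30 copies in positional groups 9/15/6."""
    return SimulationParams(strand=strand, label="human_like", rng_seed=seed)


def mouse_like_params(seed: int = 0, strand: str = "-") -> SimulationParams:
    """Mouse-shaped locus: 17 nearly identical copies, one group, minus strand."""
    return SimulationParams(
        group_sizes=(17,),
        within_group_sub_rate=0.002,
        box_mutation_rate=0.005,
        indel_rate=0.0,
        strand=strand,
        label="mouse_like",
        rng_seed=seed,
    )


def rabbit_like_params(seed: int = 0, strand: str = "-") -> SimulationParams:
    """Rabbit-shaped locus: two groups plus two deeply diverged ungrouped copies."""
    return SimulationParams(
        group_sizes=(12, 9),
        n_outliers=2,
        strand=strand,
        label="rabbit_like",
        rng_seed=seed,
    )


def truth_group_table(sim: SimulatedLocus) -> str:
    lines = ["id\tlabel"]
    for tid, label in sim.truth_groups.labels.items():
        lines.append(f"{tid}\t{label}")
    return "\n".join(lines) + "\n"


def truth_box_table(sim: SimulatedLocus) -> str:
    lines = ["id\tbox\tstart\tend\tmatched\tn_mismatches"]
    for tid, ann in sim.truth_boxes.items():
        for name in BOX_ORDER:
            hit = ann.boxes[name]
            lines.append(
                f"{tid}\t{name}\t{hit.start}\t{hit.end}\t{hit.matched}"
                f"\t{hit.n_mismatches}"
            )
    return "\n".join(lines) + "\n"


def write_locus(sim: SimulatedLocus, outdir) -> dict[str, Path]:
    """Write FASTA, BED, truth TSVs and a parameter echo; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "bed": outdir / "loci.bed",
        "truth_groups": outdir / "truth_groups.tsv",
        "truth_boxes": outdir / "truth_boxes.tsv",
        "params": outdir / "params.json",
    }
    write_fasta(sim.records, paths["fasta"])
    write_locus_table(sim.rows, paths["bed"])
    paths["truth_groups"].write_text(truth_group_table(sim))
    paths["truth_boxes"].write_text(truth_box_table(sim))
    with open(paths["params"], "w") as out:
        json.dump(asdict(sim.params), out, indent=2, sort_keys=True)
        out.write("\n")
    return paths
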