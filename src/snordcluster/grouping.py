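"""Identity-threshold grouping of tandem cluster paralogs.

Three strategies mirror how different species' clusters were organized:

* ``anchor_seeded`` — Group I is seeded by the transcript closest to the
  anchor (number 1) at the Group-I identity threshold (default 95%); the
  remainder is clustered greedily at the residual threshold (default 80%),
  largest group first, with members matching no template left ungrouped.
* ``largest_group`` — Group I is seeded by whichever transcript yields the
  largest 95%-identity group (the rat convention), then residual clustering.
* ``single_group`` — every transcript is labeled Group I provided all
  pairwise identities meet the Group-I threshold (the mouse case, where all
  copies show 95% homology or more); otherwise an error reports the worst
  pair.

Percent identity is computed over a global affine-gap alignment, excluding
columns inside terminal gap overhangs so that length differences between
near-identical tandem copies are not penalized.  All threshold comparisons
are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .alphabet import GAP
from .io_formats import RunConfig
from .locus_model import LocusCluster
from .msa import DEFAULT_SCORING, AlignScoring, needleman_wunsch

STRATEGIES = ("anchor_seeded", "largest_group", "single_group")

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
UNGROUPED = "ungrouped"


@dataclass(frozen=True)
class GroupAssignment:
    """A partition of cluster transcripts into labeled homology groups."""

    labels: dict[str, str]  # transcript id -> group label
    template_ids: dict[str, str]  # group label -> template transcript id
    thresholds: dict[str, float]
    strategy: str = ""

    def members(self, label: str) -> list[str]:
        return [tid for tid, lab in self.labels.items() if lab == label]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def same_partition(self, other: "GroupAssignment") -> bool:
        """True iff the two assignments induce the same partition by label."""
        return self.labels == other.labels


@lru_cache(maxsize=262144)
def _cached_identity(a: str, b: str, scoring: AlignScoring) -> float:
    aln = needleman_wunsch(a, b, scoring)
    ga, gb = aln.gapped_a, aln.gapped_b
    L = aln.n_columns
    # Terminal gap overhangs: leading/trailing gap runs of either row.
    lead = 0
    while lead < L and (ga[lead] == GAP or gb[lead] == GAP):
        lead += 1
    trail = 0
    while trail < L - lead and (ga[L - 1 - trail] == GAP or gb[L - 1 - trail] == GAP):
        trail += 1
    span = L - lead - trail
    if span <= 0:
        return 0.0
    same = sum(
        1
        for k in range(lead, L - trail)
        if ga[k] == gb[k] and ga[k] != GAP
    )
    return same / span


def pairwise_identity(a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING) -> float:
    """Fraction of identical positions over the global alignment of `a` and
    `b`, excluding terminal gap-overhang columns.  Symmetric; 1.0 iff the
    sequences are identical."""
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if a > b:  # symmetry -> canonical cache key
        a, b = b, a
    return _cached_identity(a, b, scoring)


def group_by_template(
    cluster: LocusCluster,
    template_id: str,
    threshold: float,
    scoring: AlignScoring = DEFAULT_SCORING,
    restrict_to: set[str] | None = None,
) -> set[str]:
    """Ids of all transcripts (template included) with identity >= threshold
    to the template.  `restrict_to` limits the candidate pool."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    template = cluster.transcript(template_id)  # raises KeyError if unknown
    members = set()
    for t in cluster.transcripts:
        if restrict_to is not None and t.id not in restrict_to:
            continue
        if t.id == template_id or pairwise_identity(
            template.sequence, t.sequence, scoring
        ) >= threshold:
            members.add(t.id)
    return members


def auto_template(
    cluster: LocusCluster,
    threshold: float,
    scoring: AlignScoring = DEFAULT_SCORING,
    restrict_to: set[str] | None = None,
) -> str:
    """The transcript whose template group is largest; ties go to the
    smallest transcript number."""
    if not cluster.transcripts:
        raise ValueError("empty cluster")
    candidates = [
        t
        for t in cluster.transcripts
        if restrict_to is None or t.id in restrict_to
    ]
    best_id, best_size, best_number = None, -1, None
    for t in sorted(candidates, key=lambda t: (t.number is None, t.number, t.id)):
        size = len(
            group_by_template(cluster, t.id, threshold, scoring, restrict_to)
        )
        if size > best_size:
            best_id, best_size = t.id, size
    return best_id


def _residual_greedy(
    cluster: LocusCluster,
    residue: set[str],
    threshold: float,
    scoring: AlignScoring,
) -> tuple[list[set[str]], dict[int, str], set[str]]:
    """Greedy largest-group-first extraction on the residue.

    Returns (extracted groups in extraction order, template per group index,
    ungrouped ids).  Members whose best template group is a singleton fail
    the threshold against everything and are ungrouped.
    """
    groups: list[set[str]] = []
    templates: dict[int, str] = {}
    residue = set(residue)
    while residue:
        tid = auto_template(cluster, threshold, scoring, restrict_to=residue)
        grp = group_by_template(cluster, tid, threshold, scoring, restrict_to=residue)
        if len(grp) <= 1:
            break  # every remaining member matches nothing but itself
        templates[len(groups)] = tid
        groups.append(grp)
        residue -= grp
    return groups, templates, residue


def _genomic_rank(cluster: LocusCluster, ids: set[str]) -> int:
    return min(
        t.number if t.number is not None else 10**9
        for t in cluster.transcripts
        if t.id in ids
    )


def assign_groups(
    cluster: LocusCluster,
    strategy: str = "anchor_seeded",
    config: RunConfig | None = None,
) -> GroupAssignment:
    """Partition cluster transcripts into Groups I, II, III, ... / ungrouped."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r} (expected {STRATEGIES})")
    config = config or RunConfig()
    scoring = config.scoring
    if not cluster.transcripts:
        raise ValueError("empty cluster")
    if any(t.number is None for t in cluster.transcripts):
        raise ValueError("cluster must be numbered before grouping")
    all_ids = {t.id for t in cluster.transcripts}
    thresholds = {
        "group1_identity": config.group1_identity,
        "residual_identity": config.residual_identity,
    }

    if strategy == "single_group":
        worst = (1.0, None)
        seqs = cluster.sequences()
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                ident = pairwise_identity(seqs[i][1], seqs[j][1], scoring)
                if ident < worst[0]:
                    worst = (ident, (seqs[i][0], seqs[j][0]))
        if worst[0] < config.group1_identity:
            a, b = worst[1]
            raise ValueError(
                f"single_group requires all pairs >= {config.group1_identity:.0%}"
                f" identity; worst pair {a} vs {b} at {worst[0]:.1%}"
            )
        template = min(cluster.transcripts, key=lambda t: t.number).id
        return GroupAssignment(
            {t.id: "I" for t in cluster.transcripts},
            {"I": template},
            thresholds,
            strategy,
        )

    if strategy == "anchor_seeded":
        template1 = min(cluster.transcripts, key=lambda t: t.number).id
    else:  # largest_group (rat convention)
        template1 = auto_template(cluster, config.group1_identity, scoring)
    group1 = group_by_template(cluster, template1, config.group1_identity, scoring)
    residue = all_ids - group1
    extracted, res_templates, ungrouped = _residual_greedy(
        cluster, residue, config.residual_identity, scoring
    )
    # Label residual groups II, III, ... by genomic order of first member.
    order = sorted(range(len(extracted)), key=lambda k: _genomic_rank(cluster, extracted[k]))
    labels: dict[str, str] = {}
    template_ids: dict[str, str] = {"I": template1}
    for tid in group1:
        labels[tid] = "I"
    for rank, k in enumerate(order):
        label = _ROMAN[rank + 1] if rank + 1 < len(_ROMAN) else f"G{rank + 2}"
        for tid in extracted[k]:
            labels[tid] = label
        template_ids[label] = res_templates[k]
    for tid in ungrouped:
        labels[tid] = UNGROUPED
    # Deterministic ordering of the mapping by transcript number.
    ordered = {
        t.id: labels[t.id] for t in cluster.transcripts
    }
    return GroupAssignment(ordered, template_ids, thresholds, strategy)


def group_table(
    cluster: LocusCluster,
    assignment: GroupAssignment,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> str:
    """TSV: id, number, label, identity to the group template."""
    lines = ["id\tnumber\tlabel\ttemplate\tidentity_to_template"]
    for t in cluster.transcripts:
        label = assignment.labels[t.id]
        template = assignment.template_ids.get(label, "")
        if template:
            ident = pairwise_identity(
                cluster.transcript(template).sequence, t.sequence, scoring
            )
            ident_s = f"{ident:.4f}"
        else:
            ident_s = ""
        lines.append(f"{t.id}\t{t.number}\t{label}\t{template}\t{ident_s}")
    return "\n".join(lines) + "\n"
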