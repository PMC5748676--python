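"""End-to-end pipeline: FASTA + BED + config -> grouped consensus analysis.

This is the library behind the ``run-all`` command and the analysis drivers:
build and number the cluster, annotate boxes, assign homology groups, align
each group, derive IUPAC threshold consensus sequences, compare every group
consensus against the Group I reference (strict and non-strict), and render
the dot/tilde/asterisk comparison display.  All outputs are plain text and
byte-reproducible for a given input and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import boxmotif
from .consensus import consensus_column_table, consensus_from_alignment
from .grouping import UNGROUPED, assign_groups, group_table
from .homology_stats import homology_table
from .io_formats import (
    RunConfig,
    SequenceRecord,
    read_alignment,
    read_fasta,
    read_locus_table,
    write_alignment,
    write_fasta,
)
from .locus_model import build_cluster, cluster_manifest, number_transcripts
from .msa import progressive_align
from .render import render_comparison


def run_all(
    fasta_path,
    bed_path,
    anchor_name: str,
    out_dir,
    config: RunConfig | None = None,
    strategy: str = "anchor_seeded",
    species: str = "sample",
    alignment_path=None,
    seed: int = 0,
) -> dict:
    """Execute the full analysis and write all reports under `out_dir`.

    Returns the JSON-serializable run summary.  `alignment_path` optionally
    substitutes an externally produced multiple alignment (aligned FASTA)
    for the internal progressive aligner when building the whole-cluster
    consensus; the summary records which path produced each alignment.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scoring = config.scoring

    records = read_fasta(fasta_path)
    rows = read_locus_table(bed_path)
    cluster = number_transcripts(
        build_cluster(records, rows, anchor_name, species=species)
    )
    (out_dir / "cluster_manifest.tsv").write_text(cluster_manifest(cluster))

    annotations = boxmotif.annotate_cluster(cluster)
    (out_dir / "boxes.tsv").write_text(boxmotif.box_table(cluster, annotations))
    n_perfect = boxmotif.count_perfect_box_transcripts(cluster, annotations)

    assignment = assign_groups(cluster, strategy, config)
    (out_dir / "groups.tsv").write_text(group_table(cluster, assignment, scoring))

    # Whole-cluster alignment and consensus.
    if alignment_path is not None:
        cluster_aln = read_alignment(alignment_path)
        cluster_source = f"external:{Path(alignment_path).name}"
    else:
        cluster_aln = progressive_align(cluster.sequences(), scoring)
        cluster_source = "internal-progressive"
    write_alignment(cluster_aln, out_dir / "cluster_alignment.fasta")
    cluster_cons = consensus_from_alignment(
        cluster_aln, config, label=f"{species}_all", source=cluster_source
    )

    # Per-group alignments and consensus sequences.
    group_labels = sorted(
        {lab for lab in assignment.labels.values() if lab != UNGROUPED},
        key=lambda lab: min(
            t.number for t in cluster.transcripts if assignment.labels[t.id] == lab
        ),
    )
    consensuses = []
    for lab in group_labels:
        member_ids = [
            t.id for t in cluster.transcripts if assignment.labels[t.id] == lab
        ]
        members = [(tid, cluster.transcript(tid).sequence) for tid in member_ids]
        if len(members) < 2:
            continue  # no consensus from a single sequence
        aln = progressive_align(members, scoring)
        write_alignment(aln, out_dir / f"group_{lab}_alignment.fasta")
        cons = consensus_from_alignment(
            aln, config, label=f"{species}_{lab}", source="internal-progressive"
        )
        (out_dir / f"group_{lab}_consensus_columns.tsv").write_text(
            consensus_column_table(cons)
        )
        consensuses.append(cons)

    all_cons = consensuses + [cluster_cons]
    write_fasta(
        [SequenceRecord(c.label, c.symbols) for c in all_cons],
        out_dir / "consensus.fasta",
    )

    summary: dict = {
        "species": species,
        "strategy": strategy,
        "seed": seed,
        "anchor": anchor_name,
        "n_transcripts": cluster.n_transcripts,
        "span_bp": cluster.span_bp,
        "strand": cluster.strand,
        "n_perfect_box_transcripts": n_perfect,
        "group_sizes": dict(sorted(assignment.group_sizes().items())),
        "templates": dict(sorted(assignment.template_ids.items())),
        "thresholds": assignment.thresholds,
        "cluster_alignment_source": cluster_source,
        "consensus": {
            c.label: {
                "n_nucleotides": c.n_nucleotides,
                "n_ambiguous": c.n_ambiguous,
                "n_indel": c.n_indel,
            }
            for c in all_cons
        },
    }

    if len(consensuses) >= 1:
        reference = consensuses[0]  # Group I
        queries = [c for c in all_cons if c.label != reference.label]
        if queries:
            (out_dir / "homology_table.tsv").write_text(
                homology_table(queries, [reference], scoring)
            )
        if len(all_cons) >= 2:
            cons_aln = progressive_align(
                [(c.label, c.symbols) for c in all_cons], scoring, mode="iupac"
            )
            (out_dir / "comparison_display.txt").write_text(
                render_comparison(cons_aln, reference.label)
            )

    with open(out_dir / "run_summary.json", "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True)
        out.write("\n")
    return summary
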