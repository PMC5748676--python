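#!/usr/bin/env python
"""Strict vs non-strict homology between consensus sequences: the
table-shaped comparison of every group/cluster consensus against the
human-shaped Group I reference, and cross-species conserved-site counts for
several species-level consensuses descended from one ancestor."""

import argparse
from pathlib import Path

import numpy as np

from snordcluster.consensus import consensus_from_alignment
from snordcluster.grouping import UNGROUPED, assign_groups
from snordcluster.homology_stats import (
    cross_species_conservation,
    homology_table,
)
from snordcluster.msa import progressive_align
from snordcluster.synthetic_data import (
    human_like_params,
    mouse_like_params,
    mutate_sequence,
    simulate_locus,
)


def group_consensuses(sim, strategy):
    asg = assign_groups(sim.cluster, strategy)
    out = []
    for lab in sorted(set(asg.labels.values()) - {UNGROUPED}):
        members = [
            (t.id, t.sequence)
            for t in sim.cluster.transcripts
            if asg.labels[t.id] == lab
        ]
        if len(members) >= 2:
            out.append(consensus_from_alignment(
                progressive_align(members),
                label=f"{sim.params.label}_{lab}",
            ))
    return out


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/homology"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    human = simulate_locus(human_like_params(seed=args.seed))
    mouse = simulate_locus(mouse_like_params(seed=args.seed))
    human_groups = group_consensuses(human, "anchor_seeded")
    mouse_all = consensus_from_alignment(
        progressive_align(mouse.cluster.sequences()), label="mouse_like_all"
    )
    references = human_groups  # human groups as column references
    queries = [mouse_all] + [c for c in human_groups[1:]]
    table = homology_table(queries, references)
    (args.out / "homology_table.tsv").write_text(table)
    print(table)

    # Cross-species conservation from one shared root ancestor.
    rng = np.random.default_rng(args.seed)
    species = []
    for k in range(6):
        anc = mutate_sequence(human.root_ancestor, 0.04, 0.0, rng)
        copies = [(f"sp{k}c{i}", mutate_sequence(anc, 0.01, 0.0, rng))
                  for i in range(12)]
        species.append(consensus_from_alignment(
            progressive_align(copies), label=f"sp{k}"
        ))
    summary = cross_species_conservation(species, "sp0")
    n = summary.n_reference_nucleotides
    print(f"cross-species conserved: {summary.nonstrict_count}/{n} "
          f"({summary.nonstrict_pct:.0%}) non-strict, "
          f"{summary.strict_count}/{n} ({summary.strict_pct:.0%}) strict")
    (args.out / "cross_species.tsv").write_text(
        "mode\tconserved\tof\tpct\n"
        f"nonstrict\t{summary.nonstrict_count}\t{n}\t{summary.nonstrict_pct:.3f}\n"
        f"strict\t{summary.strict_count}\t{n}\t{summary.strict_pct:.3f}\n"
    )


if __name__ == "__main__":
    main()
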