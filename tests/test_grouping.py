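import numpy as np
import pytest

from snordcluster.grouping import (
    assign_groups,
    auto_template,
    group_by_template,
    pairwise_identity,
)
from snordcluster.io_formats import LocusRow, RunConfig, SequenceRecord
from snordcluster.locus_model import build_cluster, number_transcripts


def _make_cluster(seqs: dict[str, str]):
    """Tandem plus-strand cluster in dict order."""
    rows = [LocusRow("chr1", 0, 100, "anchor", "+")]
    records = []
    pos = 200
    for name, seq in seqs.items():
        rows.append(LocusRow("chr1", pos, pos + len(seq), name, "+"))
        records.append(SequenceRecord(name, seq))
        pos += len(seq) + 100
    return number_transcripts(build_cluster(records, rows, "anchor"))


def _mutated(seq: str, n_subs: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestPairwiseIdentity:
    def test_examples(self):
        assert pairwise_identity("ACGT", "ACGT") == 1.0
        assert pairwise_identity("ACGT", "ACGA") == 0.75

    def test_five_substitutions_in_100nt_give_95_percent(self):
        rng = np.random.default_rng(0)
        a = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        b = _mutated(a, 5, rng)
        assert pairwise_identity(a, b) == pytest.approx(0.95)

    def test_terminal_overhangs_excluded(self):
        # b is a perfect suffix of a: overhang columns must not dilute identity
        a = "TTTTTACGTACGT"
        b = "ACGTACGT"
        assert pairwise_identity(a, b) == 1.0

    def test_symmetric_and_one_iff_identical(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = "".join("ACGT"[k] for k in rng.integers(0, 4, size=50))
            b = _mutated(a, int(rng.integers(0, 6)), rng)
            assert pairwise_identity(a, b) == pairwise_identity(b, a)
            assert (pairwise_identity(a, b) == 1.0) == (a == b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestGroupByTemplate:
    def test_identical_cluster_groups_everything(self):
        cluster = _make_cluster({f"t{i}": "ACGTACGTAC" * 10 for i in range(4)})
        assert group_by_template(cluster, "t0", 0.95) == {"t0", "t1", "t2", "t3"}

    def test_threshold_is_inclusive_at_the_boundary(self):
        rng = np.random.default_rng(1)
        base = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        cluster = _make_cluster({"tpl": base, "edge": _mutated(base, 5, rng)})
        assert pairwise_identity(base, cluster.transcript("edge").sequence) == 0.95
        assert group_by_template(cluster, "tpl", 0.95) == {"tpl", "edge"}

    def test_unknown_template(self):
        cluster = _make_cluster({"a": "ACGTACGT"})
        with pytest.raises(KeyError):
            group_by_template(cluster, "zz", 0.9)

    def test_raising_threshold_never_enlarges_group(self, human_sim):
        cluster = human_sim.cluster
        template = cluster.transcripts[0].id
        sizes = [
            len(group_by_template(cluster, template, th))
            for th in (0.70, 0.80, 0.90, 0.95, 0.99)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_recovers_truth_group_when_separation_holds(self, human_sim):
        """When realized divergences respect the thresholds, the template
        group equals the planted group of the template."""
        cluster = human_sim.cluster
        truth = human_sim.truth_groups.labels
        template = cluster.transcripts[0].id
        planted = {tid for tid, lab in truth.items() if lab == truth[template]}
        separated = all(
            pairwise_identity(
                cluster.transcript(template).sequence, t.sequence
            ) >= 0.95
            if t.id in planted
            else pairwise_identity(
                cluster.transcript(template).sequence, t.sequence
            ) < 0.95
            for t in cluster.transcripts
        )
        got = group_by_template(cluster, template, 0.95)
        if separated:
            assert got == planted
        else:  # the threshold itself defines membership
            assert template in got


class TestAutoTemplate:
    def test_all_identical_ties_break_to_number_one(self):
        cluster = _make_cluster({f"t{i}": "ACGT" * 25 for i in range(4)})
        assert auto_template(cluster, 0.95) == "t0"

    def test_member_of_larger_planted_group_wins_vs_brute_force(self):
        rng = np.random.default_rng(2)
        big = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        small = _mutated(big, 30, rng)  # far below any threshold
        seqs = {}
        for i in range(10):
            seqs[f"big{i}"] = _mutated(big, 1, rng)
        for i in range(5):
            seqs[f"small{i}"] = _mutated(small, 1, rng)
        cluster = _make_cluster(seqs)
        winner = auto_template(cluster, 0.95)
        assert winner.startswith("big")
        # brute force over every template, same tie rule
        best = None
        for t in cluster.transcripts:
            size = len(group_by_template(cluster, t.id, 0.95))
            if best is None or size > best[0]:
                best = (size, t.id)
        assert winner == best[1]

    def test_equal_groups_pick_lowest_number(self):
        rng = np.random.default_rng(4)
        a = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        b = _mutated(a, 30, rng)
        cluster = _make_cluster({"a1": a, "a2": a, "b1": b, "b2": b})
        assert auto_template(cluster, 0.95) == "a1"


class TestAssignGroups:
    def test_partition_covers_every_transcript_once(self, human_sim):
        asg = assign_groups(human_sim.cluster, "anchor_seeded")
        assert set(asg.labels) == {t.id for t in human_sim.cluster.transcripts}

    def test_planted_three_group_recovery_when_separated(self):
        """Widely separated planted groups (sizes 9/15/6) are recovered
        exactly, with labels following genomic order."""
        rng = np.random.default_rng(8)
        root = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        ancestors = [_mutated(root, 25, rng) for _ in range(3)]
        seqs = {}
        truth = {}
        for g, (anc, size) in enumerate(zip(ancestors, (9, 15, 6))):
            for i in range(size):
                name = f"g{g}t{i:02d}"
                seqs[name] = _mutated(anc, 1, rng)
                truth[name] = ["I", "II", "III"][g]
        cluster = _make_cluster(seqs)
        asg = assign_groups(cluster, "anchor_seeded")
        assert asg.labels == truth
        assert asg.group_sizes() == {"I": 9, "II": 15, "III": 6}

    def test_largest_group_strategy_seeds_from_biggest_group(self):
        rng = np.random.default_rng(9)
        root = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        small_anc = _mutated(root, 25, rng)
        seqs = {}
        # genomically first: a small tight group; then a larger one
        for i in range(4):
            seqs[f"s{i}"] = _mutated(small_anc, 1, rng)
        for i in range(8):
            seqs[f"l{i}"] = _mutated(root, 1, rng)
        cluster = _make_cluster(seqs)
        asg = assign_groups(cluster, "largest_group")
        assert asg.template_ids["I"].startswith("l")
        assert set(asg.members("I")) == {f"l{i}" for i in range(8)}

    def test_single_group_accepts_near_identical_cluster(self, mouse_sim):
        asg = assign_groups(mouse_sim.cluster, "single_group")
        assert set(asg.labels.values()) == {"I"}
        assert len(asg.labels) == 17

    def test_single_group_rejects_divergent_cluster_naming_worst_pair(self, human_sim):
        with pytest.raises(ValueError, match="worst pair"):
            assign_groups(human_sim.cluster, "single_group")

    def test_outliers_below_residual_threshold_stay_ungrouped(self, rabbit_sim):
        asg = assign_groups(rabbit_sim.cluster, "anchor_seeded")
        truth = rabbit_sim.truth_groups.labels
        planted_out = {tid for tid, lab in truth.items() if lab == "ungrouped"}
        got_out = {tid for tid, lab in asg.labels.items() if lab == "ungrouped"}
        assert planted_out <= got_out

    def test_unknown_strategy(self, human_sim):
        with pytest.raises(ValueError, match="strategy"):
            assign_groups(human_sim.cluster, "kmeans")
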