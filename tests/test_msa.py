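import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snordcluster.alphabet import GAP
from snordcluster.msa import (
    AlignScoring,
    Alignment,
    build_guide_tree,
    needleman_wunsch,
    progressive_align,
)

SCORING = AlignScoring()


def brute_force_best_score(a: str, b: str, scoring: AlignScoring) -> float:
    """Enumerate every global alignment as a column sequence and score it by
    scanning gap runs (gap of length L costs gap_open + L * gap_extend).
    Exponential; only for short sequences."""

    def columns(i, j):
        if i == len(a) and j == len(b):
            yield []
            return
        if i < len(a) and j < len(b):
            for rest in columns(i + 1, j + 1):
                yield [(a[i], b[j])] + rest
        if i < len(a):
            for rest in columns(i + 1, j):
                yield [(a[i], GAP)] + rest
        if j < len(b):
            for rest in columns(i, j + 1):
                yield [(GAP, b[j])] + rest

    def score(cols):
        total = 0.0
        prev_gap_a = prev_gap_b = False
        for x, y in cols:
            if x == GAP:
                total += scoring.gap_extend + (0 if prev_gap_a else scoring.gap_open)
                prev_gap_a, prev_gap_b = True, False
            elif y == GAP:
                total += scoring.gap_extend + (0 if prev_gap_b else scoring.gap_open)
                prev_gap_a, prev_gap_b = False, True
            else:
                total += scoring.match if x == y else scoring.mismatch
                prev_gap_a = prev_gap_b = False
        return total

    return max(score(c) for c in columns(0, 0))


class TestNeedlemanWunsch:
    def test_identical_sequences_align_gapless(self):
        aln = needleman_wunsch("ACGT", "ACGT", AlignScoring(1, -1, -2, -1))
        assert aln.score == 4 and aln.gapped_a == aln.gapped_b == "ACGT"

    def test_single_mismatch_column(self):
        aln = needleman_wunsch("A", "T")
        assert aln.score == SCORING.mismatch
        assert (aln.gapped_a, aln.gapped_b) == ("A", "T")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            needleman_wunsch("AAAA", "")

    def test_deletion_matches_brute_force(self):
        aln = needleman_wunsch("ACGT", "AGT")
        assert aln.score == brute_force_best_score("ACGT", "AGT", SCORING)
        assert aln.gapped_a.replace(GAP, "") == "ACGT"
        assert aln.gapped_b.replace(GAP, "") == "AGT"

    def test_matches_brute_force_on_random_short_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join("ACGT"[k] for k in rng.integers(0, 4, size=la))
            b = "".join("ACGT"[k] for k in rng.integers(0, 4, size=lb))
            aln = needleman_wunsch(a, b)
            assert aln.score == pytest.approx(brute_force_best_score(a, b, SCORING))

    def test_matches_biopython_scores_on_longer_pairs(self):
        """Independent cross-check against Bio.Align.PairwiseAligner with the
        equivalent affine parameterization (first gap char costs open+extend)."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = SCORING.match
        aligner.mismatch_score = SCORING.mismatch
        aligner.open_gap_score = SCORING.gap_open + SCORING.gap_extend
        aligner.extend_gap_score = SCORING.gap_extend
        rng = np.random.default_rng(7)
        for _ in range(25):
            la, lb = rng.integers(5, 40, size=2)
            a = "".join("ACGT"[k] for k in rng.integers(0, 4, size=la))
            b = "".join("ACGT"[k] for k in rng.integers(0, 4, size=lb))
            assert needleman_wunsch(a, b).score == pytest.approx(aligner.score(a, b))

    def test_no_gap_gap_columns_and_ungap_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = "".join("ACGT"[k] for k in rng.integers(0, 4, size=30))
            b = "".join("ACGT"[k] for k in rng.integers(0, 4, size=25))
            aln = needleman_wunsch(a, b)
            assert aln.gapped_a.replace(GAP, "") == a
            assert aln.gapped_b.replace(GAP, "") == b
            assert all(
                (x, y) != (GAP, GAP) for x, y in zip(aln.gapped_a, aln.gapped_b)
            )

    def test_deterministic(self):
        a, b = "ACGTACGTAC", "ACGTCGTAC"
        r1 = needleman_wunsch(a, b)
        r2 = needleman_wunsch(a, b)
        assert (r1.gapped_a, r1.gapped_b) == (r2.gapped_a, r2.gapped_b)


class TestGuideTree:
    def test_two_sequences_form_a_cherry(self):
        tree = build_guide_tree(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        assert tree.newick() == "(a,b)"

    def test_closest_pair_joined_first(self):
        D = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        tree = build_guide_tree(["A", "B", "C"], D)
        assert tree.newick() == "((A,B),C)"

    def test_ties_broken_lexicographically(self):
        D = np.full((3, 3), 0.2)
        np.fill_diagonal(D, 0.0)
        tree = build_guide_tree(["c", "a", "b"], D)
        assert tree.newick() == "((a,b),c)"

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_guide_tree(["a", "b"], np.array([[0, 0.1], [0.2, 0]]))
        with pytest.raises(ValueError, match="negative"):
            build_guide_tree(["a", "b"], np.array([[0, -0.1], [-0.1, 0]]))

    def test_root_split_recovers_planted_bipartition(self, human_sim):
        """Eight simulated sequences from two planted divergence groups must
        split at the root into the planted groups."""
        from snordcluster.grouping import pairwise_identity

        g1 = [t for t in human_sim.cluster.transcripts
              if human_sim.truth_groups.labels[t.id] == "I"][:4]
        g2 = [t for t in human_sim.cluster.transcripts
              if human_sim.truth_groups.labels[t.id] == "II"][:4]
        chosen = g1 + g2
        ids = [t.id for t in chosen]
        n = len(ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = 1 - pairwise_identity(
                    chosen[i].sequence, chosen[j].sequence
                )
        tree = build_guide_tree(ids, D)
        split = {frozenset(tree.left.leaf_ids), frozenset(tree.right.leaf_ids)}
        planted = {frozenset(t.id for t in g1), frozenset(t.id for t in g2)}
        assert split == planted


class TestProgressiveAlign:
    def test_identical_sequences_align_gapless(self):
        recs = [(f"s{i}", "ACGTACGTAC") for i in range(5)]
        aln = progressive_align(recs)
        assert aln.n_columns == 10
        assert all(GAP not in row for row in aln.rows)

    def test_internal_deletion_gives_one_gap_block(self):
        full = "ACGTACGTACGTACGTACGT"
        deleted = full[:8] + full[12:]
        aln = progressive_align([("full", full), ("del", deleted)])
        pair = needleman_wunsch(full, deleted)
        assert aln.row("full") == pair.gapped_a
        assert aln.row("del") == pair.gapped_b
        gaps = aln.row("del")
        assert gaps.count(GAP) == 4
        start = gaps.index(GAP)
        assert gaps[start:start + 4] == GAP * 4  # one contiguous block

    def test_ungap_recovers_inputs(self, human_sim):
        seqs = human_sim.cluster.sequences()[:10]
        aln = progressive_align(seqs)
        for sid, seq in seqs:
            assert aln.ungapped(sid) == seq

    def test_permuting_input_order_gives_same_gapped_rows(self, human_sim):
        seqs = human_sim.cluster.sequences()[:8]
        aln1 = progressive_align(seqs)
        aln2 = progressive_align(list(reversed(seqs)))
        assert {(i, aln1.row(i)) for i, _ in seqs} == {
            (i, aln2.row(i)) for i, _ in seqs
        }

    def test_single_record_warns(self):
        with pytest.warns(UserWarning, match="single"):
            aln = progressive_align([("only", "ACGT")])
        assert aln.rows == ["ACGT"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=5, max_size=30),
            min_size=2,
            max_size=5,
        )
    )
    def test_ungap_invariant_property(self, seqs):
        recs = [(f"s{i}", s) for i, s in enumerate(seqs)]
        aln = progressive_align(recs)
        for sid, seq in recs:
            assert aln.ungapped(sid) == seq


class TestAlignmentContainer:
    def test_ragged_and_duplicate_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment(["a", "b"], ["ACGT", "ACG"])
        with pytest.raises(ValueError, match="duplicate"):
            Alignment(["a", "a"], ["ACGT", "ACGT"])
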