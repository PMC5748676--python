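"""Global pairwise and progressive multiple sequence alignment.

The aligner is a standard affine-gap (Gotoh) global dynamic program with fully
deterministic traceback: ties are broken by preferring the diagonal move, then
the vertical (gap in the second sequence), then the horizontal.  A gap of
length L costs ``gap_open + L * gap_extend``.  The multiple aligner is
progressive: a UPGMA guide tree over pairwise distances, profiles merged by
profile-profile extension of the same dynamic program (column score = mean
pairwise character score; gaps score ``gap_extend`` against characters and 0
against gaps).

Two character models are supported: ``"dna"`` (identity match on concrete
bases) and ``"iupac"`` (two symbols score as a match when their IUPAC base
sets intersect), the latter used when aligning consensus sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alphabet import GAP, IUPAC_MASK, symbols_compatible

NEG_INF = float("-inf")
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring scheme (penalties are non-positive)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match < self.mismatch:
            raise ValueError("match score must be >= mismatch score")


DEFAULT_SCORING = AlignScoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows differ in length")
        for x, y in zip(self.gapped_a, self.gapped_b):
            if x == GAP and y == GAP:
                raise ValueError("gap-gap column in pairwise alignment")

    @property
    def n_columns(self) -> int:
        return len(self.gapped_a)


class Alignment:
    """A rectangular gapped-sequence matrix with unique row identifiers."""

    def __init__(self, row_ids: Sequence[str], rows: Sequence[str]):
        row_ids = list(row_ids)
        rows = [str(r) for r in rows]
        if len(row_ids) != len(rows):
            raise ValueError("row_ids and rows differ in length")
        if not rows:
            raise ValueError("alignment needs at least one row")
        if len(set(row_ids)) != len(row_ids):
            dupes = sorted({i for i in row_ids if row_ids.count(i) > 1})
            raise ValueError(f"duplicate row ids: {dupes}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            detail = ", ".join(f"{i}:{len(r)}" for i, r in zip(row_ids, rows))
            raise ValueError(f"ragged alignment rows ({detail})")
        self.row_ids = row_ids
        self.rows = rows

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no alignment row with id {row_id!r}") from None

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def reorder(self, row_ids: Sequence[str]) -> "Alignment":
        return Alignment(list(row_ids), [self.row(i) for i in row_ids])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.row_ids == other.row_ids and self.rows == other.rows

    def __repr__(self) -> str:
        return f"Alignment({self.n_rows} rows x {self.n_columns} columns)"


def _char_indices(seq: str, alphabet: dict[str, int], what: str) -> np.ndarray:
    try:
        return np.array([alphabet[c] for c in seq], dtype=np.intp)
    except KeyError:
        bad = next(c for c in seq if c not in alphabet)
        raise ValueError(f"invalid character {bad!r} in {what}") from None


def _substitution_matrix(mode: str, scoring: AlignScoring):
    """Return (alphabet index map, kernel matrix) for a character model."""
    if mode == "dna":
        letters = "ACGTN"
        kernel = np.full((5, 5), scoring.mismatch)
        np.fill_diagonal(kernel, scoring.match)
    elif mode == "iupac":
        letters = "ACGTRYSWKMBDHVN"
        n = len(letters)
        kernel = np.empty((n, n))
        for i, x in enumerate(letters):
            for j, y in enumerate(letters):
                kernel[i, j] = (
                    scoring.match if (IUPAC_MASK[x] & IUPAC_MASK[y]) else scoring.mismatch
                )
    else:
        raise ValueError(f"unknown character model {mode!r}")
    return {c: i for i, c in enumerate(letters)}, kernel


def _gotoh_matrices(S: np.ndarray, scoring: AlignScoring):
    """Fill the three affine-gap DP matrices for a column-score matrix S.

    S[i, j] is the score of aligning position i of `a` with position j of `b`
    (0-based).  Returns (M, X, Y) of shape (m+1, n+1): M ends in a match
    column, X in a gap in b (vertical move), Y in a gap in a (horizontal).
    """
    m, n = S.shape
    go, ge = scoring.gap_open, scoring.gap_extend
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)
    Y = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    js = np.arange(1, n + 1)
    Y[0, 1:] = go + ge * js
    for i in range(1, m + 1):
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = S[i - 1, :] + prev
        X[i, :] = ge + np.maximum(
            X[i - 1, :], go + np.maximum(M[i - 1, :], Y[i - 1, :])
        )
        # Horizontal state via running max: Y[i,j] = max_{k<j} (j-k)*ge + go + best[k]
        best = np.maximum(M[i, :], X[i, :])
        t = go + best - ge * np.arange(n + 1)
        Y[i, 1:] = ge * js + np.maximum.accumulate(t[:-1])
    return M, X, Y


def _traceback(S: np.ndarray, M: np.ndarray, X: np.ndarray, Y: np.ndarray,
               scoring: AlignScoring):
    """Deterministic traceback: prefer M (diagonal), then X (up), then Y (left)."""
    m, n = S.shape
    go, ge = scoring.gap_open, scoring.gap_extend
    i, j = m, n
    finals = (M[m, n], X[m, n], Y[m, n])
    best = max(finals)
    state = ("M", "X", "Y")[next(k for k, v in enumerate(finals) if v >= best - _TIE_TOL)]
    path: list[tuple[str, int, int]] = []  # (state, i, j) consumed at each step
    while i > 0 or j > 0:
        if state == "M":
            path.append(("M", i, j))
            target = M[i, j] - S[i - 1, j - 1]
            cands = (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]), ("Y", Y[i - 1, j - 1]))
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = next(s for s, v in cands if v >= target - _TIE_TOL)
        elif state == "X":
            path.append(("X", i, j))
            target = X[i, j] - ge
            cands = (
                ("M", go + M[i - 1, j]),
                ("X", X[i - 1, j]),
                ("Y", go + Y[i - 1, j]),
            )
            i -= 1
            if i == 0 and j == 0:
                break
            state = next(s for s, v in cands if v >= target - _TIE_TOL)
        else:  # Y
            path.append(("Y", i, j))
            target = Y[i, j] - ge
            cands = (
                ("M", go + M[i, j - 1]),
                ("X", go + X[i, j - 1]),
                ("Y", Y[i, j - 1]),
            )
            j -= 1
            if i == 0 and j == 0:
                break
            state = next(s for s, v in cands if v >= target - _TIE_TOL)
    path.reverse()
    return best, path


def needleman_wunsch(a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING,
                     mode: str = "dna") -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap costs.

    Ties during traceback are broken deterministically (diagonal, then a gap
    in `b`, then a gap in `a`).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    index, kernel = _substitution_matrix(mode, scoring)
    ia = _char_indices(a, index, "first sequence")
    ib = _char_indices(b, index, "second sequence")
    S = kernel[np.ix_(ia, ib)]
    M, X, Y = _gotoh_matrices(S, scoring)
    score, path = _traceback(S, M, X, Y, scoring)
    ga: list[str] = []
    gb: list[str] = []
    for state, i, j in path:
        if state == "M":
            ga.append(a[i - 1])
            gb.append(b[j - 1])
        elif state == "X":
            ga.append(a[i - 1])
            gb.append(GAP)
        else:
            ga.append(GAP)
            gb.append(b[j - 1])
    return PairwiseAlignment("".join(ga), "".join(gb), float(score))


# ---------------------------------------------------------------------------
# Guide tree (UPGMA)
# ---------------------------------------------------------------------------


@dataclass
class GuideTreeNode:
    """Node of a rooted UPGMA guide tree; leaves carry a single id."""

    leaf_ids: tuple[str, ...]
    height: float = 0.0
    left: "GuideTreeNode | None" = None
    right: "GuideTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def key(self) -> str:
        """Lexicographically smallest leaf id — used for deterministic ties."""
        return min(self.leaf_ids)

    def newick(self) -> str:
        if self.is_leaf:
            return self.leaf_ids[0]
        return f"({self.left.newick()},{self.right.newick()})"


def build_guide_tree(ids: Sequence[str], distances: np.ndarray) -> GuideTreeNode:
    """UPGMA tree over a symmetric distance matrix; ties joined by the
    lexicographically smallest (key_i, key_j) cluster pair."""
    ids = list(ids)
    D = np.asarray(distances, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if np.any(D < 0):
        raise ValueError("negative distances")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    if n == 0:
        raise ValueError("no sequences")
    nodes: dict[int, GuideTreeNode] = {
        k: GuideTreeNode((ids[k],)) for k in range(n)
    }
    sizes = {k: 1 for k in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        live = sorted(nodes)
        best_pair = None
        best_d = None
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                i, j = live[ai], live[bi]
                d = dist[(i, j) if i < j else (j, i)]
                ki, kj = nodes[i].key, nodes[j].key
                tiekey = (min(ki, kj), max(ki, kj))
                if best_d is None or d < best_d - 1e-12 or (
                    abs(d - best_d) <= 1e-12 and tiekey < best_key
                ):
                    best_d, best_pair, best_key = d, (i, j), tiekey
        i, j = best_pair
        a, b = nodes.pop(i), nodes.pop(j)
        # Deterministic child order: smaller key on the left.
        left, right = (a, b) if a.key <= b.key else (b, a)
        merged = GuideTreeNode(
            tuple(left.leaf_ids + right.leaf_ids), best_d / 2.0, left, right
        )
        si, sj = sizes.pop(i), sizes.pop(j)
        for k in list(nodes):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        dist.pop((i, j), None)
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        next_id += 1
    return nodes.popitem()[1]


# ---------------------------------------------------------------------------
# Progressive profile alignment
# ---------------------------------------------------------------------------


def _profile_counts(rows: list[str], index: dict[str, int]) -> np.ndarray:
    """Column count matrix of shape (len(alphabet)+1, L); last row is gaps."""
    k = len(index)
    L = len(rows[0])
    counts = np.zeros((k + 1, L))
    for row in rows:
        for j, c in enumerate(row):
            counts[k if c == GAP else index[c], j] += 1
    return counts


def _merge_profiles(rows_a: list[str], rows_b: list[str], index, kernel,
                    scoring: AlignScoring) -> tuple[list[str], list[str]]:
    """Align two profiles; return the two row groups with new gap columns."""
    k = len(index)
    big = np.zeros((k + 1, k + 1))
    big[:k, :k] = kernel
    big[k, :k] = big[:k, k] = scoring.gap_extend  # gap vs character
    big[k, k] = 0.0  # gap vs gap
    ca = _profile_counts(rows_a, index)
    cb = _profile_counts(rows_b, index)
    na, nb = len(rows_a), len(rows_b)
    S = (ca.T @ big @ cb) / (na * nb)
    M, X, Y = _gotoh_matrices(S, scoring)
    _, path = _traceback(S, M, X, Y, scoring)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    for state, i, j in path:
        if state == "M":
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
        elif state == "X":
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r in out_b:
                r.append(GAP)
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _quick_distance(a: str, b: str, scoring: AlignScoring, mode: str) -> float:
    """Fractional difference over the columns of the optimal pairwise alignment
    (guide-tree metric only; the grouping module owns the reported identity)."""
    aln = needleman_wunsch(a, b, scoring, mode)
    same = sum(
        1 for x, y in zip(aln.gapped_a, aln.gapped_b)
        if x != GAP and x == y
    )
    return 1.0 - same / aln.n_columns


def progressive_align(records: Iterable, scoring: AlignScoring = DEFAULT_SCORING,
                      mode: str = "dna") -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    `records` is an iterable of objects with ``id`` and ``sequence``
    attributes (or ``(id, sequence)`` pairs).  Row order of the result follows
    the input order; the set of gapped rows is invariant under input
    permutation.
    """
    pairs = []
    for rec in records:
        if isinstance(rec, tuple):
            pairs.append(rec)
        else:
            pairs.append((rec.id, rec.sequence))
    if not pairs:
        raise ValueError("no sequences to align")
    ids = [p[0] for p in pairs]
    seqs = {i: s for i, s in pairs}
    if len(seqs) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(pairs) == 1:
        warnings.warn("single-sequence alignment is trivial", stacklevel=2)
        return Alignment(ids, [pairs[0][1]])
    index, kernel = _substitution_matrix(mode, scoring)
    # Distances computed over lexicographically sorted ids so that the guide
    # tree (hence the alignment) is independent of input order.
    sorted_ids = sorted(ids)
    n = len(sorted_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _quick_distance(
                seqs[sorted_ids[i]], seqs[sorted_ids[j]], scoring, mode
            )
    tree = build_guide_tree(sorted_ids, D)

    def merge(node: GuideTreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return list(node.leaf_ids), [seqs[node.leaf_ids[0]]]
        ids_l, rows_l = merge(node.left)
        ids_r, rows_r = merge(node.right)
        new_l, new_r = _merge_profiles(rows_l, rows_r, index, kernel, scoring)
        return ids_l + ids_r, new_l + new_r

    out_ids, out_rows = merge(tree)
    aln = Alignment(out_ids, out_rows)
    return aln.reorder(ids)
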