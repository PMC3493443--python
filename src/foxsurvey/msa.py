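"""Progressive multiple sequence alignment.

A deterministic progressive aligner sufficient for distance estimation on
a conserved protein domain: a neighbor-joining guide tree is built from
pairwise global-alignment p-distances, and profiles are merged in guide
tree (postorder) order by profile–profile dynamic programming with
average-of-pairs column scoring and the same affine gap penalties as the
pairwise aligner.  There is no iterative refinement, sequence weighting or
position-specific gap model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from . import phylo
from .pairwise import GLOBAL_SCHEME, ScoringScheme, needleman_wunsch
from .seq_io import SequenceRecord


@dataclass
class MultipleAlignment:
    """Gapped equal-length rows over an ordered id list."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.rows:
            n_cols = len(self.rows[0])
            for c in range(n_cols):
                if all(r[c] == "-" for r in self.rows):
                    raise ValueError(f"all-gap column at position {c + 1}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


# ---------------------------------------------------------------------------
# profile-profile dynamic programming (affine gaps, average-of-pairs scores)

_MOVE_DIAG, _MOVE_UP, _MOVE_LEFT = 0, 1, 2


@njit(cache=False)
def _affine_profile_dp(S, open_cost, extend_cost):  # pragma: no cover - numba
    """Global affine DP over a precomputed column-score matrix.

    Returns the traceback as an array of moves (0 diag, 1 up/consume-A,
    2 left/consume-B), with ties broken diagonal > up > left.
    """
    n1, n2 = S.shape
    NEG = -1e30
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)  # gap in B (vertical)
    Y = np.full((n1 + 1, n2 + 1), NEG)  # gap in A (horizontal)
    ptr_m = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_x = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptr_y = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -(open_cost + (i - 1) * extend_cost)
        ptr_x[i, 0] = 1  # extend
    for j in range(1, n2 + 1):
        Y[0, j] = -(open_cost + (j - 1) * extend_cost)
        ptr_y[0, j] = 1
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            s = S[i - 1, j - 1]
            # M: best of three predecessors, diag-favoring tie-break
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            ptr_m[i, j] = ptr
            # X: open from M or extend X (vertical move)
            open_score = M[i - 1, j] - open_cost
            ext_score = X[i - 1, j] - extend_cost
            if open_score >= ext_score:
                X[i, j] = open_score
                ptr_x[i, j] = 0
            else:
                X[i, j] = ext_score
                ptr_x[i, j] = 1
            # Y: open from M or extend Y (horizontal move)
            open_score = M[i, j - 1] - open_cost
            ext_score = Y[i, j - 1] - extend_cost
            if open_score >= ext_score:
                Y[i, j] = open_score
                ptr_y[i, j] = 0
            else:
                Y[i, j] = ext_score
                ptr_y[i, j] = 1
    # choose final state, preference M > X > Y
    state = 0
    best = M[n1, n2]
    if X[n1, n2] > best:
        best = X[n1, n2]
        state = 1
    if Y[n1, n2] > best:
        best = Y[n1, n2]
        state = 2
    moves = np.empty(n1 + n2, dtype=np.int8)
    k = n1 + n2
    i, j = n1, n2
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            moves[k] = _MOVE_DIAG
            state = ptr_m[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = _MOVE_UP
            state = 0 if ptr_x[i, j] == 0 else 1
            i -= 1
        else:
            moves[k] = _MOVE_LEFT
            state = 0 if ptr_y[i, j] == 0 else 2
            j -= 1
    return moves[k:], best


_ALPHABET = "ACDEFGHIKLMNPQRSTVWYXBZ"
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Residue count matrix (n_columns x alphabet); gaps are not counted."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(_ALPHABET)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            if ch == "U":
                ch = "C"
            counts[c, _CHAR_INDEX[ch]] += 1.0
    return counts


def _score_submatrix(scheme: ScoringScheme) -> np.ndarray:
    S = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            S[i, j] = scheme.pair_score(a, b)
    return S


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], S_res: np.ndarray, scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    pair_counts = ca.sum(axis=1)[:, None] * cb.sum(axis=1)[None, :]
    totals = ca @ S_res @ cb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        col_scores = np.where(pair_counts > 0, totals / np.maximum(pair_counts, 1), 0.0)
    moves, _ = _affine_profile_dp(
        col_scores, float(scheme.gap_open + scheme.gap_extend), float(scheme.gap_extend)
    )
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for mv in moves:
        if mv == _MOVE_DIAG:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif mv == _MOVE_UP:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append("-")
            ia += 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _pairwise_p_distance(a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme) -> float:
    aln = needleman_wunsch(a, b, scheme)
    comparable = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x != "-" and y != "-"
    )
    if comparable == 0:
        return 1.0
    mismatches = comparable - aln.n_identical
    return mismatches / comparable


def progressive_align(
    seqs: Sequence[SequenceRecord], scheme: ScoringScheme = GLOBAL_SCHEME
) -> MultipleAlignment:
    """Progressively align ``seqs`` along an NJ guide tree.

    Deterministic for a fixed input order: the guide tree is NJ on
    pairwise global-alignment p-distances (ties broken by input order via
    the NJ tie-break rule), and two sequences reduce exactly to the
    pairwise global alignment.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to align")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 2:
        aln = needleman_wunsch(seqs[0], seqs[1], scheme)
        return MultipleAlignment(ids=ids, rows=[aln.aligned_a, aln.aligned_b])

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_p_distance(seqs[i], seqs[j], scheme)
    guide = phylo.neighbor_joining(phylo.DistanceMatrix(ids=ids, d=d))

    S_res = _score_submatrix(scheme)
    by_id = {s.id: s for s in seqs}

    def _align_node(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [by_id[node.name].residues]
        child_profiles = [_align_node(ch) for ch in node.children]
        ids_acc, rows_acc = child_profiles[0]
        for ids_next, rows_next in child_profiles[1:]:
            rows_acc, rows_next = _merge_profiles(rows_acc, rows_next, S_res, scheme)
            ids_acc = ids_acc + ids_next
            rows_acc = rows_acc + rows_next
        return ids_acc, rows_acc

    out_ids, out_rows = _align_node(guide.root)
    order = {name: k for k, name in enumerate(ids)}
    ranked = sorted(zip(out_ids, out_rows), key=lambda t: order[t[0]])
    return MultipleAlignment(ids=[i for i, _ in ranked], rows=[r for _, r in ranked])


def sum_of_pairs_score(msa: MultipleAlignment, scheme: ScoringScheme = GLOBAL_SCHEME) -> float:
    """Sum over row pairs of the projected pairwise affine alignment score.

    Columns where both rows of a pair are gapped are dropped before
    scoring the pair; runs of gaps are charged open + k·extend.
    """
    total = 0.0
    for i in range(len(msa.rows)):
        for j in range(i + 1, len(msa.rows)):
            a, b = msa.rows[i], msa.rows[j]
            pa = []
            pb = []
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                pa.append(x)
                pb.append(y)
            total += _score_projected_pair("".join(pa), "".join(pb), scheme)
    return total


def _score_projected_pair(a: str, b: str, scheme: ScoringScheme) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == "-":
            score -= scheme.gap_extend + (0 if in_gap_a else scheme.gap_open)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= scheme.gap_extend + (0 if in_gap_b else scheme.gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            score += scheme.pair_score(x, y)
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# aligned-FASTA / CLUSTAL output

def read_aligned_fasta(path: str | Path) -> MultipleAlignment:
    from .seq_io import FastaError

    ids: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
                current = []
                rows.append(current)
            elif current is None:
                raise FastaError(f"{path}: residues before first header")
            else:
                current.append(line.strip().upper())
    return MultipleAlignment(ids=ids, rows=["".join(r) for r in rows])


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f">{name}\n")
            for k in range(0, len(row), 60):
                fh.write(row[k : k + 60] + "\n")


def write_clustal(msa: MultipleAlignment, path: str | Path) -> None:
    """Simple CLUSTAL-format writer (for eyeballing alignments)."""
    width = max(len(i) for i in msa.ids) + 3
    with Path(path).open("w") as fh:
        fh.write("CLUSTAL format alignment\n\n")
        for start in range(0, msa.n_columns, 60):
            for name, row in zip(msa.ids, msa.rows):
                fh.write(name.ljust(width) + row[start : start + 60] + "\n")
            fh.write("\n")
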