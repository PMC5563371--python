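"""Global protein alignment and the alignment-coverage statistic.

Clusters are compared by Needleman–Wunsch/Gotoh global alignment of
their concatenated biosynthetic proteins: affine gaps (a gap of length
k costs ``gap_open + k * gap_extend`` = 10 + k by default), BLOSUM62
substitution scores, end gaps fully penalized.  Two summary statistics
drive the similarity network:

* identity = identical columns / total alignment columns (gap columns
  count against identity), and
* the coverage index ``(L_al - Gaps) / L_long`` where ``Gaps`` is the
  number of gap-containing columns and ``L_long`` the longer input
  length — i.e. the fraction of the longer sequence involved in
  residue-to-residue columns, which compensates for length differences
  between clusters.

Determinism: traceback prefers diagonal, then up (gap in the second
sequence), then left; the pair is canonically ordered internally
(longer sequence first, ties broken lexicographically) so that
``align(a, b)`` and ``align(b, a)`` report identical statistics even
when co-optimal alignments differ.

``X`` (unknown residue) scores 0 against everything, including itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


def _build_blosum62() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0.0  # unknown residue is scored neutrally
            else:
                mat[i, j] = blosum[a][b]
    return mat


BLOSUM62_X0 = _build_blosum62()

_NEG = -1e30


@njit(cache=True)
def _gotoh(a: np.ndarray, b: np.ndarray, sub: np.ndarray,
           gap_open: float, gap_ext: float):
    """Affine-gap global DP with pointer matrices; returns (score, ops)
    where ops is an int8 array over columns: 0 diagonal, 1 up (consume
    a), 2 left (consume b).  Tie-break: M > up-gap > left-gap."""
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b: consuming a, "up"
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a: consuming b, "left"
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_ext)
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_ext)
        pY[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal move; previous state preference M > X > Y
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + sub[a[i - 1], b[j - 1]]
            pM[i, j] = arg
            # X: open from M preferred over extend on ties
            op = M[i - 1, j] - (gap_open + gap_ext)
            ext = X[i - 1, j] - gap_ext
            if op >= ext:
                X[i, j], pX[i, j] = op, 0
            else:
                X[i, j], pX[i, j] = ext, 1
            op = M[i, j - 1] - (gap_open + gap_ext)
            ext = Y[i, j - 1] - gap_ext
            if op >= ext:
                Y[i, j], pY[i, j] = op, 0
            else:
                Y[i, j], pY[i, j] = ext, 1
    score, state = M[n, m], 0
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    ops = np.empty(n + m, np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = 0 if pX[i, j] == 0 else 1
            i -= 1
        else:
            ops[k] = 2
            state = 0 if pY[i, j] == 0 else 2
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise global alignment.

    ``L_al`` is the number of alignment columns, ``gap_columns`` the
    number of columns containing a gap symbol, ``L_long`` the length of
    the longer input.  ``coverage`` = (L_al - gap_columns) / L_long.
    """

    query_id: str
    target_id: str
    score: float
    L_al: int
    gap_columns: int
    n_identical: int
    identity: float
    coverage: float
    L_long: int
    aligned_query: str
    aligned_target: str


def coverage_index(L_al: int, gaps: int, L_long: int) -> float:
    """The coverage index (L_al - Gaps) / L_long.

    ``Gaps`` counts gap-containing alignment columns, so the numerator
    equals the number of residue-to-residue columns and the index is
    bounded by 1.
    """
    if L_long < 1:
        raise ValueError("L_long must be >= 1")
    if not 0 <= gaps <= L_al:
        raise ValueError("need 0 <= gaps <= L_al")
    return (L_al - gaps) / L_long


def _encode(seq: str, role: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{role} sequence is empty")
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"{role} sequence contains non-amino-acid character {exc.args[0]!r}"
        ) from None


def global_align(a: str, b: str, query_id: str = "query", target_id: str = "target",
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Returns an :class:`AlignmentResult`; statistics are symmetric in the
    two inputs (the pair is canonically ordered internally).
    """
    ea = _encode(a, "query")
    eb = _encode(b, "target")
    swapped = (len(a), a) < (len(b), b)
    s1, s2 = (b, a) if swapped else (a, b)
    e1, e2 = (eb, ea) if swapped else (ea, eb)
    score, ops = _gotoh(e1, e2, BLOSUM62_X0, float(gap_open), float(gap_extend))
    row1, row2 = [], []
    i = j = 0
    n_ident = 0
    for op in ops:
        if op == 0:
            row1.append(s1[i])
            row2.append(s2[j])
            n_ident += s1[i] == s2[j]
            i += 1
            j += 1
        elif op == 1:
            row1.append(s1[i])
            row2.append("-")
            i += 1
        else:
            row1.append("-")
            row2.append(s2[j])
            j += 1
    L_al = len(ops)
    gap_columns = int(np.count_nonzero(ops))
    L_long = max(len(a), len(b))
    aligned1, aligned2 = "".join(row1), "".join(row2)
    if swapped:
        aligned1, aligned2 = aligned2, aligned1
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        score=float(score),
        L_al=L_al,
        gap_columns=gap_columns,
        n_identical=n_ident,
        identity=n_ident / L_al,
        coverage=coverage_index(L_al, gap_columns, L_long),
        L_long=L_long,
        aligned_query=aligned1,
        aligned_target=aligned2,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Global identity on the shorter sequence: identical columns of the
    optimal global alignment divided by min(len(a), len(b)).  Used for
    CD-HIT-style redundancy reduction."""
    res = global_align(a, b)
    return res.n_identical / min(len(a), len(b))
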