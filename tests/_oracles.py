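"""Independent brute-force oracles used by the test suite.

Deliberately simple formulations, kept separate from the package's
implementations: a memoized suffix recursion for affine-gap global
alignment (vs. the iterative Gotoh matrices in bgcnet.align), and
helpers for random additive trees.
"""

from __future__ import annotations

from functools import lru_cache

from bgcnet.align import ALPHABET, BLOSUM62_X0, DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN

_IDX = {c: i for i, c in enumerate(ALPHABET)}


def affine_align_oracle(a: str, b: str,
                        gap_open: float = DEFAULT_GAP_OPEN,
                        gap_ext: float = DEFAULT_GAP_EXTEND):
    """Optimal affine-gap global alignment by memoized suffix recursion.

    Returns (score, stats) where stats is the set of
    (n_identical, gap_columns) pairs realized by *optimal* alignments.
    State: (i, j, g) = suffixes a[i:], b[j:] with g the gap state of the
    previous column (0 none/diagonal, 1 gap in b, 2 gap in a).
    """
    n, m = len(a), len(b)
    open_cost = gap_open + gap_ext

    @lru_cache(maxsize=None)
    def best(i: int, j: int, g: int) -> float:
        if i == n and j == m:
            return 0.0
        cands = []
        if i < n and j < m:
            cands.append(BLOSUM62_X0[_IDX[a[i]], _IDX[b[j]]] + best(i + 1, j + 1, 0))
        if i < n:
            cands.append(-(gap_ext if g == 1 else open_cost) + best(i + 1, j, 1))
        if j < m:
            cands.append(-(gap_ext if g == 2 else open_cost) + best(i, j + 1, 2))
        return max(cands)

    @lru_cache(maxsize=None)
    def stats(i: int, j: int, g: int) -> frozenset:
        if i == n and j == m:
            return frozenset({(0, 0)})
        target = best(i, j, g)
        out = set()
        if i < n and j < m:
            move = BLOSUM62_X0[_IDX[a[i]], _IDX[b[j]]]
            if abs(move + best(i + 1, j + 1, 0) - target) < 1e-9:
                ident = int(a[i] == b[j])
                out |= {(ni + ident, ng) for ni, ng in stats(i + 1, j + 1, 0)}
        if i < n:
            move = -(gap_ext if g == 1 else open_cost)
            if abs(move + best(i + 1, j, 1) - target) < 1e-9:
                out |= {(ni, ng + 1) for ni, ng in stats(i + 1, j, 1)}
        if j < m:
            move = -(gap_ext if g == 2 else open_cost)
            if abs(move + best(i, j + 1, 2) - target) < 1e-9:
                out |= {(ni, ng + 1) for ni, ng in stats(i, j + 1, 2)}
        return frozenset(out)

    score = best(0, 0, 0)
    result = (float(score), set(stats(0, 0, 0)))
    best.cache_clear()
    stats.cache_clear()
    return result


def random_additive_tree(rng, n_taxa: int, min_len: float = 0.2,
                         max_len: float = 1.0) -> str:
    """Random binary tree over taxa T0..T{n-1} as a Newick string, with
    branch lengths uniform on [min_len, max_len] (so the leaf-to-leaf
    distance matrix is strictly additive)."""
    nodes = [f"T{i}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(min_len, max_len, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    la, lb = rng.uniform(min_len, max_len, size=2)
    return f"({nodes[0]}:{la:.6f},{nodes[1]}:{lb:.6f});"
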