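"""Phylogeny workflow for enzymatic-domain and 16S rRNA sequences.

The pipeline mirrors the standard comparative workflow: CD-HIT-style
greedy redundancy reduction at 95% identity, progressive multiple
alignment (3-mer distances -> neighbor-joining guide tree ->
profile–profile Needleman–Wunsch merges), gap-fraction column trimming,
closed-form evolutionary distances (p, Jukes–Cantor, Kimura
2-parameter for nucleotides; Poisson correction for proteins),
Saitou–Nei neighbor joining, nonparametric bootstrap supports, and
query-subtree extraction.

Trees are ``dendropy.Tree`` objects (unrooted, branch lengths in
substitutions/site, bootstrap supports as internal node labels),
serialized as Newick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from numba import njit

from .align import ALPHABET as AA_SYMBOLS
from .align import BLOSUM62_X0, pairwise_identity

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class SequenceSet:
    """Ordered (id, sequence) pairs with a declared alphabet."""

    entries: list[tuple[str, str]]
    alphabet: str = "aa"  # "aa" or "nt"

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        if any(not s for _, s in self.entries):
            raise ValueError("empty sequence in set")


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows; ungapping a row recovers its input."""

    rows: list[tuple[str, str]]
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, row_id: str) -> str:
        for i, s in self.rows:
            if i == row_id:
                return s.replace(GAP, "")
        raise KeyError(row_id)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and nonnegative")


# ---------------------------------------------------------------------------
# redundancy reduction

def reduce_redundancy(seqs: SequenceSet, threshold: float = 0.95
                      ) -> tuple[SequenceSet, dict[str, str]]:
    """Greedy incremental clustering at a global-identity threshold.

    Sequences are processed longest-first; each joins the first existing
    representative to which its global identity (identical columns /
    shorter length) is >= ``threshold``, else founds a new cluster.
    Returns the representatives (in founding order) and the
    id -> representative-id membership map.
    """
    order = sorted(seqs.entries, key=lambda e: (-len(e[1]), e[0]))
    reps: list[tuple[str, str]] = []
    membership: dict[str, str] = {}
    for sid, seq in order:
        for rid, rseq in reps:
            if pairwise_identity(seq, rseq) >= threshold:
                membership[sid] = rid
                break
        else:
            reps.append((sid, seq))
            membership[sid] = sid
    return SequenceSet(entries=reps, alphabet=seqs.alphabet), membership


# ---------------------------------------------------------------------------
# progressive MSA

_NT_SYMBOLS = "ACGTN"


def _symbols_and_matrix(alphabet: str) -> tuple[str, np.ndarray]:
    if alphabet == "aa":
        syms = AA_SYMBOLS
        core = BLOSUM62_X0
    elif alphabet == "nt":
        syms = _NT_SYMBOLS
        core = np.full((5, 5), -4.0)
        np.fill_diagonal(core, 5.0)
        core[4, :] = core[:, 4] = 0.0  # N neutral
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    n = len(syms)
    ext = np.zeros((n + 1, n + 1))  # last symbol = gap
    ext[:n, :n] = core
    ext[n, :n] = ext[:n, n] = -4.0  # residue vs existing gap
    return syms, ext


@njit(cache=True)
def _nw_profile(S: np.ndarray, gap: float):
    """Linear-gap NW over a precomputed column-score matrix; tie-break
    diagonal > up > left.  Returns ops: 0 diag, 1 up, 2 left."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), np.int8)
    for i in range(1, n + 1):
        H[i, 0] = -gap * i
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = -gap * j
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + S[i - 1, j - 1]
            arg = 0
            up = H[i - 1, j] - gap
            if up > best:
                best, arg = up, 1
            left = H[i, j - 1] - gap
            if left > best:
                best, arg = left, 2
            H[i, j], P[i, j] = best, arg
    ops = np.empty(n + m, np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i, j]
        ops[k] = p
        if p == 0:
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
        k += 1
    return ops[:k][::-1].copy()


def _profile_freq(rows: list[str], syms: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(syms)}
    gap_i = len(syms)
    L = len(rows[0])
    F = np.zeros((L, gap_i + 1))
    for row in rows:
        for pos, c in enumerate(row):
            F[pos, gap_i if c == GAP else idx[c]] += 1.0
    return F / len(rows)


def _merge_profiles(a: list[tuple[str, str]], b: list[tuple[str, str]],
                    syms: str, smat: np.ndarray, gap_pen: float
                    ) -> list[tuple[str, str]]:
    Fa = _profile_freq([s for _, s in a], syms)
    Fb = _profile_freq([s for _, s in b], syms)
    S = Fa @ smat @ Fb.T
    ops = _nw_profile(S, gap_pen)
    ga = GAP
    out_a = ["" for _ in a]
    out_b = ["" for _ in b]
    i = j = 0
    cols_a, cols_b = [], []
    for op in ops:
        cols_a.append(i if op != 2 else -1)
        cols_b.append(j if op != 1 else -1)
        if op != 2:
            i += 1
        if op != 1:
            j += 1
    for r, (_, s) in enumerate(a):
        out_a[r] = "".join(s[c] if c >= 0 else ga for c in cols_a)
    for r, (_, s) in enumerate(b):
        out_b[r] = "".join(s[c] if c >= 0 else ga for c in cols_b)
    return [(a[r][0], out_a[r]) for r in range(len(a))] + \
           [(b[r][0], out_b[r]) for r in range(len(b))]


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    from collections import Counter
    counters = [Counter(s[i:i + k] for i in range(max(len(s) - k + 1, 0)))
                for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = max(min(sum(counters[i].values()), sum(counters[j].values())), 1)
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return d


def progressive_msa(seqs: SequenceSet, gap_penalty: float = 8.0) -> MultipleAlignment:
    """Progressive multiple alignment.

    Guide order comes from neighbor joining on pairwise 3-mer distances;
    profiles are merged with sum-of-pairs profile–profile
    Needleman–Wunsch (linear gap penalty).  Deterministic for a fixed
    input order; the output rows keep the input order.
    """
    entries = seqs.entries
    if len(entries) == 1:
        return MultipleAlignment(rows=list(entries), alphabet=seqs.alphabet)
    syms, smat = _symbols_and_matrix(seqs.alphabet)
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [e] for i, e in enumerate(entries)}
    if len(entries) == 2:
        agenda = [(0, 1)]
    else:
        d = _kmer_distance([s for _, s in entries])
        joins, final = _nj_core(d)
        agenda = [(i, j) for i, j, _, _, _ in joins]
        agenda += [(final[0], final[1]), (len(entries) + len(joins), final[2])]
    next_id = len(entries)
    for i, j in agenda:
        profiles[next_id] = _merge_profiles(profiles.pop(i), profiles.pop(j),
                                            syms, smat, gap_penalty)
        next_id += 1
    merged = profiles.popitem()[1]
    order = {sid: pos for pos, (sid, _) in enumerate(entries)}
    merged.sort(key=lambda r: order[r[0]])
    return MultipleAlignment(rows=merged, alphabet=seqs.alphabet)


# ---------------------------------------------------------------------------
# column trimming

def trim_columns(aln: MultipleAlignment, max_gap_fraction: float = 0.5
                 ) -> tuple[MultipleAlignment, list[int]]:
    """Keep, in order, columns whose gap fraction is <= the threshold.
    Returns the trimmed alignment and the retained column indices."""
    n_rows = len(aln.rows)
    keep = [c for c in range(aln.n_columns)
            if sum(s[c] == GAP for _, s in aln.rows) / n_rows <= max_gap_fraction]
    if not keep:
        raise ValueError(
            "no columns survive trimming; raise max_gap_fraction")
    rows = [(i, "".join(s[c] for c in keep)) for i, s in aln.rows]
    return MultipleAlignment(rows=rows, alphabet=aln.alphabet), keep


def trim_to_shared_span(aln: MultipleAlignment) -> MultipleAlignment:
    """Trim to equal informative length: drop columns covered by any
    row's leading or trailing terminal gap run (the usual preparation of
    16S alignments before distance computation)."""
    starts, ends = [], []
    for _, s in aln.rows:
        stripped = s.strip(GAP)
        first = len(s) - len(s.lstrip(GAP))
        starts.append(first)
        ends.append(first + len(stripped) - 1)
    lo, hi = max(starts), min(ends)
    if lo > hi:
        raise ValueError("rows share no common aligned span")
    rows = [(i, s[lo:hi + 1]) for i, s in aln.rows]
    return MultipleAlignment(rows=rows, alphabet=aln.alphabet)


# ---------------------------------------------------------------------------
# distances

MODELS = ("p", "JC", "K2P", "poisson")
_PURINES = {"A", "G"}


def _pair_stats(s1: str, s2: str) -> tuple[int, int, int]:
    """(comparable columns, differences, transitions) over columns where
    both rows are ungapped."""
    n = diff = ts = 0
    for a, b in zip(s1, s2):
        if a == GAP or b == GAP:
            continue
        n += 1
        if a != b:
            diff += 1
            if (a in _PURINES) == (b in _PURINES):
                ts += 1
    return n, diff, ts


def _model_distance(model: str, n: int, diff: int, ts: int) -> float:
    p = diff / n
    if model == "p":
        return p
    if model == "JC":
        arg = 1.0 - 4.0 * p / 3.0
        return math.inf if arg <= 0 else -0.75 * math.log(arg)
    if model == "poisson":
        arg = 1.0 - p
        return math.inf if arg <= 0 else -math.log(arg)
    if model == "K2P":
        P = ts / n
        Q = p - P
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return math.inf
        return -0.5 * math.log(a1) - 0.25 * math.log(a2)
    raise ValueError(f"unknown model {model!r} (expected one of {MODELS})")


def pairwise_distance(aln: MultipleAlignment, model: str = "p",
                      max_distance: float = 10.0) -> DistanceMatrix:
    """Pairwise evolutionary distances over shared (both-ungapped)
    columns.  "p" and "JC"/"K2P" are nucleotide models; "poisson"
    (-ln(1-p)) is the protein correction.  Saturated pairs are capped at
    ``max_distance`` and flagged."""
    if model in ("JC", "K2P") and aln.alphabet != "nt":
        raise ValueError(f"model {model} requires a nucleotide alignment")
    ids = [i for i, _ in aln.rows]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 rows")
    d = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            cols, diff, ts = _pair_stats(aln.rows[i][1], aln.rows[j][1])
            if cols == 0:
                raise ValueError(
                    f"rows {ids[i]} and {ids[j]} share no comparable columns")
            dist = _model_distance(model, cols, diff, ts)
            if dist > max_distance:
                logger.warning("distance %s-%s saturated; capped at %g",
                               ids[i], ids[j], max_distance)
                saturated.add((ids[i], ids[j]))
                dist = max_distance
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d, saturated=saturated)


# ---------------------------------------------------------------------------
# neighbor joining

def _nj_core(dist: np.ndarray):
    """Saitou–Nei agglomeration on a copy of ``dist``.

    Returns (joins, final): joins is a list of
    (node_i, node_j, length_i, length_j, new_node_id) with leaf ids
    0..n-1 and internal ids counting upward; final is
    (node_x, node_y, node_z, lx, ly, lz) for the last three nodes around
    the central vertex.  Ties on the Q criterion break on the lowest
    (i, j) position pair.  Negative branch lengths are clamped to zero.
    """
    n = dist.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    active = list(range(n))
    D = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n)}
    next_id = n
    joins = []

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else D[(i, j)] if (i, j) in D else D[(j, i)]

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.debug("negative branch length %g at %s clamped to 0", x, what)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active) for a in active}
        best = None
        best_q = math.inf
        for pi in range(m):
            for pj in range(pi + 1, m):
                a, b = active[pi], active[pj]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (pi, pj)
        pi, pj = best
        a, b = active[pi], active[pj]
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = clamp(la, f"join({a},{b})"), clamp(lb, f"join({a},{b})")
        u = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            D[(u, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        joins.append((a, b, la, lb, u))
        active = [c for c in active if c not in (a, b)] + [u]

    x, y, z = active
    lx = clamp(0.5 * (get(x, y) + get(x, z) - get(y, z)), "final")
    ly = clamp(0.5 * (get(x, y) + get(y, z) - get(x, z)), "final")
    lz = clamp(0.5 * (get(x, z) + get(y, z) - get(x, y)), "final")
    return joins, (x, y, z, lx, ly, lz)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; three children at the seed
    vertex) with branch lengths, as a ``dendropy.Tree``."""
    joins, final = _nj_core(dm.d)
    ns = dendropy.TaxonNamespace(dm.ids)
    nodes: dict[int, dendropy.Node] = {}
    for i, taxon_label in enumerate(dm.ids):
        node = dendropy.Node(taxon=ns.get_taxon(taxon_label))
        nodes[i] = node
    for a, b, la, lb, u in joins:
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        nodes[u] = parent
    x, y, z, lx, ly, lz = final
    center = dendropy.Node()
    for child, ln in ((x, lx), (y, ly), (z, lz)):
        center.add_child(nodes[child])
        nodes[child].edge.length = ln
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, subtree extraction

def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf-label sets (the side
    not containing the lexicographically smallest leaf)."""
    all_leaves = _leaf_labels(tree)
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 2 <= len(side) <= len(all_leaves) - 2:
            if anchor in side:
                side = all_leaves - side
            out.add(frozenset(side))
    return out


def bootstrap_support(aln: MultipleAlignment, model: str = "p",
                      n_reps: int = 1000, seed: int = 0,
                      max_distance: float = 10.0) -> dendropy.Tree:
    """Full-data NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement (seeded); each replicate is
    re-distanced and re-joined, and the support of every internal edge
    of the full-data tree is the fraction of replicates whose tree
    contains the same bipartition.  Supports are written as internal
    node labels (3 decimals).  Replicates whose resample leaves some
    pair with no comparable columns are skipped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full_dm = pairwise_distance(aln, model, max_distance)
    tree = nj_tree(full_dm)
    target = bipartitions(tree)
    if not target:
        return tree
    rng = np.random.default_rng(seed)
    counts = {bp: 0 for bp in target}
    n_ok = 0
    ncol = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, ncol)
        rows = [(i, "".join(s[c] for c in cols)) for i, s in aln.rows]
        rep_aln = MultipleAlignment(rows=rows, alphabet=aln.alphabet)
        try:
            rep_tree = nj_tree(pairwise_distance(rep_aln, model, max_distance))
        except ValueError:
            continue
        n_ok += 1
        rep_bps = bipartitions(rep_tree)
        for bp in target & rep_bps:
            counts[bp] += 1
    denom = max(n_ok, 1)
    all_leaves = _leaf_labels(tree)
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = frozenset(all_leaves - side if anchor in side else side)
            node.label = f"{counts[key] / denom:.3f}"
    return tree


def _subtree_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        name = node.taxon.label.replace(" ", "_")
        ln = node.edge.length
        return name if ln is None else f"{name}:{ln:.6f}"
    inner = ",".join(_subtree_newick(c) for c in node.child_nodes())
    label = node.label or ""
    ln = node.edge.length
    suffix = "" if ln is None else f":{ln:.6f}"
    return f"({inner}){label}{suffix}"


def extract_subtree(tree: dendropy.Tree, query_ids: set[str]) -> dendropy.Tree:
    """Minimal spanning subtree containing the query leaves: the clade
    under their most recent common ancestor (non-query leaves falling
    inside that clade are retained).  Branch lengths and supports are
    preserved."""
    if not query_ids:
        raise ValueError("query_ids is empty")
    leaves = _leaf_labels(tree)
    missing = sorted(set(query_ids) - leaves)
    if missing:
        raise ValueError(f"query ids not in tree: {missing}")
    if len(query_ids) == 1:
        (qid,) = query_ids
        return dendropy.Tree.get(data=f"{qid.replace(' ', '_')};",
                                 schema="newick")
    import warnings
    with warnings.catch_warnings():
        # the unrooted tree is deliberately read as rooted at its seed here
        warnings.simplefilter("ignore", UserWarning)
        mrca = tree.mrca(taxon_labels=sorted(query_ids))
    if mrca.is_leaf():  # all queries identical label set pathologies
        mrca = mrca.parent_node
    inner = ",".join(_subtree_newick(c) for c in mrca.child_nodes())
    sub = dendropy.Tree.get(data=f"({inner}){mrca.label or ''};", schema="newick",
                            suppress_internal_node_taxa=True)
    sub.is_rooted = False
    return sub


# ---------------------------------------------------------------------------
# Newick I/O

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(Path(path)), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".6f")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(Path(path)), schema="newick",
                             suppress_internal_node_taxa=True)


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Leaf-to-leaf path length (sum of branch lengths)."""
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.patristic_distance(ta, tb)
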