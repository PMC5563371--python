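"""Redundancy reduction, progressive MSA, distances, neighbor joining,
bootstrap, and subtree extraction."""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pytest

from _oracles import random_additive_tree
from bgcnet.align import global_align
from bgcnet.phylo import (
    DistanceMatrix,
    MultipleAlignment,
    SequenceSet,
    bipartitions,
    bootstrap_support,
    extract_subtree,
    nj_tree,
    pairwise_distance,
    patristic_distance,
    progressive_msa,
    read_newick,
    reduce_redundancy,
    trim_columns,
    trim_to_shared_span,
    write_newick,
    _model_distance,
)
from bgcnet.simulate import evolve_along_tree, mutate_protein, random_protein


def tree_from_newick(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick",
                             suppress_internal_node_taxa=True)


def leaf_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    ids = sorted(l.taxon.label for l in tree.leaf_node_iter())
    n = len(ids)
    d = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i in range(n):
        for j in range(i + 1, n):
            ta = tree.taxon_namespace.get_taxon(ids[i])
            tb = tree.taxon_namespace.get_taxon(ids[j])
            d[i, j] = d[j, i] = pdm.patristic_distance(ta, tb)
    return DistanceMatrix(ids=ids, d=d)


class TestReduceRedundancy:
    def test_identical_pair_collapses(self):
        seqs = SequenceSet(entries=[("a", "MKLVMKLV"), ("b", "MKLVMKLV")])
        reps, membership = reduce_redundancy(seqs)
        assert len(reps.entries) == 1
        assert membership["a"] == membership["b"]

    def test_dissimilar_set_all_representatives(self, rng):
        entries = [(f"s{i}", random_protein(rng, 60)) for i in range(5)]
        reps, membership = reduce_redundancy(SequenceSet(entries=entries))
        assert len(reps.entries) == 5
        assert all(membership[i] == i for i, _ in entries)

    def test_members_within_threshold_of_representative(self, rng):
        """Post-hoc oracle: every member is >= 95% identical (on the
        shorter length) to its assigned representative."""
        base = [random_protein(rng, 80) for _ in range(3)]
        entries = []
        for bi, b in enumerate(base):
            entries.append((f"b{bi}", b))
            for k in range(2):
                entries.append((f"b{bi}m{k}", mutate_protein(b, 0.98, rng)))
        reps, membership = reduce_redundancy(SequenceSet(entries=entries), 0.95)
        lookup = dict(entries)
        for sid, rid in membership.items():
            if sid == rid:
                continue
            res = global_align(lookup[sid], lookup[rid])
            ident = res.n_identical / min(len(lookup[sid]), len(lookup[rid]))
            assert ident >= 0.95


class TestProgressiveMSA:
    def test_identical_pair_gapless(self):
        aln = progressive_msa(SequenceSet(entries=[("a", "MKLV"), ("b", "MKLV")]))
        assert [s for _, s in aln.rows] == ["MKLV", "MKLV"]

    def test_single_sequence_trivial(self):
        aln = progressive_msa(SequenceSet(entries=[("a", "MKLV")]))
        assert aln.rows == [("a", "MKLV")]

    def test_ungapping_recovers_inputs(self, rng):
        entries = [(f"s{i}", random_protein(rng, int(rng.integers(30, 60))))
                   for i in range(6)]
        aln = progressive_msa(SequenceSet(entries=entries))
        assert len({len(s) for _, s in aln.rows}) == 1
        for sid, seq in entries:
            assert aln.ungapped(sid) == seq
        assert [i for i, _ in aln.rows] == [i for i, _ in entries]

    def test_pairwise_alignment_is_optimal(self, rng):
        """For two sequences the profile merge degenerates to plain NW;
        its realized score must equal the brute-force optimum under the
        same linear-gap scoring."""
        from functools import lru_cache
        from bgcnet.align import ALPHABET, BLOSUM62_X0
        idx = {c: i for i, c in enumerate(ALPHABET)}
        gap = 8.0

        def oracle(a, b):
            @lru_cache(maxsize=None)
            def f(i, j):
                if i == len(a) and j == len(b):
                    return 0.0
                out = -math.inf
                if i < len(a) and j < len(b):
                    out = max(out, BLOSUM62_X0[idx[a[i]], idx[b[j]]] + f(i + 1, j + 1))
                if i < len(a):
                    out = max(out, -gap + f(i + 1, j))
                if j < len(b):
                    out = max(out, -gap + f(i, j + 1))
                return out
            return f(0, 0)

        def realized(row_a, row_b):
            score = 0.0
            for ca, cb in zip(row_a, row_b):
                if ca == "-" or cb == "-":
                    score -= gap
                else:
                    score += BLOSUM62_X0[idx[ca], idx[cb]]
            return score

        for _ in range(10):
            a = random_protein(rng, int(rng.integers(5, 14)))
            b = random_protein(rng, int(rng.integers(5, 14)))
            aln = progressive_msa(SequenceSet(entries=[("a", a), ("b", b)]))
            rows = dict(aln.rows)
            assert realized(rows["a"], rows["b"]) == pytest.approx(oracle(a, b))


class TestTrimColumns:
    def test_gapless_alignment_unchanged(self):
        aln = MultipleAlignment(rows=[("a", "MKLV"), ("b", "MKIV")])
        trimmed, kept = trim_columns(aln)
        assert trimmed.rows == aln.rows and kept == [0, 1, 2, 3]

    def test_majority_gap_column_removed(self):
        rows = [("a", "M-KL"), ("b", "M-KL"), ("c", "M-KL"), ("d", "MAKL")]
        trimmed, kept = trim_columns(MultipleAlignment(rows=rows), 0.5)
        assert kept == [0, 2, 3]
        assert trimmed.ungapped("a") == "MKL"

    def test_matches_column_scan_oracle(self, rng):
        rows = []
        for r in range(5):
            rows.append((f"s{r}", "".join(
                "-" if rng.random() < 0.3 else "A" for _ in range(40))))
        aln = MultipleAlignment(rows=rows)
        trimmed, kept = trim_columns(aln, 0.4)
        expect = [c for c in range(40)
                  if sum(s[c] == "-" for _, s in rows) / 5 <= 0.4]
        assert kept == expect and trimmed.n_columns == len(expect)

    def test_all_columns_removed_is_an_error(self):
        aln = MultipleAlignment(rows=[("a", "--"), ("b", "AA")])
        with pytest.raises(ValueError, match="max_gap_fraction"):
            trim_columns(aln, 0.0)

    def test_terminal_gap_trimming_equalizes_span(self):
        rows = [("a", "--ACGTACGT"), ("b", "CCACGTAC--"), ("c", "GGACGTACGT")]
        trimmed = trim_to_shared_span(MultipleAlignment(rows=rows, alphabet="nt"))
        assert trimmed.n_columns == 6
        assert all(("-" not in s[:1] and "-" not in s[-1:]) for _, s in trimmed.rows)


class TestPairwiseDistance:
    def test_identical_rows_zero_under_every_model(self):
        aln = MultipleAlignment(rows=[("a", "ACGTACGT"), ("b", "ACGTACGT")],
                                alphabet="nt")
        for model in ("p", "JC", "K2P"):
            assert pairwise_distance(aln, model).d[0, 1] == 0.0

    def test_p_distance(self):
        aln = MultipleAlignment(rows=[("a", "AAAA"), ("b", "AAAT")], alphabet="nt")
        assert pairwise_distance(aln, "p").d[0, 1] == pytest.approx(0.25)

    def test_jc_closed_form(self):
        # p = 0.25 -> -(3/4) ln(2/3) = 0.304099
        assert _model_distance("JC", 4, 1, 0) == pytest.approx(0.3040988, abs=1e-6)

    def test_k2p_reduces_to_jc_under_even_changes(self):
        # with P = Q/2 structure K2P and JC differ; sanity: K2P >= 0, symmetric matrix
        aln = MultipleAlignment(rows=[("a", "AAAAGGGGCC"), ("b", "GAAAAGGGCC")],
                                alphabet="nt")
        dm = pairwise_distance(aln, "K2P")
        assert dm.d[0, 1] == dm.d[1, 0] > 0

    def test_gapped_columns_excluded(self):
        aln = MultipleAlignment(rows=[("a", "A-CG"), ("b", "ATCG")], alphabet="nt")
        assert pairwise_distance(aln, "p").d[0, 1] == 0.0

    def test_saturation_capped_and_flagged(self):
        aln = MultipleAlignment(rows=[("a", "AAAA"), ("b", "TTTT")], alphabet="nt")
        dm = pairwise_distance(aln, "JC", max_distance=5.0)
        assert dm.d[0, 1] == 5.0 and ("a", "b") in dm.saturated

    def test_no_comparable_columns_is_an_error(self):
        aln = MultipleAlignment(rows=[("a", "A--"), ("b", "--T")], alphabet="nt")
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance(aln, "p")

    def test_protein_models_guarded(self):
        aln = MultipleAlignment(rows=[("a", "MK"), ("b", "MV")], alphabet="aa")
        with pytest.raises(ValueError, match="nucleotide"):
            pairwise_distance(aln, "JC")
        assert pairwise_distance(aln, "poisson").d[0, 1] == pytest.approx(-math.log(0.5))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(ids=["A", "B", "C"], d=d))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 3.0, "B": 2.0, "C": 6.0})

    def test_recovers_random_additive_trees_exactly(self, rng):
        """Topology and all leaf-to-leaf path lengths of random 4-7
        taxon trees are reconstructed to 1e-9 from their additive
        distance matrices."""
        for _ in range(100):
            n = int(rng.integers(4, 8))
            true = tree_from_newick(random_additive_tree(rng, n))
            dm = leaf_distance_matrix(true)
            est = nj_tree(dm)
            assert bipartitions(est) == bipartitions(true)
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1:]:
                    assert patristic_distance(est, a, b) == pytest.approx(
                        dm.d[dm.ids.index(a), dm.ids.index(b)], abs=1e-9)

    def test_agrees_with_scikit_bio(self, rng):
        """Independent oracle: same topology as skbio's neighbor joining
        on a random (noisy, non-additive) matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        n = 6
        ids = [f"T{i}" for i in range(n)]
        base = tree_from_newick(random_additive_tree(rng, n))
        d = leaf_distance_matrix(base).d
        noise = rng.uniform(0, 0.02, size=(n, n))
        d = d + (noise + noise.T) / 2
        np.fill_diagonal(d, 0)
        mine = nj_tree(DistanceMatrix(ids=ids, d=d))
        theirs = skbio_nj(SkbioDM(d, ids))
        import io as _io
        buf = _io.StringIO()
        theirs.write(buf, format="newick")
        theirs_dp = tree_from_newick(buf.getvalue())
        assert bipartitions(mine) == bipartitions(theirs_dp)

    def test_too_few_taxa_rejected(self):
        d = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(ids=["a", "b"], d=d))

    def test_deterministic(self, rng):
        true = tree_from_newick(random_additive_tree(rng, 6))
        dm = leaf_distance_matrix(true)
        n1 = nj_tree(dm).as_string(schema="newick")
        n2 = nj_tree(dm).as_string(schema="newick")
        assert n1 == n2


def two_clade_alignment(n_per_clade=4, n_cols=120, seed=5) -> MultipleAlignment:
    """Synthetic nucleotide alignment with a clean split: clade A and
    clade B differ at a third of the columns, members within a clade
    carry only private noise."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=n_cols)
    other = base.copy()
    third = rng.choice(n_cols, size=n_cols // 3, replace=False)
    for c in third:
        other[c] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[c]]
    rows = []
    for k in range(n_per_clade):
        for name, tpl in (("A", base), ("B", other)):
            row = tpl.copy()
            for c in rng.choice(n_cols, size=2, replace=False):
                row[c] = rng.choice(list("ACGT"))
            rows.append((f"{name}{k}", "".join(row)))
    return MultipleAlignment(rows=sorted(rows), alphabet="nt")


class TestBootstrap:
    def test_separating_bipartition_strongly_supported(self):
        aln = two_clade_alignment()
        tree = bootstrap_support(aln, model="p", n_reps=200, seed=7)
        split = frozenset(n for n, _ in aln.rows if n.startswith("B"))
        supports = {}
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        anchor = min(leaves)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf() or node.label is None:
                continue
            side = {l.taxon.label for l in node.leaf_iter()}
            key = frozenset(leaves - side if anchor in side else side)
            supports[key] = float(node.label)
        assert supports[split] >= 0.95

    def test_single_replicate_supports_binary(self):
        aln = two_clade_alignment()
        tree = bootstrap_support(aln, model="p", n_reps=1, seed=3)
        vals = [float(n.label) for n in tree.preorder_node_iter()
                if n.label is not None]
        assert vals and set(vals) <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self):
        aln = two_clade_alignment()
        t1 = bootstrap_support(aln, n_reps=50, seed=11).as_string(schema="newick")
        t2 = bootstrap_support(aln, n_reps=50, seed=11).as_string(schema="newick")
        assert t1 == t2

    def test_supports_in_unit_interval(self):
        aln = two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=30, seed=1)
        for node in tree.preorder_node_iter():
            if node.label is not None:
                assert 0.0 <= float(node.label) <= 1.0


class TestExtractSubtree:
    def test_all_leaves_returns_same_topology(self, rng):
        tree = tree_from_newick(random_additive_tree(rng, 6))
        sub = extract_subtree(tree, {f"T{i}" for i in range(6)})
        assert bipartitions(sub) == bipartitions(tree)

    def test_single_leaf(self, rng):
        tree = tree_from_newick(random_additive_tree(rng, 5))
        sub = extract_subtree(tree, {"T2"})
        assert [l.taxon.label for l in sub.leaf_node_iter()] == ["T2"]

    def test_unknown_ids_listed(self, rng):
        tree = tree_from_newick(random_additive_tree(rng, 5))
        with pytest.raises(ValueError, match="T9"):
            extract_subtree(tree, {"T1", "T9"})

    def test_path_lengths_preserved(self, rng):
        """On random 8-leaf trees, query-to-query path lengths in the
        extracted subtree equal those in the full tree."""
        for _ in range(10):
            tree = tree_from_newick(random_additive_tree(rng, 8))
            queries = sorted(rng.choice([f"T{i}" for i in range(8)], size=3,
                                        replace=False))
            sub = extract_subtree(tree, set(queries))
            for i, a in enumerate(queries):
                for b in queries[i + 1:]:
                    assert patristic_distance(sub, a, b) == pytest.approx(
                        patristic_distance(tree, a, b), abs=1e-6)


class TestNewickRoundTrip:
    def test_lengths_preserved_to_6_decimals(self, rng, tmp_path):
        true = tree_from_newick(random_additive_tree(rng, 7))
        path = tmp_path / "t.nwk"
        write_newick(true, path)
        back = read_newick(path)
        assert bipartitions(back) == bipartitions(true)
        for i in range(7):
            for j in range(i + 1, 7):
                a, b = f"T{i}", f"T{j}"
                assert patristic_distance(back, a, b) == pytest.approx(
                    patristic_distance(true, a, b), abs=1e-5)


def test_16s_pipeline_recovers_known_topology():
    """End to end: sequences evolved along a known tree -> MSA -> shared
    span trimming -> JC distances -> NJ recovers the generating
    topology."""
    true = tree_from_newick(
        "((A:0.02,B:0.02):0.10,(C:0.02,D:0.02):0.10,(E:0.02,F:0.02):0.10);")
    leaves = evolve_along_tree(true, length=800, seed=9, alphabet="nt")
    aln = progressive_msa(SequenceSet(entries=sorted(leaves), alphabet="nt"))
    aln = trim_to_shared_span(aln)
    dm = pairwise_distance(aln, "JC")
    est = nj_tree(dm)
    assert bipartitions(est) == bipartitions(true)
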