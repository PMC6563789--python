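"""JC distances, NJ reconstruction, bootstrap, clade purity."""

import itertools
import math

import numpy as np
import pytest

from sptrf.elements import MosaicAlignment
from sptrf.errors import ContractError, SaturationError
from sptrf.io import SequenceRecord
from sptrf.phylogeny import (DistanceMatrix, PhyloTree, bootstrap_support,
                             clade_purity, jc_distance, jc_matrix, nj_tree)


def make_aln(rows, ids=None):
    ids = ids or [f"t{i}" for i in range(len(rows))]
    recs = [SequenceRecord(i, r, aligned=True) for i, r in zip(ids, rows)]
    return MosaicAlignment(recs, list(rows))


def enumerate_topologies(taxa):
    """All unrooted binary tree shapes on the given taxa, as adjacency dicts
    (nodes are ints; leaves 0..n-1 map to taxa in order)."""
    n = len(taxa)
    base = {0: {100: None}, 1: {100: None}, 2: {100: None},
            100: {0: None, 1: None, 2: None}}  # internal ids start at 100
    trees = [base]
    for next_leaf in range(3, n):
        grown = []
        for adj in trees:
            edges = {frozenset((u, v)) for u in adj for v in adj[u]}
            for e in edges:
                u, v = tuple(e)
                new = {k: dict(d) for k, d in adj.items()}
                mid = max(new) + 1
                leaf = next_leaf
                del new[u][v]
                del new[v][u]
                new[mid] = {u: None, v: None, leaf: None}
                new[u][mid] = None
                new[v][mid] = None
                new.setdefault(leaf, {})[mid] = None
                grown.append(new)
        trees = grown
    return trees


def with_lengths(adj, rng):
    lengths = {}
    for u in adj:
        for v in adj[u]:
            e = frozenset((u, v))
            if e not in lengths:
                lengths[e] = float(rng.uniform(0.05, 0.4))
    out = {u: {v: lengths[frozenset((u, v))] for v in adj[u]} for u in adj}
    return out


def tree_from_adj(adj, taxa):
    leaves = {i: taxa[i] for i in range(len(taxa))}
    return PhyloTree(adj, leaves)


class TestJcDistance:
    def test_identical_rows_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_quarter_mismatch_closed_form(self):
        d = jc_distance("AAAA", "AAAT")
        assert d == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-9)

    def test_matches_direct_formula_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT-"), size=120, p=[.23, .23, .23, .23, .08]))
            b = "".join(rng.choice(list("ACGT-"), size=120, p=[.23, .23, .23, .23, .08]))
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            p = sum(x != y for x, y in shared) / len(shared)
            if p >= 0.75:
                with pytest.raises(SaturationError):
                    jc_distance(a, b)
            else:
                expect = -0.75 * math.log(1 - 4 * p / 3)
                assert jc_distance(a, b) == pytest.approx(expect, abs=1e-12)

    def test_pairwise_deletion_ignores_gap_columns(self):
        assert jc_distance("AC--GT", "ACTTGT") == 0.0

    def test_symmetry(self):
        a, b = "ACGTTGCA", "ACGATGCA"
        assert jc_distance(a, b) == jc_distance(b, a)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_distance("AAAA", "TTTT")

    def test_clamp_mode_returns_finite(self):
        assert math.isfinite(jc_distance("AAAA", "TTTT", saturation="clamp"))


class TestNj:
    def test_three_taxa_three_point_formulas(self):
        d = DistanceMatrix(("a", "b", "c"), np.array(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]))
        tree = nj_tree(d)
        m = tree.leaf_distances()
        assert np.allclose(m.matrix, d.matrix, atol=1e-9)
        internal = [n for n in tree.adjacency if n not in tree.leaf_labels]
        assert len(internal) == 1 and len(tree.adjacency[internal[0]]) == 3

    def test_four_taxon_additive_recovery_against_enumeration(self):
        rng = np.random.default_rng(8)
        taxa = ("a", "b", "c", "d")
        for adj in enumerate_topologies(taxa):
            t = tree_from_adj(with_lengths(adj, rng), taxa)
            dm = t.leaf_distances()
            rec = nj_tree(dm)
            # oracle: the generating topology is the unique one whose path
            # metric reproduces the additive matrix
            matching = []
            for adj2 in enumerate_topologies(taxa):
                t2 = tree_from_adj(with_lengths(adj2, np.random.default_rng(0)), taxa)
                if t2.bipartitions() == rec.bipartitions():
                    matching.append(t2)
            assert rec.bipartitions() == t.bipartitions()
            assert np.allclose(rec.leaf_distances().matrix, dm.matrix, atol=1e-9)
            assert len(matching) == 1

    def test_simulated_clades_tree_distances_correlate(self, germ):
        from sptrf.elements import element_align
        recs = [SequenceRecord(f"S{a}-{g.pattern_name}-1", g.sequence)
                for a, gg in germ.genotypes.items() for g in gg][:20]
        aln = element_align(recs, germ.library)
        dm = jc_matrix(aln, saturation="clamp")
        tree = nj_tree(dm)
        td = tree.leaf_distances()
        order = [td.ids.index(i) for i in dm.ids]
        tm = td.matrix[np.ix_(order, order)]
        iu = np.triu_indices(len(dm), 1)
        r = np.corrcoef(dm.matrix[iu], tm[iu])[0, 1]
        assert r > 0.95

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ContractError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_matches_dendropy_topology(self):
        """Independent NJ oracle: dendropy's implementation on a random
        (noisy, non-additive) matrix yields the same unrooted topology."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(12)
        n = 8
        base = rng.uniform(0.1, 1.0, size=(n, n))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = tuple(f"t{i}" for i in range(n))
        mine = nj_tree(DistanceMatrix(ids, m))

        import io as _io
        csv = "," + ",".join(ids) + "\n" + "\n".join(
            ids[i] + "," + ",".join(str(m[i, j]) for j in range(n)) for i in range(n))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=",")
        dt = pdm.nj_tree()
        dt.encode_bipartitions()
        dt_bips = set()
        all_taxa = frozenset(ids)
        ref = min(ids)
        for edge in dt.preorder_edge_iter():
            if edge.bipartition is None:
                continue
            side = frozenset(
                t.label for t in edge.bipartition.leafset_taxa(dt.taxon_namespace))
            side = side if ref not in side else all_taxa - side
            if 1 < len(side) < n - 1:
                dt_bips.add(side)
        assert mine.bipartitions() == dt_bips


class TestBootstrap:
    @pytest.fixture(scope="class")
    def block_aln(self):
        # identical within clade, strongly (but sub-saturation) diverged
        # between clades, so clade distances stay additive-like
        rng = np.random.default_rng(3)

        def mutate(seq, rate):
            return "".join(
                rng.choice([x for x in "ACGT" if x != ch]) if rng.random() < rate else ch
                for ch in seq)

        root = "".join(rng.choice(list("ACGT"), size=200))
        a, b, c = (mutate(root, 0.15) for _ in range(3))
        return make_aln([a, a, b, b, c, c], ids=["a1", "a2", "b1", "b2", "c1", "c2"])

    def test_clade_bipartitions_fully_supported(self, block_aln):
        tree = bootstrap_support(block_aln, replicates=30, seed=1)
        clades = [frozenset({"a1", "a2"}), frozenset({"b1", "b2"}), frozenset({"c1", "c2"})]
        canon = {tree._canonical(c) for c in clades}
        for bp in canon & set(tree.supports):
            assert tree.supports[bp] == 100.0

    def test_single_replicate_supports_binary(self, block_aln):
        tree = bootstrap_support(block_aln, replicates=1, seed=9)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self, block_aln):
        t1 = bootstrap_support(block_aln, replicates=10, seed=4)
        t2 = bootstrap_support(block_aln, replicates=10, seed=4)
        assert t1.supports == t2.supports

    def test_newick_suppresses_low_supports(self, block_aln):
        tree = bootstrap_support(block_aln, replicates=30, seed=1)
        tree.supports = {bp: (40.0 if i else 90.0)
                         for i, bp in enumerate(tree.supports)}
        nwk = tree.newick(min_support=50)
        assert ")90" in nwk and ")40" not in nwk


class TestCladePurity:
    def cherry_tree(self):
        # ((A1,A2),(B1,B2)) unrooted
        adj = {0: {4: 0.1}, 1: {4: 0.1}, 2: {5: 0.1}, 3: {5: 0.1},
               4: {0: 0.1, 1: 0.1, 5: 0.2}, 5: {2: 0.1, 3: 0.1, 4: 0.2}}
        return PhyloTree(adj, {0: "A1", 1: "A2", 2: "B1", 3: "B2"})

    def test_pattern_cherries_are_pure(self):
        tree = self.cherry_tree()
        rep = clade_purity(tree, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        assert rep.purity == 1.0 and not rep.violators

    def test_grafted_leaf_breaks_monophyly_and_is_identified(self):
        # ((A1,A2),(B1,(x,B2))): foreign leaf x grafted inside the B clade
        adj = {0: {5: 0.1}, 1: {5: 0.1}, 2: {6: 0.1}, 3: {7: 0.1}, 4: {7: 0.1},
               5: {0: 0.1, 1: 0.1, 6: 0.2},
               6: {5: 0.2, 2: 0.1, 7: 0.2},
               7: {6: 0.2, 3: 0.1, 4: 0.1}}
        tree = PhyloTree(adj, {0: "A1", 1: "A2", 2: "B1", 3: "x", 4: "B2"})
        rep = clade_purity(
            tree, {"A1": "A", "A2": "A", "B1": "B", "x": "X", "B2": "B"})
        assert rep.monophyletic["A"] is True
        assert rep.monophyletic["X"] is True  # singleton, trivially
        assert rep.monophyletic["B"] is False
        assert rep.violators["B"] == ("x",)
        assert rep.purity == pytest.approx(2 / 3)
        # brute-force oracle: no edge side equals {B1, B2}
        sides = [frozenset(s) for s in tree._edge_sides()]
        assert frozenset({"B1", "B2"}) not in sides + \
            [frozenset(tree.taxa) - s for s in sides]

    def test_single_pattern_tree_vacuously_pure(self):
        tree = self.cherry_tree()
        rep = clade_purity(tree, {t: "A" for t in tree.taxa})
        assert rep.purity == 1.0

    def test_pattern_groups_merge_before_testing(self):
        tree = self.cherry_tree()
        labels = {"A1": "01", "A2": "02", "B1": "B", "B2": "B"}
        rep = clade_purity(tree, labels, groups=[{"01", "02"}])
        assert rep.monophyletic["01/02"] is True and rep.purity == 1.0

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ContractError):
            clade_purity(self.cherry_tree(), {"A1": "A"})
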