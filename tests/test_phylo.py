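"""Distances, neighbor joining, midpoint rooting, clade composition."""

import dendropy
import numpy as np
import pytest

from _oracles import exhaustive_midpoint_edge, ls_best_quartet
from tetpipe.phylo import (
    DistanceMatrix,
    clade_composition,
    midpoint_root,
    nj_tree,
    p_distance_matrix,
    read_newick,
    trim_gap_columns,
    write_newick,
)
from tetpipe.seqsim import simulate_cargo_transfer_alignment


def _random_additive_tree(rng, n):
    """Random topology + branch lengths; returns (dendropy tree, labels, D)."""
    labels = [f"t{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    import random as _random

    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=taxa, rng=_random.Random(int(rng.integers(1 << 30))),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                D[i, j] = pdm.distance(a, b)
    return tree, labels, D


class TestTrimGapColumns:
    def test_gapless_unchanged(self):
        rows = {"a": "ACDE", "b": "ACDF"}
        assert trim_gap_columns(rows) == rows

    def test_boundary_column_removed(self):
        rows = {f"r{i}": ("-" if i < 6 else "A") + "C" for i in range(10)}
        out = trim_gap_columns(rows, 0.5)  # 60% gaps > 0.5 -> removed
        assert all(v == "C" for v in out.values())

    def test_exactly_half_kept(self):
        rows = {f"r{i}": ("-" if i < 5 else "A") + "C" for i in range(10)}
        out = trim_gap_columns(rows, 0.5)
        assert all(len(v) == 2 for v in out.values())

    def test_matches_column_filter_oracle(self, rng):
        for _ in range(10):
            nrow, ncol = int(rng.integers(3, 8)), int(rng.integers(5, 30))
            rows = {
                f"r{i}": "".join(rng.choice(list("AC-"), ncol)) for i in range(nrow)
            }
            try:
                out = trim_gap_columns(rows, 0.5)
            except ValueError:
                out = None
            keep = [
                c for c in range(ncol)
                if sum(rows[f"r{i}"][c] == "-" for i in range(nrow)) / nrow <= 0.5
            ]
            if not keep:
                assert out is None
            else:
                assert out == {
                    k: "".join(v[c] for c in keep) for k, v in rows.items()
                }


class TestPDistance:
    def test_identical_rows(self):
        d = p_distance_matrix({"a": "ACDE", "b": "ACDE"})
        assert d.matrix[0, 1] == 0.0

    def test_one_in_four(self):
        d = p_distance_matrix({"a": "AAAA", "b": "AAAT"})
        assert d.matrix[0, 1] == 0.25

    def test_pairwise_deletion_oracle(self, rng):
        for _ in range(10):
            rows = {
                f"r{i}": "".join(rng.choice(list("ACD-"), 40)) for i in range(4)
            }
            try:
                d = p_distance_matrix(rows)
            except ValueError:
                continue
            labs = list(rows)
            for i in range(4):
                for j in range(i + 1, 4):
                    a, b = rows[labs[i]], rows[labs[j]]
                    num = den = 0
                    for x, y in zip(a, b):
                        if x != "-" and y != "-":
                            den += 1
                            num += x != y
                    assert d.matrix[i, j] == pytest.approx(num / den)

    def test_disjoint_rows_raise(self):
        with pytest.raises(ValueError, match="no comparable"):
            p_distance_matrix({"a": "A-", "b": "-C"})


class TestNJTree:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(5)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(9)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(10)

    def test_additive_matrix_recovers_tree(self, rng):
        for _ in range(6):
            true, labels, D = _random_additive_tree(rng, int(rng.integers(5, 9)))
            got = nj_tree(DistanceMatrix(labels, D))
            pdm = got.phylogenetic_distance_matrix()
            taxa = {x.label: x for x in got.taxon_namespace}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D[i, j], abs=1e-9)

    def test_quartet_topology_matches_least_squares(self, rng):
        for _ in range(8):
            _, labels, D = _random_additive_tree(rng, 4)
            got = nj_tree(DistanceMatrix(labels, D))
            want_split = ls_best_quartet(labels, D)
            # extract the cherry partition from the NJ tree
            for node in got.preorder_node_iter():
                leaves = [l.taxon.label for l in node.leaf_iter()]
                if len(leaves) == 2:
                    pair = frozenset(leaves)
                    rest = frozenset(set(labels) - pair)
                    assert frozenset({pair, rest}) == want_split
                    break

    def test_duplicate_taxon_zero_cherry(self):
        D = np.array([
            [0, 0, 7, 11], [0, 0, 7, 11], [7, 7, 0, 6], [11, 11, 6, 0]
        ], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "a2", "b", "c"], D))
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["a2"]) == pytest.approx(0.0)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], dtype=float))

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        import io as _io

        from skbio.tree import nj as skbio_nj

        _, labels, D = _random_additive_tree(rng, 6)
        ours = nj_tree(DistanceMatrix(labels, D))
        buf = _io.StringIO()
        skbio_nj(skbio.DistanceMatrix(D, labels)).write(buf)
        theirs_nwk = buf.getvalue()
        tns = ours.taxon_namespace
        theirs = dendropy.Tree.get(data=theirs_nwk, schema="newick", taxon_namespace=tns)
        from dendropy.calculate import treecompare
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        assert treecompare.symmetric_difference(ours, theirs) == 0


class TestMidpointRoot:
    def test_two_leaves(self):
        t = read_newick("(a:1,b:3);", from_path=False)
        r = midpoint_root(t)
        depths = {l.taxon.label: l.distance_from_root() for l in r.leaf_node_iter()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_max_depth_is_half_diameter(self, rng):
        for _ in range(6):
            tree, labels, D = _random_additive_tree(rng, int(rng.integers(4, 9)))
            r = midpoint_root(tree)
            maxdepth = max(l.distance_from_root() for l in r.leaf_node_iter())
            assert maxdepth == pytest.approx(D.max() / 2, abs=1e-9)

    def test_matches_exhaustive_edge_oracle(self, rng):
        for _ in range(5):
            tree, labels, D = _random_additive_tree(rng, 7)
            _, best_val = exhaustive_midpoint_edge(tree.clone(depth=1))
            r = midpoint_root(tree)
            maxdepth = max(l.distance_from_root() for l in r.leaf_node_iter())
            assert maxdepth == pytest.approx(best_val, abs=1e-9)

    def test_idempotent(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);", from_path=False)
        r1 = midpoint_root(t)
        r2 = midpoint_root(r1)
        d1 = {l.taxon.label: l.distance_from_root() for l in r1.leaf_node_iter()}
        d2 = {l.taxon.label: l.distance_from_root() for l in r2.leaf_node_iter()}
        assert d1 == pytest.approx(d2)

    def test_zero_lengths_flagged(self):
        t = read_newick("(a:0,b:0,c:0);", from_path=False)
        with pytest.warns(UserWarning, match="midpoint undefined"):
            midpoint_root(t)


class TestNewickRoundTrip:
    def test_roundtrip_preserves_tree(self, rng):
        for _ in range(5):
            tree, labels, D = _random_additive_tree(rng, 6)
            s = write_newick(tree)
            back = dendropy.Tree.get(data=s, schema="newick",
                                     taxon_namespace=tree.taxon_namespace)
            from dendropy.calculate import treecompare
            a, b = tree.clone(depth=1), back.clone(depth=1)
            for t in (a, b):  # compare as unrooted trees
                t.deroot()
                t.encode_bipartitions()
            assert treecompare.symmetric_difference(a, b) == 0
            pdm1 = tree.phylogenetic_distance_matrix()
            pdm2 = back.phylogenetic_distance_matrix()
            for a in tree.taxon_namespace:
                for b in tree.taxon_namespace:
                    assert pdm2.distance(a, b) == pytest.approx(
                        pdm1.distance(a, b), abs=1e-5)


class TestCladeComposition:
    def test_two_by_two_split(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);", from_path=False)
        comp = clade_composition(t, {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        two_leaf = [c for c in comp if len(c.leaves) == 2]
        assert all(c.pure for c in two_leaf)

    def test_single_category_all_pure(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);", from_path=False)
        comp = clade_composition(t, dict.fromkeys("abcd", "X"))
        assert all(c.pure for c in comp)

    def test_unmapped_leaf_raises(self):
        t = read_newick("(a:1,b:1,c:1);", from_path=False)
        with pytest.raises(ValueError, match="unmapped"):
            clade_composition(t, {"a": "X", "b": "X"})

    def test_transfer_yields_mixed_clade(self):
        """A cargo gene transferred across superfamilies produces a
        well-populated clade of mixed host-superfamily composition."""
        rows, cats = simulate_cargo_transfer_alignment(seed=5)
        tree = midpoint_root(nj_tree(p_distance_matrix(rows)))
        comp = clade_composition(tree, cats)
        mixed = [c for c in comp if not c.pure and len(c.leaves) >= 4]
        assert mixed
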