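import numpy as np
import pandas as pd
import pytest

from nichebreadth import trees
from nichebreadth.trees import (
    DuplicateTipError,
    NewickError,
    NotUltrametricError,
    consensus_with_edges,
    cophenetic_matrix,
    force_ultrametric_extend,
    node_ages,
    prune,
    read_newick,
    resolve_polytomies,
    taxonomy_to_tree,
    write_newick,
)


def ages_by_label(tree):
    out = {}
    for node, age in node_ages(tree).items():
        if node.is_leaf():
            out[node.taxon.label] = age
    return out


class TestNewickIO:
    def test_parse_with_lengths(self, three_tip_tree):
        assert sorted(trees.tip_labels(three_tip_tree)) == ["A", "B", "C"]
        assert trees.tree_height(three_tip_tree) == pytest.approx(2.0)

    def test_missing_lengths_default_to_one(self):
        t = read_newick("((A,B),C);")
        assert trees.tree_height(t) == pytest.approx(2.0)
        d = cophenetic_matrix(t)
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(3.0)  # two unit edges + one

    def test_duplicate_tip_rejected(self):
        with pytest.raises(DuplicateTipError):
            read_newick("((A:1,A:1):1,C:2);")

    def test_malformed_input_reports_error(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,B:1:1,C;")

    @pytest.mark.parametrize(
        "nwk",
        [
            "((A:1,B:1):1,C:2);",
            "((A:1.5,B:1.5):0.25,(C:1,D:1):0.75);",
            "(A:3,B:3,C:3);",
        ],
    )
    def test_roundtrip_preserves_distances(self, nwk):
        t1 = read_newick(nwk)
        t2 = read_newick(write_newick(t1))
        d1, d2 = cophenetic_matrix(t1), cophenetic_matrix(t2)
        labs = sorted(d1.index)
        np.testing.assert_allclose(
            d1.loc[labs, labs].values, d2.loc[labs, labs].values, atol=1e-9
        )


class TestNodeAges:
    def test_ages_of_three_tip_tree(self, three_tip_tree):
        ages = sorted(node_ages(three_tip_tree).values())
        assert ages == pytest.approx([0.0, 0.0, 0.0, 1.0, 2.0])

    def test_star_tree(self):
        ages = sorted(node_ages(read_newick("(A:3,B:3,C:3);")).values())
        assert ages == pytest.approx([0.0, 0.0, 0.0, 3.0])

    def test_non_ultrametric_rejected(self):
        with pytest.raises(NotUltrametricError):
            node_ages(read_newick("((A:1,B:2):1,C:2);"))


class TestForceUltrametric:
    def test_extends_short_terminals_only(self):
        t = force_ultrametric_extend(read_newick("((A:1,B:2):1,C:2);"))
        assert trees.is_ultrametric(t)
        assert trees.tree_height(t) == pytest.approx(3.0)
        # internal branch untouched
        ages = node_ages(t)
        internal = [a for n, a in ages.items() if not n.is_leaf() and n.parent_node]
        assert internal == pytest.approx([2.0])

    def test_identity_on_ultrametric(self, three_tip_tree):
        t = force_ultrametric_extend(three_tip_tree)
        np.testing.assert_allclose(
            cophenetic_matrix(t).values, cophenetic_matrix(three_tip_tree).values
        )

    def test_two_tip(self):
        t = force_ultrametric_extend(read_newick("(A:1,B:5);"))
        assert ages_by_label(t) == {"A": 0.0, "B": 0.0}
        assert trees.tree_height(t) == pytest.approx(5.0)

    def test_idempotent(self):
        t = read_newick("((A:1,B:2):1,(C:0.5,D:2):2);")
        once = force_ultrametric_extend(t)
        twice = force_ultrametric_extend(once)
        np.testing.assert_allclose(
            cophenetic_matrix(once).values, cophenetic_matrix(twice).values, atol=1e-12
        )


class TestResolvePolytomies:
    def test_binary_tree_unchanged(self, three_tip_tree):
        out = resolve_polytomies(three_tip_tree, seed=1)
        np.testing.assert_allclose(
            cophenetic_matrix(out).values, cophenetic_matrix(three_tip_tree).values
        )

    def test_trifurcation_distances_preserved(self):
        t = read_newick("(A:1,B:1,C:1);")
        out = resolve_polytomies(t, seed=7)
        assert all(len(n.child_nodes()) in (0, 2) for n in out.preorder_node_iter())
        d = cophenetic_matrix(out)
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert d.loc[a, b] == pytest.approx(2.0)

    @pytest.mark.parametrize("seeds", [(0, 1), (2, 3)])
    def test_five_way_polytomy_distance_matrix_invariant(self, seeds):
        t = read_newick("((A:1,B:1,C:1,D:1,E:1):1,F:2);")
        labs = ["A", "B", "C", "D", "E", "F"]
        mats = []
        for s in seeds:
            out = resolve_polytomies(t, seed=s)
            assert all(len(n.child_nodes()) in (0, 2) for n in out.preorder_node_iter())
            mats.append(cophenetic_matrix(out).loc[labs, labs].values)
        base = cophenetic_matrix(t).loc[labs, labs].values
        for m in mats:
            np.testing.assert_allclose(m, base, atol=1e-12)


class TestConsensus:
    def test_identity_on_copies(self, three_tip_tree):
        c = consensus_with_edges([three_tip_tree] * 5)
        d = cophenetic_matrix(c)
        np.testing.assert_allclose(
            d.loc[["A", "B", "C"], ["A", "B", "C"]].values,
            cophenetic_matrix(three_tip_tree).loc[["A", "B", "C"], ["A", "B", "C"]].values,
        )

    def test_majority_rule(self):
        ts = [
            read_newick("((A,B),C);"),
            read_newick("((A,B),C);"),
            read_newick("((A,C),B);"),
        ]
        c = consensus_with_edges(ts)
        d = cophenetic_matrix(c)
        assert d.loc["A", "B"] < d.loc["A", "C"]  # AB clade retained

    def test_mean_edge_lengths(self):
        t1 = read_newick("((A:1,B:1):1,C:1);")
        t2 = read_newick("((A:3,B:3):3,C:3);")
        c = consensus_with_edges([t1, t2])
        d = cophenetic_matrix(c)
        assert d.loc["A", "B"] == pytest.approx(4.0)  # mean terminal edges 2 + 2

    def test_tip_set_mismatch(self, three_tip_tree):
        with pytest.raises(ValueError, match="tip set"):
            consensus_with_edges([three_tip_tree, read_newick("((A:1,B:1):1,D:2);")])

    def test_majority_against_dendropy(self):
        # independent topology oracle: dendropy's majority-rule consensus
        import dendropy

        newicks = [
            "((A,B),(C,D));",
            "((A,B),(C,D));",
            "((A,C),(B,D));",
            "(((A,B),C),D);",
        ]
        mine = consensus_with_edges([read_newick(n) for n in newicks])
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList(
            [dendropy.Tree.get(data=n, schema="newick", taxon_namespace=tns) for n in newicks]
        )
        ref = tl.consensus(min_freq=0.5)
        ref.encode_bipartitions()
        full = frozenset("ABCD")

        def splits(tree):
            # compare as unrooted splits: a clade and its complement coincide
            out = set()
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None or nd.is_leaf():
                    continue
                clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                if 1 < len(clade) < len(full):
                    out.add(min(clade, full - clade, key=sorted))
            return out

        assert splits(mine) == splits(ref)


class TestTaxonomyToTree:
    @pytest.fixture
    def rank_table(self):
        return pd.DataFrame(
            {
                "species": ["s1", "s2", "s3", "s4", "s5"],
                "genus": ["g1", "g1", "g2", "g3", "g4"],
                "subfamily": ["sf1", "sf1", "sf1", "sf2", "sf3"],
                "family": ["f1", "f1", "f1", "f1", "f2"],
            }
        )

    def test_rank_distances(self, rank_table):
        t = taxonomy_to_tree(rank_table)
        d = cophenetic_matrix(t)
        assert d.loc["s1", "s2"] == pytest.approx(2.0)  # congeners
        assert d.loc["s1", "s3"] == pytest.approx(4.0)  # same subfamily
        assert d.loc["s1", "s4"] == pytest.approx(6.0)  # same family only
        assert d.loc["s1", "s5"] == pytest.approx(8.0)  # different families

    def test_ultrametric_height_four(self, rank_table):
        t = taxonomy_to_tree(rank_table)
        assert trees.is_ultrametric(t)
        assert trees.tree_height(t) == pytest.approx(4.0)

    def test_inconsistent_nesting_rejected(self, rank_table):
        bad = rank_table.copy()
        bad.loc[1, "subfamily"] = "sf9"  # g1 now spans two subfamilies
        with pytest.raises(ValueError, match="nesting"):
            taxonomy_to_tree(bad)

    def test_duplicate_species_rejected(self, rank_table):
        bad = pd.concat([rank_table, rank_table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            taxonomy_to_tree(bad)


class TestPrune:
    def test_path_sum_collapse(self, three_tip_tree):
        p = prune(three_tip_tree, {"A", "C"})
        d = cophenetic_matrix(p)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert trees.tree_height(p) == pytest.approx(2.0)

    def test_full_tip_set_identity(self, three_tip_tree):
        p = prune(three_tip_tree, {"A", "B", "C"})
        np.testing.assert_allclose(
            cophenetic_matrix(p).loc[["A", "B", "C"], ["A", "B", "C"]].values,
            cophenetic_matrix(three_tip_tree).loc[["A", "B", "C"], ["A", "B", "C"]].values,
        )

    def test_single_tip_keeps_depth(self, three_tip_tree):
        p = prune(three_tip_tree, {"A"})
        assert trees.tip_labels(p) == ["A"]
        assert trees.tree_height(p) == pytest.approx(2.0)

    def test_unknown_tip(self, three_tip_tree):
        with pytest.raises(KeyError):
            prune(three_tip_tree, {"A", "Z"})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_subsets_preserve_distances_and_depth(self, seed):
        from nichebreadth import simulate

        cfg = simulate.SimulationConfig(n_hosts=25)
        t = simulate.simulate_host_tree(cfg, seed)
        full = cophenetic_matrix(t)
        rng = np.random.default_rng(seed)
        keep = list(rng.choice(full.index, size=8, replace=False))
        p = prune(t, keep)
        np.testing.assert_allclose(
            cophenetic_matrix(p).loc[keep, keep].values,
            full.loc[keep, keep].values,
            atol=1e-12,
        )
        assert trees.tree_height(p) == pytest.approx(trees.tree_height(t))
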