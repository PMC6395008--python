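import itertools
import math

import numpy as np
import pytest

from homeokit import trees
from homeokit.trees import (
    Clade,
    TreeError,
    classify_topology_groups,
    distance_matrix,
    enumerate_topologies,
    monophyly_frequencies,
    nj_tree,
    parse_newick,
    root_at_outgroup,
    sliding_trees,
    topology_weights,
)
from homeokit.variants import MISSING, HaplotypeAlignment


def _aln(haps, positions=None):
    haps = np.asarray(haps, dtype=np.int8)
    n, s = haps.shape
    return HaplotypeAlignment(
        [chr(65 + i) for i in range(n)],
        np.repeat("chr1", s),
        np.asarray(positions) if positions is not None else np.arange(1, s + 1),
        np.repeat("A", s), np.repeat("T", s), haps,
    )


class TestDistances:
    def test_identical_and_simple_counts(self):
        # ACGT vs ACGA analog: one difference over four sites
        aln = _aln([[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 0, 0]])
        d, labels = distance_matrix(aln, mode="count")
        assert d[0, 2] == 0
        assert d[0, 1] == 1
        dps, _ = distance_matrix(aln, mode="per-site")
        assert dps[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_with_missing(self):
        # A?GT vs ACGA: 3 comparable sites, 1 difference
        aln = _aln([[0, MISSING, 0, 0], [0, 0, 0, 1], [0, 0, 0, 0]])
        d, _ = distance_matrix(aln, mode="per-site")
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites(self):
        aln = _aln([[MISSING, 0], [1, MISSING], [0, 0]])
        d, _ = distance_matrix(aln)
        assert np.isnan(d[0, 1])
        with pytest.raises(TreeError):
            distance_matrix(aln, strict=True)


def _topology_of(clade):
    """Canonical label-nesting of a Clade, ignoring branch lengths."""
    if clade.is_leaf():
        return clade.name
    return "(" + ",".join(sorted(_topology_of(c) for c in clade.children)) + ")"


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 2], [6, 6, 2, 0]], dtype=float
        )
        tree = nj_tree(d, labels)
        rooted = root_at_outgroup(tree, "D")
        assert _topology_of(rooted) == "(((A,B),C),D)"

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["A"] == pytest.approx(0.5 * (3 + 5 - 4))
        assert lengths["B"] == pytest.approx(0.5 * (3 + 4 - 5))
        assert lengths["C"] == pytest.approx(0.5 * (5 + 4 - 3))

    def test_invariant_to_taxon_order(self, rng):
        labels = list("ABCDEF")
        base = rng.random((6, 6))
        d = base + base.T
        np.fill_diagonal(d, 0)
        t1 = root_at_outgroup(nj_tree(d, labels), "F")
        perm = rng.permutation(6)
        t2 = root_at_outgroup(nj_tree(d[np.ix_(perm, perm)], [labels[i] for i in perm]), "F")
        assert _topology_of(t1) == _topology_of(t2)

    def test_matches_skbio_on_additive_matrices(self, rng):
        """Independent implementation check: same topology as scikit-bio's nj."""
        import io

        from skbio import DistanceMatrix as SkbioDM, TreeNode
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            # random additive matrix from a random binary tree with positive lengths
            n = 6
            labels = [f"t{i}" for i in range(n)]
            # build random tree via random pair joins
            nodes = {i: Clade(name=labels[i], length=rng.uniform(0.5, 2)) for i in range(n)}
            keys = list(nodes)
            while len(keys) > 2:
                i, j = sorted(rng.choice(len(keys), 2, replace=False))
                a, b = keys[i], keys[j]
                parent = Clade(length=rng.uniform(0.5, 2), children=[nodes[a], nodes[b]])
                k = max(nodes) + 1
                nodes[k] = parent
                keys = [x for x in keys if x not in (a, b)] + [k]
            root = Clade(children=[nodes[keys[0]], nodes[keys[1]]])

            # distances by path lengths
            paths = {}

            def walk(node, dist, path):
                if node.is_leaf():
                    paths[node.name] = dist
                for c in node.children:
                    walk(c, dist + c.length, path)

            def tip_dist(a, b):
                # via newick -> skbio for an independent path computation
                return skt.find(a).distance(skt.find(b))

            skt = TreeNode.read(io.StringIO(root.to_newick()))
            d = np.zeros((n, n))
            for x, y in itertools.combinations(range(n), 2):
                d[x, y] = d[y, x] = tip_dist(labels[x], labels[y])

            mine = root_at_outgroup(nj_tree(d, labels), "t0")
            theirs = skbio_nj(SkbioDM(d, labels))
            theirs_rooted = parse_newick(str(theirs).strip())
            theirs_rooted = root_at_outgroup(theirs_rooted, "t0")
            assert _topology_of(mine) == _topology_of(theirs_rooted)

    def test_undefined_entries_raise(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(TreeError):
            nj_tree(d, ["A", "B", "C"])


class TestSlidingTrees:
    def test_tree_count_bounded_by_genome_size(self, clean_dataset):
        from homeokit.pipeline import _combine, _reindex_outgroup

        truth, panels = clean_dataset["truth"], clean_dataset["panels"]
        co = truth.co_alignment()
        og = _reindex_outgroup(panels.outgroup, co)
        combined = _combine([truth.co_alignment(), truth.cg_alignment(), og])
        wins, skipped = sliding_trees(combined, window_bp=50_000, min_complete_sites=20)
        assert len(wins) <= clean_dataset["params"].seq_length // 50_000 + 8
        assert len(wins) > 0

    def test_homogeneous_windows_match_whole_alignment_topology(self, clean_dataset):
        from homeokit.pipeline import _combine, _reindex_outgroup

        truth, panels = clean_dataset["truth"], clean_dataset["panels"]
        co = truth.co_alignment()
        og = _reindex_outgroup(panels.outgroup, co)
        combined = _combine([co, truth.cg_alignment(), og])
        wins, _ = sliding_trees(combined, window_bp=50_000, min_complete_sites=20)
        groups = {
            "co": set(co.names),
            "cg": set(truth.cg_alignment().names),
        }
        freq = monophyly_frequencies([t for *_, t in wins], groups, outgroup="OUT_1")
        # both subgenomes monophyletic in nearly every window tree
        assert (freq.frequency >= 0.95).all()


class TestMonophyly:
    def test_hand_built_frequencies(self):
        t_mono = parse_newick("((A,B),(C,O));")
        t_not = parse_newick("((A,C),(B,O));")
        freq = monophyly_frequencies(
            [t_mono, t_mono, t_mono, t_not], {"AB": {"A", "B"}}, outgroup="O"
        )
        assert freq.frequency.iloc[0] == pytest.approx(0.75)

    def test_trees_missing_tips_are_skipped(self):
        t_ok = parse_newick("((A,B),(C,O));")
        t_missing = parse_newick("((A,C),O);")  # group member B absent
        freq = monophyly_frequencies([t_ok, t_missing], {"AB": {"A", "B"}}, outgroup="O")
        assert freq.n_trees.iloc[0] == 1


class TestTopologySpace:
    @pytest.mark.parametrize("k,expected", [(3, 3), (4, 15), (5, 105)])
    def test_rooted_topology_counts_match_double_factorial(self, k, expected):
        labels = [f"G{i}" for i in range(k)]
        topos = enumerate_topologies(labels)
        assert len(topos) == expected
        assert len(set(topos)) == expected
        assert expected == math.prod(range(2 * k - 3, 0, -2))

    def test_single_tip_per_group_gives_unit_weight(self):
        tree = parse_newick("(((A,E),M),(P,O));")
        w = topology_weights(
            tree, {"A": "ASI", "E": "EUR", "M": "ME", "P": "PARENT"}, outgroup="O"
        )
        assert sum(w.values()) == pytest.approx(1.0)
        assert w["(((ASI,EUR),ME),PARENT)"] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_match_combination_counting(self, rng):
        """Exhaustive weights equal a brute-force count over an independent oracle."""
        import dendropy

        for rep in range(5):
            tips = {
                "ASI": [f"a{i}" for i in range(3)],
                "EUR": [f"e{i}" for i in range(2)],
                "ME": [f"m{i}" for i in range(2)],
                "PARENT": [f"p{i}" for i in range(2)],
            }
            all_tips = [t for v in tips.values() for t in v] + ["OUT"]
            # random binary tree over the tips
            newick = _random_newick(all_tips, rng)
            tree = parse_newick(newick)
            tip2group = {t: g for g, v in tips.items() for t in v}
            w = topology_weights(tree, tip2group, outgroup="OUT", method="exhaustive")
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)

            # oracle: dendropy-extracted induced subtrees, classified by MRCA depths
            dtree = dendropy.Tree.get(data=newick, schema="newick")
            counts = {}
            combos = list(itertools.product(tips["ASI"], tips["EUR"], tips["ME"], tips["PARENT"]))
            for combo in combos:
                topo = _oracle_topology(dtree, dict(zip(combo, ["ASI", "EUR", "ME", "PARENT"])))
                counts[topo] = counts.get(topo, 0) + 1
            for topo, cnt in counts.items():
                assert w[topo] == pytest.approx(cnt / len(combos))

    def test_montecarlo_agrees_with_exhaustive(self):
        tree = parse_newick("(((a1,a2),(e1,(m1,m2))),((p1,p2),OUT));")
        tip2group = {
            "a1": "ASI", "a2": "ASI", "e1": "EUR", "m1": "ME", "m2": "ME",
            "p1": "PARENT", "p2": "PARENT",
        }
        exact = topology_weights(tree, tip2group, outgroup="OUT", method="exhaustive")
        mc = topology_weights(
            tree, tip2group, outgroup="OUT", method="montecarlo", n_samples=4000, seed=2
        )
        for topo, wx in exact.items():
            se = np.sqrt(max(wx * (1 - wx), 1e-9) / 4000)
            assert abs(mc[topo] - wx) < 4 * se + 1e-9

    def test_empty_group_raises(self):
        tree = parse_newick("((A,B),O);")
        with pytest.raises(TreeError):
            # the ME group's only tip is absent from the tree
            topology_weights(tree, {"A": "ASI", "B": "EUR", "C": "ME"}, outgroup="O")


def _random_newick(tips, rng):
    nodes = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def _oracle_topology(dtree, chosen):
    """Independent induced-topology computation via dendropy MRCA depths."""
    import dendropy

    t = dtree.clone(depth=1)
    t.is_rooted = True
    t.to_outgroup_position(
        t.find_node_with_taxon_label("OUT"), update_bipartitions=False
    )
    for nd in t.preorder_node_iter():
        nd.depth = 0 if nd.parent_node is None else nd.parent_node.depth + 1
    taxa = {lbl: t.taxon_namespace.get_taxon(lbl) for lbl in chosen}

    items = {frozenset([lbl]): lbl for lbl in chosen}
    labels = {frozenset([lbl]): chosen[lbl] for lbl in chosen}
    while len(items) > 1:
        # deepest MRCA among current item pairs joins next
        best, best_depth = None, -1
        for x, y in itertools.combinations(items, 2):
            mrca = t.mrca(taxa=[taxa[lbl] for lbl in (x | y)])
            if mrca.depth > best_depth:
                best, best_depth = (x, y), mrca.depth
        x, y = best
        merged = x | y
        labels[merged] = "(" + ",".join(sorted([labels[x], labels[y]])) + ")"
        for k in (x, y):
            items.pop(k, None)
            labels.pop(k, None)
        items[merged] = labels[merged]
    return labels[next(iter(items))]


class TestClassification:
    def test_known_example_classes(self):
        assert (
            trees._topology_class("((ASI,PARENT),(EUR,ME))", "PARENT", ("ASI", "EUR", "ME"))
            == "ASI+parent"
        )
        assert (
            trees._topology_class("(((ASI,EUR),ME),PARENT)", "PARENT", ("ASI", "EUR", "ME"))
            == "species-tree"
        )
        assert (
            trees._topology_class("(((ASI,EUR),PARENT),ME)", "PARENT", ("ASI", "EUR", "ME"))
            == "other"
        )

    def test_class_weights_sum_to_one(self):
        topos = enumerate_topologies(["ASI", "EUR", "ME", "PARENT"])
        w = {t: 1 / 15 for t in topos}
        classes = classify_topology_groups(w)
        assert sum(classes.values()) == pytest.approx(1.0)

    def test_partition_sizes_over_fifteen_topologies(self):
        """3 species trees, 3 per population+parent class, 3 other."""
        topos = enumerate_topologies(["ASI", "EUR", "ME", "PARENT"])
        classes = classify_topology_groups({t: 1.0 for t in topos})
        assert classes == {
            "species-tree": 3.0, "ASI+parent": 3.0, "EUR+parent": 3.0,
            "ME+parent": 3.0, "other": 3.0,
        }

    def test_classification_matches_sister_set_oracle(self):
        """Independent rule: class from the tip set sister to PARENT via dendropy."""
        import dendropy

        pops = ("ASI", "EUR", "ME")
        for topo in enumerate_topologies([*pops, "PARENT"]):
            dt = dendropy.Tree.get(data=topo + ";", schema="newick")
            leaf = next(
                lf for lf in dt.leaf_node_iter() if lf.taxon.label == "PARENT"
            )
            sisters = {
                lf.taxon.label
                for lf in leaf.parent_node.leaf_iter()
                if lf.taxon.label != "PARENT"
            }
            if sisters == set(pops):
                expect = "species-tree"
            elif len(sisters) == 1:
                expect = f"{next(iter(sisters))}+parent"
            else:
                expect = "other"
            assert trees._topology_class(topo, "PARENT", pops) == expect
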