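import itertools
import random

import pytest

import oracles
from genefam.genetree import (
    Node,
    SpeciesTree,
    TreeError,
    build_candidate_trees,
    all_rootings,
    leaf_species_map,
    neighbor_joining,
    parse_newick,
    read_nhx,
    reconcile,
    select_and_root,
    species_tree_from_taxonomy,
    write_nhx,
)
from genefam.msa import CodonAlignment, ProteinAlignment
from skbio import DistanceMatrix


TAXONOMY = [
    ("human", "primates"),
    ("chimp", "primates"),
    ("primates", "mammals"),
    ("mouse", "rodents"),
    ("rodents", "mammals"),
]


def leafset(node):
    return frozenset(node.leaf_names())


def splits(node):
    """Non-trivial bipartitions of an unrooted tree topology."""
    all_leaves = leafset(node)
    out = set()
    for n in node.postorder():
        ls = leafset(n)
        if 1 < len(ls) < len(all_leaves) - 1:
            out.add(frozenset({ls, all_leaves - ls}))
    return out


class TestSpeciesTreeFromTaxonomy:
    def test_shape_forced_by_table(self):
        sp = species_tree_from_taxonomy(TAXONOMY)
        assert sp.species == ["chimp", "human", "mouse"]
        # rodents is unary and must collapse; primates groups human+chimp
        primates = sp.node_of("primates")
        assert leafset(primates) == frozenset({"human", "chimp"})
        assert leafset(sp.root) == frozenset({"human", "chimp", "mouse"})

    def test_single_species(self):
        sp = species_tree_from_taxonomy([("human", "")])
        assert sp.species == ["human"]
        assert sp.root.is_leaf()

    def test_cycle_rejected(self):
        with pytest.raises(TreeError):
            species_tree_from_taxonomy([("a", "b"), ("b", "a")])

    def test_multiple_roots_rejected(self):
        with pytest.raises(TreeError):
            species_tree_from_taxonomy([("a", ""), ("b", "")])


class TestSpeciesTreeLoad:
    def test_polytomy_resolved_deterministically(self):
        sp = SpeciesTree.from_newick("(c,a,b);")
        for n in sp.root.postorder():
            assert len(n.children) in (0, 2)
        assert sorted(sp.root.leaf_names()) == ["a", "b", "c"]

    def test_unnamed_internals_get_stable_labels(self):
        sp = SpeciesTree.from_newick("((a,b),c);")
        names = {n.name for n in sp.root.postorder() if not n.is_leaf()}
        assert names == {"a.2", "a.3"}

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError):
            SpeciesTree.from_newick("((a,a),b);")


class TestNeighborJoining:
    def test_additive_quartet_recovers_ab_cd_split(self):
        ids = ["A", "B", "C", "D"]
        d = {
            ("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 5,
            ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7,
        }
        import numpy as np

        m = np.zeros((4, 4))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    m[i, j] = d.get((x, y), d.get((y, x)))
        tree = neighbor_joining(DistanceMatrix(m, ids))
        want = oracles.ls_best_quartet_topology(d, ids)
        assert want == frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        got = splits(tree)
        assert got == {frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})}

    def test_recovers_random_additive_trees(self):
        # distances generated on a random binary tree are additive, so NJ
        # must recover the generating topology exactly
        rng = random.Random(23)
        for trial in range(6):
            n = rng.randrange(4, 9)
            labels = [f"L{i}" for i in range(n)]
            nodes = [Node(name=l, length=rng.uniform(0.5, 2.0)) for l in labels]
            while len(nodes) > 3:
                a = nodes.pop(rng.randrange(len(nodes)))
                b = nodes.pop(rng.randrange(len(nodes)))
                nodes.append(Node(length=rng.uniform(0.5, 2.0), children=[a, b]))
            true = Node(children=nodes)

            # path distances on the true unrooted tree
            import numpy as np

            parent = {}
            for nd in true.postorder():
                for c in nd.children:
                    parent[id(c)] = nd
            by_name = {nd.name: nd for nd in true.leaves()}

            def path_to_root(x):
                out = []
                while x is not None:
                    out.append(x)
                    x = parent.get(id(x))
                return out

            m = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                pi = path_to_root(by_name[labels[i]])
                pj = path_to_root(by_name[labels[j]])
                shared = {id(x) for x in pi} & {id(x) for x in pj}
                dist = sum(x.length for x in pi if id(x) not in shared)
                dist += sum(x.length for x in pj if id(x) not in shared)
                m[i, j] = m[j, i] = dist
            got = neighbor_joining(DistanceMatrix(m, labels))
            assert splits(got) == splits(true)


class TestCandidateTrees:
    def make_alignments(self):
        prot = ProteinAlignment({"a_x": "MKVLW", "b_y": "MKVLW", "c_z": "MKILW", "d_w": "MQILW"})
        codons = {
            "a_x": "ATGAAAGTACTATGG",
            "b_y": "ATGAAAGTACTCTGG",
            "c_z": "ATGAAAATACTATGG",
            "d_w": "ATGCAAATACTATGG",
        }
        return CodonAlignment(codons), prot

    def test_exactly_five_trees_same_leaf_set(self):
        codon, prot = self.make_alignments()
        trees = build_candidate_trees(codon, prot)
        assert len(trees) == 5
        for t in trees:
            assert sorted(t.leaf_names()) == sorted(prot.rows)

    def test_three_sequences_unique_topology(self):
        prot = ProteinAlignment({"a": "MKV", "b": "MKV", "c": "MQV"})
        codon = CodonAlignment(
            {"a": "ATGAAAGTA", "b": "ATGAAGGTA", "c": "ATGCAAGTA"}
        )
        for t in build_candidate_trees(codon, prot):
            assert sorted(t.leaf_names()) == ["a", "b", "c"]

    def test_identical_sequences_zero_distances(self):
        prot = ProteinAlignment({"a": "MKV", "b": "MKV", "c": "MKV"})
        codon = CodonAlignment({"a": "ATGAAAGTA", "b": "ATGAAAGTA", "c": "ATGAAAGTA"})
        for t in build_candidate_trees(codon, prot):
            assert t.total_branch_length() == 0

    def test_fewer_than_three_rejected(self):
        prot = ProteinAlignment({"a": "MKV", "b": "MKV"})
        codon = CodonAlignment({"a": "ATGAAAGTA", "b": "ATGAAAGTA"})
        with pytest.raises(TreeError):
            build_candidate_trees(codon, prot)

    def test_all_gap_overlap_names_the_pair(self):
        prot = ProteinAlignment({"a": "MK--", "b": "--VL", "c": "MKVL"})
        codon = CodonAlignment(
            {"a": "ATGAAA------", "b": "------GTACTA", "c": "ATGAAAGTACTA"}
        )
        with pytest.raises(TreeError, match="a.*b"):
            build_candidate_trees(codon, prot)


CONGRUENT_SP = "((A,B),C);"


def gene_tree(newick):
    return parse_newick(newick)


class TestReconcile:
    def test_congruent_tree_all_speciations(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        gt = gene_tree("((g1_A:1,g2_B:1):1,g3_C:1);")
        annotated, dups, losses = reconcile(gt, sp)
        assert (dups, losses) == (0, 0)
        events = [n.event for n in annotated.postorder() if not n.is_leaf()]
        assert events == ["S", "S"]

    def test_within_species_duplication_scores_one(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        gt = gene_tree("((g1_A:1,g2_A:1):1,g3_B:1);")
        annotated, dups, _ = reconcile(gt, sp)
        inner = annotated.children[0]
        assert dups == 1
        assert inner.event == "D"
        assert inner.dcs == 1.0

    def test_partial_overlap_duplication_dcs_half(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        gt = gene_tree("((g1_A:1,g2_B:1):1,g3_A:1);")
        annotated, dups, _ = reconcile(gt, sp)
        assert annotated.event == "D"  # root maps where its child maps
        assert annotated.dcs == 0.5
        assert dups == 1

    def test_dcs_bounds_and_identity_condition(self):
        sp = SpeciesTree.from_newick("((A,B),(C,D));")
        gt = gene_tree("(((g1_A,g2_B),(g3_A,g4_B)),(g5_C,g6_D));")
        annotated, _, _ = reconcile(gt, sp)
        for n in annotated.postorder():
            if n.event == "D":
                assert 0 <= n.dcs <= 1
        root_left = annotated.children[0]
        assert root_left.event == "D"
        assert root_left.dcs == 1.0  # both children span exactly {A,B}

    def test_losses_counted_on_skipped_species_edges(self):
        sp = SpeciesTree.from_newick("((A,B),C);")
        gt = gene_tree("(g1_A:1,g2_C:1);")
        _, dups, losses = reconcile(gt, sp)
        # speciation at the root; the A-side lineage skips the A+B ancestor
        assert dups == 0
        assert losses == 1

    def test_unknown_species_rejected(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        with pytest.raises(TreeError):
            reconcile(gene_tree("(g1_A:1,(g2_B:1,g3_Q:1):1);"), sp)


class TestSelectAndRoot:
    def test_forced_minimum_on_congruent_candidate(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        cand = gene_tree("(g1_A:1,g2_B:1,g3_C:2);")  # unrooted triplet
        best = select_and_root([cand], sp)
        _, dups, losses = reconcile(best, sp)
        assert (dups, losses) == (0, 0)
        # the selected rooting separates C from (A,B)
        top = {leafset(c) for c in best.children}
        assert frozenset({"g3_C"}) in top

    def test_zero_duplication_candidate_preferred(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        good = gene_tree("(g1_A:1,g2_B:1,g3_C:1);")
        bad = gene_tree("(g1_A:1,g3_C:1,g2_B:1);")  # same unrooted tree
        dup_heavy = gene_tree("((g1_A:1,g3_C:1):1,(g2_B:1,g4_A:1):1);")
        best = select_and_root([dup_heavy.children[0], good], sp)
        _, dups, _ = reconcile(best, sp)
        assert dups == 0

    def test_idempotent_on_identical_candidates(self):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        cand = gene_tree("(g1_A:1,g2_B:1,g3_C:2);")
        one = select_and_root([cand], sp)
        three = select_and_root([cand.copy(), cand.copy(), cand.copy()], sp)
        assert one.to_newick(nhx=True) == three.to_newick(nhx=True)

    def test_invariant_to_candidate_order(self):
        sp = SpeciesTree.from_newick("((A,B),(C,D));")
        c1 = gene_tree("(g1_A:1,g2_B:2,(g3_C:1,g4_D:1):1);")
        c2 = gene_tree("(g1_A:2,g3_C:1,(g2_B:1,g4_D:1):1);")
        fwd = select_and_root([c1, c2], sp)
        rev = select_and_root([c2, c1], sp)
        assert fwd.to_newick(nhx=True) == rev.to_newick(nhx=True)


class TestNhxIO:
    def test_single_leaf_form(self, tmp_path):
        leaf = Node(name="g1", species="A")
        p = tmp_path / "t.nhx"
        write_nhx(leaf, p)
        assert p.read_text().strip() == "g1[&&NHX:S=A];"

    def test_roundtrip_preserves_events_species_and_dcs(self, tmp_path):
        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        gt = gene_tree("((g1_A:1,g2_A:1):1,g3_B:1);")
        annotated, _, _ = reconcile(gt, sp)
        p = tmp_path / "t.nhx"
        write_nhx(annotated, p)
        back = read_nhx(p)
        assert back.to_newick(nhx=True) == annotated.to_newick(nhx=True)
        inner = back.children[0]
        assert inner.event == "D"
        assert inner.dcs == 1.0
        assert {l.species for l in back.leaves()} == {"A", "B"}

    def test_dcs_serialized_compactly(self):
        n = Node(children=[Node(name="x_A", species="A"), Node(name="y_A", species="A")])
        n.event = "D"
        n.species = "A"
        n.dcs = 0.5
        assert ":DCS=0.5]" in n.to_newick(nhx=True)

    def test_emitted_newick_parseable_by_dendropy(self, tmp_path):
        import dendropy

        sp = SpeciesTree.from_newick(CONGRUENT_SP)
        gt = gene_tree("((g1_A:1,g2_B:1):1,g3_C:1);")
        annotated, _, _ = reconcile(gt, sp)
        tree = dendropy.Tree.get(
            data=annotated.to_newick(nhx=True), schema="newick",
            suppress_internal_node_taxa=True,
        )
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        # dendropy maps unquoted underscores to spaces per the standard
        assert labels in (["g1 A", "g2 B", "g3 C"], ["g1_A", "g2_B", "g3_C"])

    def test_malformed_nhx_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((a,b)")


class TestRootings:
    def test_every_edge_yields_binary_rooted_tree(self):
        cand = gene_tree("(a_A:1,b_B:1,(c_C:1,d_D:1):1);")
        roots = all_rootings(cand)
        # unrooted quartet: 5 edges
        assert len(roots) == 5
        for r in roots:
            assert sorted(r.leaf_names()) == ["a_A", "b_B", "c_C", "d_D"]
            for n in r.postorder():
                assert len(n.children) in (0, 2)


class TestLeafSpeciesMap:
    def test_longest_suffix_demangling(self):
        out = leaf_species_map(["g1_sp1", "g2_sp10"], ["sp1", "sp10"])
        assert out == {"g1_sp1": "sp1", "g2_sp10": "sp10"}
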