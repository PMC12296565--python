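import itertools

import numpy as np
import pytest

from agarcode.distances import distance_matrix
from agarcode.njboot import (
    _nj_from_matrix,
    bootstrap_support,
    nj_tree,
    species_monophyly,
    write_newick,
)

from _oracles import random_additive_tree
from conftest import make_alignment


def bipartition_set(tree):
    return set(tree.bipartitions())


class TestNJ:
    def test_additive_four_taxon_example(self):
        # AB=5 AC=7 AD=8 BC=8 BD=9 CD=9 -> topology AB|CD, internal branch 1,
        # leaf branches A=2 B=3 C=4 D=5 (four-point condition)
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = _nj_from_matrix(d, ids)
        assert bipartition_set(tree) == {frozenset({"C", "D"})}
        lengths = {leaf.name: leaf.raw_length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})
        (internal,) = [c for c in tree.root.children if not c.is_leaf]
        assert internal.raw_length == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = _nj_from_matrix(d, ("A", "B", "C"))
        lengths = {leaf.name: leaf.raw_length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 4})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            _nj_from_matrix(np.zeros((2, 2)), ("A", "B"))

    def test_tie_rule_deterministic_on_equidistant_matrix(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = _nj_from_matrix(d, ("A", "B", "C", "D"))
        t2 = _nj_from_matrix(d, ("A", "B", "C", "D"))
        assert t1.newick() == t2.newick()
        # lowest-index pair joined first
        assert bipartition_set(t1) == {frozenset({"C", "D"})}

    def test_negative_branch_clamped_raw_retained(self):
        # a non-additive matrix that forces a negative length estimate
        d = np.array(
            [
                [0.0, 0.862, 0.638, 0.356],
                [0.862, 0.0, 0.588, 0.216],
                [0.638, 0.588, 0.0, 0.118],
                [0.356, 0.216, 0.118, 0.0],
            ]
        )
        tree = _nj_from_matrix(d, ("A", "B", "C", "D"))
        raws = [n.raw_length for n in tree.root.leaves()] + [
            c.raw_length for c in tree.root.children if not c.is_leaf
        ]
        clamped = [
            n for n in tree.root.leaves() if n.raw_length < 0 and n.length == 0.0
        ]
        assert any(r < 0 for r in raws)
        assert all(n.length == 0.0 for n in clamped)

    def test_recovers_random_additive_trees(self):
        """NJ on an additive matrix recovers the generating topology and
        reproduces path lengths within 1e-9 (25 random trees, n <= 8)."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            dm, leaves, true_bips = random_additive_tree(rng, n)
            tree = _nj_from_matrix(dm, tuple(leaves))
            assert bipartition_set(tree) == true_bips
            for i, j in itertools.combinations(range(n), 2):
                assert tree.leaf_path_length(leaves[i], leaves[j]) == pytest.approx(
                    dm[i, j], abs=1e-9
                )

    def test_agrees_with_skbio_on_random_matrix(self):
        """Cross-check topology against scikit-bio's independent NJ."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        dm, leaves, _ = random_additive_tree(rng, 7)
        mine = _nj_from_matrix(dm, tuple(leaves))
        ref = skbio.tree.nj(skbio.DistanceMatrix((dm + dm.T) / 2, ids=leaves))
        ref_bips = set()
        full = frozenset(leaves)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(leaves) - 1:
                ref_bips.add(side if "L0" not in side else full - side)
        assert bipartition_set(mine) == ref_bips


class TestBootstrap:
    def test_single_replicate_supports_binary(self, two_species_alignment):
        aln, _ = two_species_alignment
        tree = bootstrap_support(aln, B=1, seed=3)
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_same_seed_reproducible(self, two_species_alignment):
        aln, _ = two_species_alignment
        t1 = bootstrap_support(aln, B=20, seed=7)
        t2 = bootstrap_support(aln, B=20, seed=7)
        assert t1.newick() == t2.newick()

    def test_large_gap_saturates_support(self, two_species_alignment):
        """inter >> intra: the species-separating bipartition reaches >= 95%."""
        aln, _ = two_species_alignment
        tree = bootstrap_support(aln, B=100, seed=1)
        members = frozenset(
            rid for rid, sp in zip(aln.ids, aln.species) if sp == "spB"
        )
        bips = tree.bipartitions()
        assert members in bips
        assert bips[members].support >= 95

    def test_leaf_order_invariance(self):
        # tie-free fixture: every pairwise distance distinct, so the NJ tie
        # rule never engages and the topology is order-independent
        from agarcode.synthgen import SpeciesSpec, SynthConfig, generate_alignment
        from agarcode.distances import distance_matrix

        cfg = SynthConfig(
            marker="matK", length=1000,
            species=(SpeciesSpec("spA", 4, 4), SpeciesSpec("spB", 4, 4)),
            theta_intra=0.02, theta_inter=0.15, seed=12,
        )
        aln, _ = generate_alignment(cfg)
        dm = distance_matrix(aln)
        off = [dm.d[i, j] for i in range(8) for j in range(i + 1, 8)]
        assert len(set(off)) == len(off)
        perm = list(aln.ids[::-1])
        t1 = bootstrap_support(aln, B=10, seed=9)
        t2 = bootstrap_support(aln.subset(perm), B=10, seed=9)
        # canonical bipartitions must coincide (supports may differ by the
        # resampling stream only; same seed + same columns -> same stream)
        s1 = {frozenset(b) for b in t1.bipartitions()}
        full = frozenset(aln.ids)
        s2 = set()
        for b in t2.bipartitions():
            s2.add(b if aln.ids[0] not in b else full - b)
        assert s1 == s2

    def test_invalid_B(self, two_species_alignment):
        aln, _ = two_species_alignment
        with pytest.raises(ValueError):
            bootstrap_support(aln, B=0)


class TestMonophyly:
    def test_clean_and_interleaved_topologies(self):
        aln = make_alignment(
            ["AAAAAAAAAA", "AAAAAAAAAG", "TTTTTTTTTT", "TTTTTTTTTG"],
            species=("a", "a", "b", "b"),
            ids=("a1", "a2", "b1", "b2"),
        )
        tree = nj_tree(distance_matrix(aln))
        mono = species_monophyly(tree, dict(zip(aln.ids, aln.species)))
        assert mono["a"]["monophyletic"] and mono["b"]["monophyletic"]

        aln2 = make_alignment(
            ["AAAAAAAAAA", "TTTTTTTTTA", "AAAAAAAAAG", "TTTTTTTTTG"],
            species=("a", "b", "a", "b"),
            ids=("a1", "b1", "a2", "b2"),
        )
        tree2 = nj_tree(distance_matrix(aln2))
        mono2 = species_monophyly(tree2, dict(zip(aln2.ids, aln2.species)))
        # sequences cluster by the final-column state, not by label
        assert not (mono2["a"]["monophyletic"] and mono2["b"]["monophyletic"])

    def test_singleton_trivially_monophyletic(self, two_species_alignment):
        aln, _ = two_species_alignment
        labels = dict(zip(aln.ids, aln.species))
        labels[aln.ids[0]] = "solo"
        tree = nj_tree(distance_matrix(aln))
        mono = species_monophyly(tree, labels)
        assert mono["solo"] == {"monophyletic": True, "support": None, "n": 1}


class TestNewick:
    def test_three_leaf_shape(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = _nj_from_matrix(d, ("A", "B", "C"))
        assert tree.newick() == "(A:1.000000,B:1.000000,C:1.000000);"

    def test_round_trip_bipartitions_and_supports(self, tmp_path, two_species_alignment):
        skbio = pytest.importorskip("skbio")
        aln, _ = two_species_alignment
        tree = bootstrap_support(aln, B=10, seed=2)
        path = write_newick(tree, tmp_path / "t.nwk")
        back = skbio.TreeNode.read(str(path))
        full = frozenset(aln.ids)
        back_bips = {}
        for node in back.non_tips(include_self=False):
            # newick readers conventionally map underscores to spaces
            side = frozenset(t.name.replace(" ", "_") for t in node.tips())
            if 1 < len(side) < len(aln.ids) - 1:
                key = side if aln.ids[0] not in side else full - side
                back_bips[key] = None if node.name is None else float(node.name)
        mine = {
            bip: node.support for bip, node in tree.bipartitions().items()
        }
        assert set(back_bips) == set(mine)
        for bip, sup in mine.items():
            assert back_bips[bip] == pytest.approx(round(sup), abs=0.5)
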