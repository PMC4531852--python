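import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj as skbio_nj

from gssualign.gssu import decompose
from gssualign.multiple import (AverageStructure, DistanceMatrix,
                                MultiAlignError, distance_matrix,
                                merge_structures, nj_tree, progressive_align)
from gssualign.superpose import align_structures
from gssualign.synthetic import (HairpinSpec, SynthSpec, make_family,
                                 make_multi_hairpin)


def _family(n, sigma=0.3, seeds=None):
    base, bp = make_multi_hairpin(
        SynthSpec([HairpinSpec(4, 4), HairpinSpec(5, 4)], linker_nt=[3]),
        structure_id="fam")
    members = make_family(base, sigma, seeds or list(range(1, n + 1)))
    return members, [bp] * n


def _bipartitions(root: TreeNode) -> set[frozenset]:
    leaves = frozenset(t.name for t in root.tips())
    parts = set()
    for node in root.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(leaves) - 1:
            parts.add(min(below, leaves - below, key=sorted))
    return parts


def _random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths + its leaf matrix."""
    nodes = [TreeNode(name=f"L{k}") for k in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        nodes.append(TreeNode(children=[a, b]))
    root = nodes[0]
    names = [f"L{k}" for k in range(n_leaves)]
    tips = {t.name: t for t in root.tips()}
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            dist = tips[names[i]].distance(tips[names[j]])
            d[i, j] = d[j, i] = dist
    return root, DistanceMatrix(names, d)


class TestDistanceMatrix:
    def test_pair_count_and_symmetry(self):
        members, pairs = _family(4)
        dm = distance_matrix(members, pairs_list=pairs)
        assert dm.n_alignments == 6
        assert np.array_equal(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)

    def test_identical_copies_give_zero_matrix(self):
        members, pairs = _family(3, sigma=0.0)
        dm = distance_matrix(members, pairs_list=pairs)
        assert np.all(dm.d == 0.0)

    def test_thread_count_does_not_change_result(self):
        members, pairs = _family(5)
        d1 = distance_matrix(members, threads=1, pairs_list=pairs)
        d4 = distance_matrix(members, threads=4, pairs_list=pairs)
        assert d1.d.tobytes() == d4.d.tobytes()

    def test_single_structure_rejected(self):
        members, pairs = _family(2)
        with pytest.raises(MultiAlignError):
            distance_matrix(members[:1])


class TestNeighborJoining:
    def test_two_leaves_split_evenly(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = nj_tree(dm)
        tips = {t.name: t.length for t in tree.root.tips()}
        assert tips == {"a": 1.5, "b": 1.5}
        assert tree.merge_order == [(frozenset(["a"]), frozenset(["b"]))]

    def test_three_leaves_closed_form(self):
        d_ab, d_ac, d_bc = 4.0, 6.0, 8.0
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, d_ab, d_ac],
                                      [d_ab, 0, d_bc],
                                      [d_ac, 0 + d_bc, 0]], dtype=float))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_matrix_recovery(self, seed):
        rng = np.random.default_rng(seed)
        true_tree, dm = _random_additive_tree(rng, int(rng.integers(4, 9)))
        est = nj_tree(dm)
        assert _bipartitions(est.root) == _bipartitions(true_tree)
        tips = {t.name: t for t in est.root.tips()}
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                assert tips[a].distance(tips[dm.ids[j]]) == pytest.approx(
                    dm.d[i, j], abs=1e-9)

    def test_agrees_with_skbio_reference(self):
        rng = np.random.default_rng(123)
        _, dm = _random_additive_tree(rng, 6)
        ours = nj_tree(dm)
        ref = skbio_nj(SkbioDM(dm.d, ids=dm.ids))
        assert _bipartitions(ours.root) == _bipartitions(ref)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(MultiAlignError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]])))
        with pytest.raises(MultiAlignError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]])))


class TestMerging:
    def test_self_merge_preserves_coordinates(self):
        members, pairs = _family(2, sigma=0.0)
        a = AverageStructure.from_structure(members[0], pairs[0])
        b = AverageStructure.from_structure(members[1], pairs[1])
        merged = merge_structures(a, b)
        assert merged.weight == 2
        assert np.array_equal(merged.structure.rep_points(),
                              members[0].rep_points())

    def test_matched_points_move_to_midpoint(self):
        members, pairs = _family(2, sigma=0.0)
        shifted = members[1].transformed(np.eye(3), np.zeros(3))
        for r in shifted.residues:
            r.rep_point = r.rep_point + np.array([2.0, 0, 0])
            for name in r.atoms:
                r.atoms[name] = r.atoms[name] + np.array([2.0, 0, 0])
        a = AverageStructure.from_structure(members[0], pairs[0])
        b = AverageStructure.from_structure(shifted, pairs[1])
        merged = merge_structures(a, b)
        # the optimal alignment removes the rigid offset entirely, so the
        # average coincides with a up to rounding
        assert np.allclose(merged.structure.rep_points(),
                           members[0].rep_points(), atol=1e-9)

    def test_weighted_mean_arithmetic(self):
        members, pairs = _family(3, sigma=0.2, seeds=[1, 2, 3])
        a = AverageStructure.from_structure(members[0], pairs[0])
        b = AverageStructure.from_structure(members[1], pairs[1])
        c = AverageStructure.from_structure(members[2], pairs[2])
        ab = merge_structures(a, b)
        abc = merge_structures(ab, c)
        assert abc.weight == 3
        res = align_structures(ab.structure, c.structure,
                               decompose(ab.structure, ab.pairs),
                               decompose(c.structure, c.pairs))
        ct = c.structure.transformed(res.superposition.rotation,
                                     res.superposition.translation)
        for i, j in res.superposition.pairs:
            expected = (2 * ab.structure.residues[i].rep_point
                        + ct.residues[j].rep_point) / 3
            assert np.allclose(abc.structure.residues[i].rep_point,
                               expected, atol=1e-12)


class TestProgressive:
    def test_two_structures_have_equal_distance_to_average(self):
        members, pairs = _family(2)
        result = progressive_align(members, pairs_list=pairs)
        (ida, ra), (idb, rb) = result.per_member
        assert ra.s_distance == pytest.approx(rb.s_distance, abs=1e-9)

    def test_identical_copies_average_exactly(self):
        members, pairs = _family(4, sigma=0.0)
        result = progressive_align(members, pairs_list=pairs)
        dev = np.abs(result.average.structure.rep_points()
                     - members[0].rep_points()).max()
        assert dev == 0.0
        assert all(res.s_distance == 0.0 for _, res in result.per_member)
        assert result.average.weight == 4

    def test_average_not_worse_than_worst_pair(self):
        members, pairs = _family(4, sigma=0.3, seeds=[1, 2, 3, 4])
        result = progressive_align(members, pairs_list=pairs)
        dm = result.distance_matrix
        decomps = [decompose(m, pairs[0]) for m in members]
        worst = max(
            align_structures(members[i], members[j], decomps[i],
                             decomps[j]).quality.rmsd_phosphate
            for i in range(4) for j in range(i + 1, 4))
        for _, res in result.per_member:
            assert res.quality.rmsd_phosphate <= worst

    def test_report_order_is_descending(self):
        members, pairs = _family(5, sigma=0.35, seeds=[3, 5, 8, 13, 21])
        result = progressive_align(members, pairs_list=pairs)
        dists = [res.s_distance for _, res in result.per_member]
        assert dists == sorted(dists, reverse=True)

    def test_input_permutation_changes_only_labels(self):
        members, pairs = _family(4, sigma=0.3, seeds=[1, 2, 3, 4])
        fwd = progressive_align(members, pairs_list=pairs)
        perm = [2, 0, 3, 1]
        rev = progressive_align([members[k] for k in perm],
                                pairs_list=[pairs[k] for k in perm])
        d_fwd = {sid: res.s_distance for sid, res in fwd.per_member}
        d_rev = {sid: res.s_distance for sid, res in rev.per_member}
        assert d_fwd.keys() == d_rev.keys()
        for sid in d_fwd:
            assert d_fwd[sid] == pytest.approx(d_rev[sid], abs=1e-9)

    def test_newick_and_phylip_exports(self, tmp_path):
        members, pairs = _family(4)
        result = progressive_align(members, pairs_list=pairs)
        nwk = tmp_path / "t.nwk"
        nwk.write_text(result.tree.to_newick())
        reread = TreeNode.read(str(nwk))
        assert {t.name for t in reread.tips()} == {m.id for m in members}
        phylip = result.distance_matrix.to_phylip()
        lines = phylip.strip().splitlines()
        assert lines[0].strip() == "4"
        assert len(lines) == 5
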