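import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gssualign.gssu import decompose
from gssualign.superpose import (AlignmentError, AlignParams, Superposition,
                                 align_structures, kabsch_fit,
                                 refine_mutual_nn, seed_gssu_superposition,
                                 _anchors_and_candidates, _score_seed)
from gssualign.synthetic import (HairpinSpec, SynthSpec, make_hairpin,
                                 make_multi_hairpin)

from conftest import random_rigid_motion


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        sup = kabsch_fit(pts, pts)
        assert np.array_equal(sup.rotation, np.eye(3))
        assert np.array_equal(sup.translation, np.zeros(3))
        assert sup.rmsd == 0.0

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        shift = np.array([1.0, 2.0, 3.0])
        sup = kabsch_fit(pts, pts + shift)
        assert sup.rmsd < 1e-9
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, -shift, atol=1e-9)

    def test_matches_numerical_minimum_on_noisy_points(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(10, 3))
        R, t = random_rigid_motion(rng)
        b = (a - 0.1 * rng.normal(size=(10, 3))) @ R.T + t
        fitted = kabsch_fit(a, b).rmsd

        ac, bc = a - a.mean(0), b - b.mean(0)

        def objective(rotvec):
            m = Rotation.from_rotvec(rotvec).as_matrix()
            d = ac - bc @ m.T
            return np.sqrt(np.mean(np.sum(d * d, axis=1)))

        best = min(minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 5000}).fun
                   for x0 in [np.zeros(3), [1, 0, 0], [0, 2, 0], [1, 1, 1]])
        assert fitted <= best + 1e-6

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(3)
        sup = kabsch_fit(rng.normal(size=(7, 3)), rng.normal(size=(7, 3)))
        assert np.abs(sup.rotation @ sup.rotation.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_errors(self):
        pts = np.zeros((4, 3))
        with pytest.raises(AlignmentError):
            kabsch_fit(pts, np.zeros((5, 3)))
        with pytest.raises(AlignmentError):
            kabsch_fit(pts[:2], pts[:2])


class TestSeeding:
    def test_self_seed_is_exact(self, decomposed_hairpin):
        s, _, gssus = decomposed_hairpin
        sup = seed_gssu_superposition(gssus[0], gssus[0], s, s)
        assert sup.rmsd == 0.0
        assert all(i == j for i, j in sup.pairs)

    def test_rigid_copy_recovered(self, decomposed_hairpin):
        s, pairs, gssus = decomposed_hairpin
        R, t = random_rigid_motion(np.random.default_rng(5))
        moved = s.transformed(R, t, new_id="moved")
        gm = decompose(moved, pairs)
        sup = seed_gssu_superposition(gssus[0], gm[0], s, moved)
        assert sup.rmsd < 1e-6
        assert np.allclose(sup.rotation, R.T, atol=1e-6)

    def test_exhaustive_loop_pair_oracle(self):
        sa, pa = make_hairpin(4, 4, structure_id="a")
        sb, pb = make_hairpin(4, 6, noise_sigma=0.2, seed=3, structure_id="b")
        ga = decompose(sa, pa)[0]
        gb = decompose(sb, pb)[0]
        sup = seed_gssu_superposition(ga, gb, sa, sb)

        anchors_a, cand_a = _anchors_and_candidates(ga)
        anchors_b, cand_b = _anchors_and_candidates(gb)
        assert len(cand_a) * len(cand_b) == 24
        scores = [_score_seed(ga, gb, sa.rep_points(), sb.rep_points(),
                              anchors_a, anchors_b, u, v)[0]
                  for u in cand_a for v in cand_b]
        assert sup.rmsd == pytest.approx(min(scores), abs=1e-12)


class TestAlign:
    def test_self_alignment_is_exactly_zero(self, decomposed_hairpin):
        s, _, gssus = decomposed_hairpin
        res = align_structures(s, s, gssus, gssus)
        assert res.s_distance == 0.0
        assert res.quality.rmsd_phosphate == 0.0
        assert res.quality.psi == 100.0
        assert res.quality.pid == 100.0

    def test_rigid_copy_alignment(self, three_hairpin):
        s, pairs = three_hairpin
        gssus = decompose(s, pairs)
        R, t = random_rigid_motion(np.random.default_rng(11))
        moved = s.transformed(R, t, new_id="moved")
        gm = decompose(moved, pairs)
        res = align_structures(s, moved, gssus, gm)
        assert res.s_distance < 1e-6
        assert np.allclose(res.superposition.rotation @ R, np.eye(3), atol=1e-6)

    def test_best_seed_avoids_perturbed_hairpin(self):
        spec = SynthSpec([HairpinSpec(4, 4), HairpinSpec(4, 4),
                          HairpinSpec(4, 4)], linker_nt=[3, 3])
        sa, pa = make_multi_hairpin(spec, structure_id="ref")
        sb = sa.copy("pert")
        gssus_a = decompose(sa, pa)
        rng = np.random.default_rng(9)
        # perturb only the middle hairpin's loop
        for r in gssus_a[1].loop:
            res = sb.residues[r]
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(0, 0.5, 3)
            res.rep_point = res.atoms["P"].copy()
        gssus_b = decompose(sb, pa)
        result = align_structures(sa, sb, gssus_a, gssus_b)
        assert result.best_gssu_pair[0] != 1

        best = np.inf
        for ga in gssus_a:
            for gb in gssus_b:
                sup = seed_gssu_superposition(ga, gb, sa, sb)
                best = min(best, sup.rmsd)
        chosen = seed_gssu_superposition(gssus_a[result.best_gssu_pair[0]],
                                         gssus_b[result.best_gssu_pair[1]],
                                         sa, sb)
        assert chosen.rmsd == pytest.approx(best, abs=1e-12)

    def test_symmetry_is_exact(self):
        sa, pa = make_hairpin(5, 4, structure_id="aa")
        sb, pb = make_hairpin(5, 5, noise_sigma=0.3, seed=4, structure_id="bb")
        ga, gb = decompose(sa, pa), decompose(sb, pb)
        fwd = align_structures(sa, sb, ga, gb)
        rev = align_structures(sb, sa, gb, ga)
        assert fwd.s_distance == rev.s_distance
        assert fwd.quality.psi == rev.quality.psi
        assert fwd.best_gssu_pair == rev.best_gssu_pair[::-1]


class TestRefine:
    def test_fixed_point_on_identical_structures(self, decomposed_hairpin):
        s, _, gssus = decomposed_hairpin
        start = Superposition(np.eye(3), np.zeros(3))
        out = refine_mutual_nn(s, s, start)
        assert out.rmsd == 0.0
        assert out.converged

    def test_offset_start_converges(self, decomposed_hairpin):
        s, _, _ = decomposed_hairpin
        start = Superposition(np.eye(3), np.array([2.0, 0.0, 0.0]))
        out = refine_mutual_nn(s, s, start)
        assert out.rmsd < 1e-6
        idx_a = [i for i, _ in out.pairs]
        idx_b = [j for _, j in out.pairs]
        start_rmsd = np.sqrt(np.mean(np.sum(
            (s.rep_points()[idx_a] - start.apply(s.rep_points())[idx_b]) ** 2,
            axis=1)))
        assert out.rmsd <= start_rmsd

    def test_too_few_mutual_pairs_sets_warning(self, decomposed_hairpin):
        s, _, _ = decomposed_hairpin
        far = s.copy("far")
        for k, r in enumerate(far.residues):
            if k >= 2:  # only two residues stay near the original
                for name in r.atoms:
                    r.atoms[name] = r.atoms[name] + np.array([500.0, 0, 0])
                r.rep_point = r.atoms["P"].copy()
        start = Superposition(np.eye(3), np.zeros(3))
        out = refine_mutual_nn(s, far, start)
        assert not out.converged
        assert np.array_equal(out.rotation, start.rotation)
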