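"""Basis formation, reduction, selection, refinement and end-to-end indexing."""

import numpy as np
import pytest

from snapindex.geometry import NodeSet
from snapindex.lattice import (
    CandidateBasis,
    IndexingConfig,
    LatticeBasis,
    SelectionConfig,
    compute_defects,
    count_predicted,
    enumerate_candidate_bases,
    fractional_indices,
    index,
    reduce_basis,
    refine_basis,
    select_lattices,
)
from snapindex.search import CandidatePeak, SearchVolume
from snapindex.synthetic import (
    SceneParams,
    bases_equivalent,
    simulate_scene,
)
from tests.conftest import brute_force_minima, hkl_ball, random_reduced_lattice


class TestFractionalIndices:
    def test_cubic_axis(self):
        basis = LatticeBasis(np.diag([10.0, 10.0, 10.0]))
        assert np.allclose(
            fractional_indices(basis, np.array([0.1, 0.0, 0.0])), [1, 0, 0]
        )
        assert np.allclose(fractional_indices(basis, np.zeros(3)), 0.0)

    def test_round_trip_through_reciprocal(self, rng):
        for _ in range(20):
            basis = random_reduced_lattice(rng)
            hkl = rng.integers(-5, 6, size=(10, 3)).astype(float)
            q = hkl @ basis.reciprocal_rows
            rec = fractional_indices(basis, q)
            assert np.allclose(rec, hkl, atol=1e-10)

    def test_singular_basis_errors(self):
        with pytest.raises(ValueError, match="singular"):
            fractional_indices(LatticeBasis(np.zeros((3, 3))), np.zeros(3))


class TestCountPredicted:
    def test_own_nodes_all_counted(self, cubic_nodes):
        basis, nodes = cubic_nodes
        n, asg = count_predicted(basis, nodes, 0.05)
        assert n == nodes.K
        assert asg.assigned.all()

    def test_zero_tolerance_random_nodes(self, rng):
        basis = random_reduced_lattice(rng)
        nodes = NodeSet(rng.uniform(-0.2, 0.2, (30, 3)))
        n, _ = count_predicted(basis, nodes, 0.0)
        assert n == 0

    def test_noisy_lattice_with_margin(self, rng):
        basis = random_reduced_lattice(rng)
        hkl = rng.integers(-4, 5, size=(20, 3)).astype(float)
        q = hkl @ basis.reciprocal_rows
        # fractional noise 0.05 on the lattice nodes
        frac_noise = rng.uniform(-0.05, 0.05, (20, 3))
        q_noisy = (hkl + frac_noise) @ basis.reciprocal_rows
        # spurious nodes at fractional offsets in [0.3, 0.5]: outside tol 0.15
        spur_frac = rng.integers(-3, 4, size=(5, 3)) + rng.choice(
            [-1, 1], (5, 3)
        ) * rng.uniform(0.3, 0.5, (5, 3))
        q_spur = spur_frac @ basis.reciprocal_rows
        nodes = NodeSet(np.vstack([q_noisy, q_spur]))
        n, asg = count_predicted(basis, nodes, 0.15)
        assert n == 20
        assert asg.assigned[:20].all() and not asg.assigned[20:].any()


class TestReduceBasis:
    def test_orthogonal_fixed_point(self):
        basis = LatticeBasis(np.diag([10.0, 12.0, 15.0]))
        red = reduce_basis(basis)
        assert np.allclose(np.sort(red.lengths), [10.0, 12.0, 15.0])
        assert red.determinant > 0

    def test_recovers_short_vectors_from_skewed(self):
        a = np.array([10.0, 0, 0])
        b = np.array([0, 12.0, 0])
        c = np.array([0, 0, 15.0])
        skew = LatticeBasis(np.array([a, b, a + b + c]))
        red = reduce_basis(skew)
        assert np.allclose(np.sort(red.lengths), [10.0, 12.0, 15.0], atol=1e-9)

    def test_matches_successive_minima(self, rng):
        for _ in range(60):
            basis = random_reduced_lattice(rng)
            red = reduce_basis(basis)
            target = brute_force_minima(basis.matrix)
            assert np.allclose(np.sort(red.lengths), target, rtol=1e-9)

    def test_determinant_preserved_and_unimodular(self, rng):
        for _ in range(60):
            basis = random_reduced_lattice(rng)
            red = reduce_basis(basis)
            assert abs(red.determinant) == pytest.approx(
                abs(basis.determinant), rel=1e-9
            )
            # transform expressing reduced rows in the original basis
            u = red.matrix @ np.linalg.inv(basis.matrix)
            assert np.allclose(u, np.round(u), atol=1e-6)
            assert abs(np.linalg.det(np.round(u))) == pytest.approx(1.0)

    def test_singular_errors(self):
        with pytest.raises(ValueError, match="singular"):
            reduce_basis(LatticeBasis(np.array([[1.0, 0, 0], [2.0, 0, 0], [0, 0, 1.0]])))


class TestDefects:
    def test_noise_free_scene_zero_defects(self, cubic_nodes):
        basis, nodes = cubic_nodes
        rep = compute_defects(basis, nodes, 0.1)
        assert rep.absolute_defect == pytest.approx(0.0, abs=1e-12)
        assert rep.relative_defect == pytest.approx(0.0, abs=1e-12)
        assert rep.n_predicted == nodes.K

    def test_single_node_offset(self):
        basis = LatticeBasis(np.diag([10.0, 10.0, 10.0]))
        q = np.array([[0.11, 0.0, 0.0]])  # fractional offset (0.1, 0, 0)
        rep = compute_defects(basis, NodeSet(q), 0.15)
        assert rep.relative_defect == pytest.approx(0.1, abs=1e-12)
        assert rep.absolute_defect == pytest.approx(0.01, abs=1e-12)

    def test_dual_formulation_agreement(self, rng):
        # absolute defect via reciprocal rows vs via a pseudo-inverse solve
        basis = random_reduced_lattice(rng)
        hkl = rng.integers(-4, 5, (15, 3)) + rng.uniform(-0.1, 0.1, (15, 3))
        nodes = NodeSet(hkl @ basis.reciprocal_rows)
        rep = compute_defects(basis, nodes, 0.15)
        F = nodes.q @ basis.matrix.T
        H = np.round(F)
        q_pred = np.linalg.solve(basis.matrix, H.T).T
        direct = np.linalg.norm(nodes.q - q_pred, axis=1).mean()
        assert rep.absolute_defect == pytest.approx(direct, abs=1e-10)

    def test_no_predictions_inf_sentinel(self, rng):
        basis = LatticeBasis(np.diag([10.0, 10.0, 10.0]))
        nodes = NodeSet(np.array([[0.135, 0.027, 0.046]]))
        rep = compute_defects(basis, nodes, 0.01)
        assert rep.n_predicted == 0
        assert np.isinf(rep.absolute_defect)


def peaks_from_vectors(vectors, score=1.0):
    return [
        CandidatePeak(position=np.asarray(v, dtype=float), score=score, inliers=25)
        for v in vectors
    ]


class TestEnumerateCandidates:
    def test_true_triple_survives(self, cubic_nodes):
        basis, nodes = cubic_nodes
        peaks = peaks_from_vectors(basis.matrix)
        cands = enumerate_candidate_bases(peaks, nodes)
        assert len(cands) == 1
        assert abs(cands[0].basis.determinant) == pytest.approx(40.0**3, rel=1e-6)

    def test_coplanar_triple_rejected(self, cubic_nodes):
        basis, nodes = cubic_nodes
        a, b, _ = basis.matrix
        peaks = peaks_from_vectors([a, b, a + b])
        assert enumerate_candidate_bases(peaks, nodes) == []

    def test_low_predicting_vector_dropped(self, cubic_nodes):
        basis, nodes = cubic_nodes
        rogue = np.array([33.3, 17.7, 21.1])  # not a lattice vector
        peaks = peaks_from_vectors([*basis.matrix, rogue])
        cands = enumerate_candidate_bases(peaks, nodes)
        for c in cands:
            assert not any(np.allclose(row, rogue) for row in c.basis.matrix)

    def test_cap_at_500(self, cubic_nodes, rng):
        basis, nodes = cubic_nodes
        combos = hkl_ball(1).astype(float) @ basis.matrix
        peaks = peaks_from_vectors(combos, score=1.0)
        cands = enumerate_candidate_bases(peaks, nodes)
        assert 0 < len(cands) <= 500

    def test_fewer_than_three_peaks(self, cubic_nodes):
        _, nodes = cubic_nodes
        assert enumerate_candidate_bases(peaks_from_vectors([[40, 0, 0]]), nodes) == []


class TestSelectLattices:
    def test_supercell_trap_prefers_small_determinant(self, cubic_nodes):
        basis, nodes = cubic_nodes
        true_cand = CandidateBasis(basis=basis, score=3.0)
        super_cand = CandidateBasis(basis=LatticeBasis(2.0 * basis.matrix), score=3.0)
        sols = select_lattices([super_cand, true_cand], nodes)
        assert len(sols) == 1
        assert abs(sols[0].basis.determinant) == pytest.approx(
            abs(basis.determinant), rel=1e-6
        )

    def test_single_lattice_scene(self, cubic_nodes):
        basis, nodes = cubic_nodes
        peaks = peaks_from_vectors(hkl_ball(1).astype(float) @ basis.matrix)
        cands = enumerate_candidate_bases(peaks, nodes)
        sols = select_lattices(cands, nodes)
        assert len(sols) == 1
        assert bases_equivalent(sols[0].basis, basis)

    def test_no_duplicate_lattices(self, bench_config):
        scene = simulate_scene(SceneParams(n_lattices=2), seed=5)
        sols = index(scene.nodes, bench_config, seed=5)
        for i in range(len(sols)):
            for j in range(i + 1, len(sols)):
                assert not bases_equivalent(sols[i].basis, sols[j].basis)

    def test_empty_candidates(self, cubic_nodes):
        _, nodes = cubic_nodes
        assert select_lattices([], nodes) == []


class TestRefineBasis:
    def test_noise_free_no_op(self, cubic_nodes):
        basis, nodes = cubic_nodes
        refined = refine_basis(basis, nodes)
        assert np.allclose(refined.matrix, basis.matrix, atol=1e-9)

    def test_defect_not_worse_after_refinement(self, rng):
        scene = simulate_scene(
            SceneParams(n_nodes=30).with_noise_fraction(0.01), seed=7
        )
        true = scene.true_bases[0]
        strain = np.eye(3) + 0.01 * rng.standard_normal((3, 3))
        perturbed = LatticeBasis(true.matrix @ strain.T)
        before = compute_defects(perturbed, scene.nodes, 0.15)
        refined = refine_basis(perturbed, scene.nodes)
        after = compute_defects(refined, scene.nodes, 0.15)
        assert after.absolute_defect <= before.absolute_defect + 1e-15

    def test_too_few_inliers_returns_input(self, rng):
        basis = LatticeBasis(np.diag([10.0, 10.0, 10.0]))
        nodes = NodeSet(rng.uniform(0.31, 0.44, (6, 3)))  # nothing assignable
        out = refine_basis(basis, nodes)
        assert np.allclose(out.matrix, basis.matrix)


class TestIndexEndToEnd:
    def test_clean_scene_unknown_cell(self, bench_config):
        scene = simulate_scene(SceneParams(), seed=42)
        sols = index(scene.nodes, bench_config, seed=42)
        assert len(sols) == 1
        assert bases_equivalent(sols[0].basis, scene.true_bases[0])
        assert sols[0].defects.n_predicted >= 5

    def test_known_cell_prior(self):
        scene = simulate_scene(SceneParams().with_noise_fraction(0.01), seed=43)
        cfg = IndexingConfig(known_cell=SceneParams().cell)
        sols = index(scene.nodes, cfg, seed=43)
        assert len(sols) >= 1
        assert bases_equivalent(sols[0].basis, scene.true_bases[0])
        # reported cell agrees with the prior
        red = reduce_basis(sols[0].basis)
        assert np.allclose(np.sort(red.lengths), [35.0, 45.0, 60.0], rtol=0.02)

    def test_pure_noise_scene_empty(self, bench_config, rng):
        nodes = NodeSet(rng.uniform(-0.2, 0.2, (25, 3)))
        sols = index(nodes, bench_config, seed=0)
        assert sols == []

    def test_too_few_nodes_is_no_solution(self, bench_config, rng):
        nodes = NodeSet(rng.uniform(-0.2, 0.2, (4, 3)))
        assert index(nodes, bench_config, seed=0) == []

    def test_delete_and_retry_two_lattices(self, bench_volume):
        scene = simulate_scene(
            SceneParams(n_lattices=2).with_noise_fraction(0.01), seed=9
        )
        cfg = IndexingConfig(volume=bench_volume, mode="delete_and_retry")
        sols = index(scene.nodes, cfg, seed=9)
        assert len(sols) == 2
        hits = [
            any(bases_equivalent(s.basis, t) for s in sols) for t in scene.true_bases
        ]
        assert all(hits)
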