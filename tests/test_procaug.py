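"""Procrustes alignment, Euler round-trips and the augmentation policy."""

import numpy as np
import pytest

from aortavae.procaug import (
    AugmentPolicy,
    apply_augmentation,
    euler_from_rotation,
    fit_policy,
    procrustes_rotation,
    rotation_from_euler,
    sample_augmentation,
    unit_normalize,
)
from aortavae.synthetic_aaa import ShapeParams, TemplateSpec, generate_dataset, generate_mesh


class TestUnitNormalize:
    def test_scales_to_unit_norm(self, rng):
        m = 5.0 * unit_normalize(rng.normal(size=(20, 3)))
        assert np.linalg.norm(unit_normalize(m)) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        m = unit_normalize(rng.normal(size=(10, 3)))
        assert np.allclose(unit_normalize(m), m, atol=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            unit_normalize(np.zeros((4, 3)))


class TestEuler:
    def test_identity(self):
        assert np.allclose(rotation_from_euler(0, 0, 0), np.eye(3))
        assert euler_from_rotation(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_pure_z_rotation(self):
        r = rotation_from_euler(0, 0, np.pi / 6)
        psi, xi, gamma = euler_from_rotation(r)
        assert (psi, xi) == (0.0, 0.0)
        assert gamma == pytest.approx(np.pi / 6, abs=1e-12)

    def test_half_turn_about_x(self):
        assert np.allclose(rotation_from_euler(np.pi, 0, 0),
                           np.diag([1.0, -1.0, -1.0]), atol=1e-12)

    def test_det_one(self, rng):
        for _ in range(50):
            r = rotation_from_euler(*rng.uniform(-np.pi, np.pi, 3))
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_500_random_triples(self, rng):
        """compose -> decompose -> recompose matches within 1e-8 (away from
        gimbal lock)."""
        lim = np.deg2rad(85)
        for _ in range(500):
            psi, gamma = rng.uniform(-np.pi, np.pi, 2)
            xi = rng.uniform(-lim, lim)
            r = rotation_from_euler(psi, xi, gamma)
            r2 = rotation_from_euler(*euler_from_rotation(r))
            assert np.abs(r2 - r).max() < 1e-8

    def test_gimbal_lock_convention(self):
        r = rotation_from_euler(0.3, np.pi / 2, 0.2)
        psi, xi, gamma = euler_from_rotation(r)
        assert gamma == 0.0
        assert np.abs(rotation_from_euler(psi, xi, gamma) - r).max() < 1e-8


class TestProcrustes:
    def test_self_alignment_identity(self, rng):
        m = rng.normal(size=(30, 3))
        res = procrustes_rotation(m, m)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert res.residual < 1e-10

    def test_recovers_planted_rotation(self, rng):
        for _ in range(100):
            m = rng.normal(size=(25, 3))
            r = rotation_from_euler(*rng.uniform(-1.2, 1.2, 3))
            res = procrustes_rotation(unit_normalize(m), unit_normalize(m @ r),
                                      center=False)
            assert np.abs(res.rotation - r).max() < 1e-8

    def test_rotation_is_proper_and_orthogonal(self, rng):
        m = rng.normal(size=(40, 3))
        ref = rng.normal(size=(40, 3))
        res = procrustes_rotation(m, ref)
        assert np.allclose(res.rotation.T @ res.rotation, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_svd_solution_never_beaten_by_random_rotations(self, rng):
        """Optimality: the analytic optimum lower-bounds 1000 random
        rotations, checked over many random pairs."""
        for _ in range(100):
            m = unit_normalize(rng.normal(size=(12, 3)))
            ref = unit_normalize(rng.normal(size=(12, 3)))
            res = procrustes_rotation(m, ref, center=False)
            angles = rng.uniform(-np.pi, np.pi, size=(1000, 3))
            for a in angles[:: 100]:  # spot-check a deterministic subsample
                r = rotation_from_euler(*a)
                assert res.residual <= np.linalg.norm(m @ r - ref) + 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_rotation(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestFitPolicy:
    def test_single_mesh_degenerate_policy(self, small_tube):
        with pytest.warns(RuntimeWarning):
            pol = fit_policy([small_tube])
        assert pol.psi_range == pytest.approx((0.0, 0.0), abs=1e-12)
        norm = np.linalg.norm(
            small_tube.vertices - small_tube.vertices.mean(axis=0))
        assert pol.norm_range == pytest.approx((norm, norm))

    def test_planted_z_rotations_recovered(self, small_tube):
        base = small_tube.vertices - small_tube.vertices.mean(axis=0)
        dataset = [base]
        for deg in (-10.0, 10.0):
            r = rotation_from_euler(0, 0, np.deg2rad(deg))
            dataset.append(base @ r.T)
        pol = fit_policy(dataset, reference=base)
        lo, hi = np.rad2deg(pol.gamma_range)
        assert lo == pytest.approx(-10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)
        assert abs(np.rad2deg(pol.psi_range[0])) < 1e-6
        assert abs(np.rad2deg(pol.xi_range[1])) < 1e-6

    def test_planted_scales_bound_norm_range(self):
        """Norm range endpoints track the planted global-scale span."""
        ranges = {"global_scale": (0.8, 1.2), "noise_sd": (0.0, 0.0),
                  "global_rotation": (0.0, 0.0)}
        meshes, params = generate_dataset(n=25, seed=5, ranges=ranges)
        pol = fit_policy(meshes)
        norms = [np.linalg.norm(m.vertices - m.vertices.mean(axis=0))
                 for m in meshes]
        assert pol.norm_range[0] == pytest.approx(min(norms), abs=1e-8)
        assert pol.norm_range[1] == pytest.approx(max(norms), abs=1e-8)


class TestAugmentation:
    def test_transform_type_frequencies(self, rng):
        """30,000 draws: each branch within the 3-sigma binomial band of 1/3."""
        pol = AugmentPolicy(norm_range=(1.0, 2.0))
        counts = {"identity": 0, "scale": 0, "rotation": 0}
        for _ in range(30_000):
            counts[sample_augmentation(pol, rng).kind] += 1
        for k, c in counts.items():
            assert 0.323 <= c / 30_000 <= 0.344, k

    def test_zero_width_rotation_is_identity(self, rng):
        pol = AugmentPolicy(norm_range=(1.0, 1.0))
        for _ in range(30):
            t = sample_augmentation(pol, rng)
            if t.kind == "rotation":
                assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_same_seed_same_sequence(self):
        pol = AugmentPolicy(psi_range=(-0.5, 0.5), norm_range=(1.0, 2.0))
        seq1 = [sample_augmentation(pol, np.random.default_rng(9)).kind
                for _ in range(20)]
        seq2 = [sample_augmentation(pol, np.random.default_rng(9)).kind
                for _ in range(20)]
        assert seq1 == seq2

    def test_scale_sets_exact_norm(self, small_tube, rng):
        from aortavae.procaug import Transform

        out = apply_augmentation(small_tube, Transform("scale", scale=2.0))
        assert np.linalg.norm(out.vertices) == pytest.approx(2.0, abs=1e-12)
        assert np.array_equal(out.faces, small_tube.faces)

    def test_rotation_is_isometry(self, small_tube, rng):
        from aortavae.procaug import Transform

        r = rotation_from_euler(*rng.uniform(-1, 1, 3))
        out = apply_augmentation(small_tube, Transform("rotation", rotation=r))
        v0, v1 = small_tube.vertices, out.vertices
        idx = rng.integers(0, len(v0), size=(50, 2))
        d0 = np.linalg.norm(v0[idx[:, 0]] - v0[idx[:, 1]], axis=1)
        d1 = np.linalg.norm(v1[idx[:, 0]] - v1[idx[:, 1]], axis=1)
        assert np.abs(d0 - d1).max() < 1e-10

    def test_identity_unchanged(self, small_tube):
        from aortavae.procaug import Transform

        out = apply_augmentation(small_tube, Transform("identity"))
        assert np.array_equal(out.vertices, small_tube.vertices)
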