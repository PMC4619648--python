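"""Kabsch superposition and ICP registration."""

import numpy as np
import pytest
import trimesh

from braincast import (
    RigidTransform,
    apply_transform,
    default_init,
    icp_register,
    kabsch,
)


def rms(P, Q):
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


class TestRigidTransform:
    def test_compose_inverse_is_identity(self):
        T = RigidTransform.from_euler_deg((20, -35, 50), (1, 2, 3))
        I = T.compose(T.inverse())
        assert np.allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(I.translation, 0, atol=1e-12)

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_json_round_trip(self, tmp_path):
        T = RigidTransform.from_euler_deg((5, 10, -15), (0.1, -0.2, 0.3))
        T.to_json(tmp_path / "T.json")
        back = RigidTransform.from_json(tmp_path / "T.json")
        assert np.allclose(back.rotation, T.rotation)
        assert np.allclose(back.translation, T.translation)


class TestKabsch:
    def test_exact_recovery_of_known_transform(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])  # non-coplanar
        T = RigidTransform.from_euler_deg((0, 0, 15), (1, 2, 3))
        est = kabsch(P, T.apply(P))
        assert np.allclose(est.rotation, T.rotation, atol=1e-10)
        assert np.allclose(est.translation, T.translation, atol=1e-10)
        assert rms(est.apply(P), T.apply(P)) <= 1e-10

    def test_identical_point_sets_give_identity(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(20, 3))
        est = kabsch(P, P)
        assert np.allclose(est.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(est.translation, 0, atol=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            kabsch(line, line + 1.0)

    def test_noisy_pairs_beat_true_transform_and_angle_grid(self):
        """Least-squares optimality: the estimated transform's residual is no
        worse than the generating transform's, nor than any small-angle
        perturbation of the estimate (brute-force grid oracle)."""
        rng = np.random.default_rng(42)
        P = rng.normal(size=(60, 3)) * 3
        T = RigidTransform.from_euler_deg((8, -5, 12), (0.5, -1, 2))
        Q = T.apply(P) + rng.normal(scale=0.05, size=P.shape)
        est = kabsch(P, Q)
        r_est = rms(est.apply(P), Q)
        assert r_est <= rms(T.apply(P), Q) + 1e-12
        for da in (-0.2, 0.2):
            for axis in range(3):
                angles = [0.0, 0.0, 0.0]
                angles[axis] = da
                perturbed = est.compose(RigidTransform.from_euler_deg(angles))
                assert r_est <= rms(perturbed.apply(P), Q) + 1e-12


class TestApplyTransform:
    def test_identity_and_inverse_round_trip(self, bumpy_blob):
        T = RigidTransform.from_euler_deg((10, 20, 30), (1, -2, 0.5))
        same = apply_transform(bumpy_blob, RigidTransform.identity())
        assert np.allclose(same.vertices, bumpy_blob.vertices)
        back = apply_transform(apply_transform(bumpy_blob, T), T.inverse())
        assert np.allclose(back.vertices, bumpy_blob.vertices, atol=1e-9)

    def test_volume_invariance(self, bumpy_blob):
        T = RigidTransform.from_euler_deg((33, -21, 7), (4, 4, 4))
        assert apply_transform(bumpy_blob, T).volume == pytest.approx(bumpy_blob.volume, rel=1e-9)


class TestDefaultInit:
    def test_concentric_meshes_give_zero_translation(self, bumpy_blob):
        T = default_init(bumpy_blob, bumpy_blob)
        assert np.allclose(T.translation, 0, atol=1e-12)
        assert np.allclose(T.rotation, np.eye(3))

    def test_shifted_copy_gives_exact_shift(self, bumpy_blob):
        moved = apply_transform(bumpy_blob, RigidTransform(np.eye(3), np.array([3.0, -1.0, 2.0])))
        T = default_init(bumpy_blob, moved)
        assert np.allclose(T.translation, [3.0, -1.0, 2.0], atol=1e-9)

    def test_principal_axes_recovers_90_degree_rotation(self):
        """Principal-axes init on an asymmetric ellipsoidal cloud: against an
        exhaustive search over the 24 axis-aligned orientations, the init must
        pick the best one."""
        base = trimesh.creation.icosphere(3, radius=1.0)
        v = base.vertices * np.array([3.0, 2.0, 1.0])
        v[:, 0] += 0.35 * (v[:, 0] / 3.0) ** 2  # break the x mirror symmetry
        v[:, 1] += 0.25 * (v[:, 1] / 2.0) ** 2
        v[:, 2] += 0.2 * v[:, 2] ** 2
        blob = trimesh.Trimesh(vertices=v, faces=base.faces, process=False)
        T_true = RigidTransform.from_euler_deg((0, 0, 90), (1.0, 0.0, -2.0))
        fixed = apply_transform(blob, T_true)
        T = default_init(blob, fixed, mode="principal_axes")

        def cost(R):
            c_m = blob.vertices.mean(axis=0)
            c_f = fixed.vertices.mean(axis=0)
            moved = (blob.vertices - c_m) @ R.T + c_f
            return rms(moved, fixed.vertices)

        # exhaustive 24 proper axis-permutation rotations
        best = np.inf
        for perm in [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]:
            for sx in (-1, 1):
                for sy in (-1, 1):
                    for sz in (-1, 1):
                        R = np.zeros((3, 3))
                        for row, (col, s) in enumerate(zip(perm, (sx, sy, sz))):
                            R[row, col] = s
                        if np.linalg.det(R) > 0:
                            best = min(best, cost(R))
        assert cost(T.rotation) <= best + 1e-9


class TestICP:
    def test_identical_meshes_converge_immediately(self, bumpy_blob):
        T, trace = icp_register(bumpy_blob, bumpy_blob, init=RigidTransform.identity())
        assert trace.converged and trace.iterations == 1
        assert np.allclose(T.rotation, np.eye(3)) and np.allclose(T.translation, 0)

    def test_max_iter_zero_returns_init_unconverged(self, bumpy_blob):
        init = RigidTransform.from_euler_deg((5, 0, 0), (1, 0, 0))
        T, trace = icp_register(bumpy_blob, bumpy_blob, init=init, max_iter=0)
        assert not trace.converged and trace.iterations == 0
        assert np.allclose(T.rotation, init.rotation) and np.allclose(T.translation, init.translation)

    def test_recovers_known_transform_with_monotone_trace(self, bumpy_blob):
        T_true = RigidTransform.from_euler_deg((12, -17, 8), (1.5, -2.0, 1.0))
        fixed = apply_transform(bumpy_blob, T_true)
        T, trace = icp_register(bumpy_blob, fixed, max_iter=300, tol=1e-10)
        err = T.compose(T_true.inverse())
        assert err.angle_deg <= 1e-3
        assert np.linalg.norm(T.apply(bumpy_blob.vertices) - fixed.vertices, axis=1).max() <= 1e-3
        trace.assert_monotone()

    def test_nonfinite_vertices_rejected(self, bumpy_blob):
        bad = bumpy_blob.copy()
        v = bad.vertices.copy()
        v[0, 0] = np.nan
        bad = trimesh.Trimesh(vertices=v, faces=bad.faces, process=False)
        with pytest.raises(ValueError):
            icp_register(bad, bumpy_blob)
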