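"""Null-space basis, scaling, rotation, projection and the reachable cone."""

import numpy as np
import pytest

from wristnull.nullspace import (NullspaceModel, build_nullspace_model,
                                 estimate_cocontraction, estimate_offset,
                                 make_rotation, nullspace_basis, scale_basis)
from wristnull.preprocess import EnvelopeRecording

from conftest import rref_kernel

FS = 1000.0


def _envelope_rec(alpha: np.ndarray, seconds: float = 3.0) -> EnvelopeRecording:
    n = int(seconds * FS)
    env = np.tile(np.asarray(alpha, dtype=float), (n, 1))
    return EnvelopeRecording(time=np.arange(n) / FS, envelope=env,
                             force=np.zeros((n, 2)), fs=FS)


def _random_H(seed):
    rng = np.random.default_rng(seed)
    while True:
        H = rng.standard_normal((2, 4)) * 3
        if np.linalg.matrix_rank(H) == 2:
            return H


class TestBasis:
    def test_coordinate_subspace_complement(self):
        H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        N = nullspace_basis(H)
        # rows span {e3, e4}: first two columns vanish
        np.testing.assert_allclose(N[:, :2], 0, atol=1e-12)
        np.testing.assert_allclose(N @ N.T, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_defining_properties(self, seed):
        H = _random_H(seed)
        N = nullspace_basis(H)
        assert np.abs(N @ H.T).max() < 1e-10
        assert np.abs(N @ N.T - np.eye(2)).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_span_matches_rref_kernel(self, seed):
        """The SVD basis spans exactly the kernel found by independent
        Gauss-Jordan elimination."""
        H = _random_H(seed + 10)
        N = nullspace_basis(H)
        K = rref_kernel(H)           # (4, 2)
        # project K onto span(N rows); residual must vanish
        P = N.T @ N
        np.testing.assert_allclose(P @ K, K, atol=1e-9)

    def test_rank_deficient_rejected(self):
        H = np.ones((2, 4))
        with pytest.raises(np.linalg.LinAlgError):
            nullspace_basis(H)

    def test_deterministic_orientation(self):
        H = _random_H(42)
        np.testing.assert_array_equal(nullspace_basis(H), nullspace_basis(H))


class TestScaling:
    def test_kappa_is_max_row_norm(self):
        H = np.array([[3.0, 0, 0, 0], [0, 4.0, 0, 0]])
        N = nullspace_basis(H)
        kappa, Ns = scale_basis(N, H)
        assert kappa == pytest.approx(4.0)
        np.testing.assert_allclose(Ns, 4.0 * N)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_norm_oracle(self, seed):
        H = _random_H(seed + 20)
        kappa, _ = scale_basis(nullspace_basis(H), H)
        assert kappa == pytest.approx(
            max(float(np.sqrt((H[i] ** 2).sum())) for i in range(2)))


class TestOffsetAndCocontraction:
    def test_zero_envelope_gives_zero_offset(self):
        H = _random_H(1)
        _, Ns = scale_basis(nullspace_basis(H), H)
        np.testing.assert_allclose(
            estimate_offset(_envelope_rec(np.zeros(4)), Ns), [0, 0])

    def test_constant_rest_envelope_projects_linearly(self):
        H = _random_H(2)
        _, Ns = scale_basis(nullspace_basis(H), H)
        alpha = np.array([0.1, 0.2, 0.05, 0.3])
        np.testing.assert_allclose(
            estimate_offset(_envelope_rec(alpha), Ns), Ns @ alpha, atol=1e-12)

    def test_noisy_rest_matches_two_pass_mean_oracle(self):
        rng = np.random.default_rng(3)
        H = _random_H(3)
        _, Ns = scale_basis(nullspace_basis(H), H)
        n = 3000
        env = rng.uniform(0, 0.2, (n, 4))
        rec = EnvelopeRecording(time=np.arange(n) / FS, envelope=env,
                                force=np.zeros((n, 2)), fs=FS)
        n0 = estimate_offset(rec, Ns, window_s=2.0)
        manual_mean = env[-2000:].sum(axis=0) / 2000.0
        np.testing.assert_allclose(n0, Ns @ manual_mean, atol=1e-12)

    def test_too_short_rest_rejected(self):
        H = _random_H(4)
        _, Ns = scale_basis(nullspace_basis(H), H)
        with pytest.raises(ValueError, match="rest recording"):
            estimate_offset(_envelope_rec(np.zeros(4), seconds=1.5), Ns)

    def test_cocontraction_mean_and_errors(self):
        H = _random_H(5)
        _, Ns = scale_basis(nullspace_basis(H), H)
        n0 = np.zeros(2)
        rng = np.random.default_rng(5)
        alphas = rng.uniform(0.1, 0.6, (6, 4))
        reps = [_envelope_rec(a) for a in alphas]
        n_c = estimate_cocontraction(reps, Ns, n0)
        oracle = sum(Ns @ a for a in alphas) / 6.0
        np.testing.assert_allclose(n_c, oracle, atol=1e-10)
        with pytest.raises(ValueError, match="6"):
            estimate_cocontraction(reps[:4], Ns, n0)
        with pytest.raises(ValueError, match="zero"):
            estimate_cocontraction([_envelope_rec(np.zeros(4))] * 6, Ns,
                                   np.zeros(2))


class TestRotation:
    def test_aligned_vector_gives_identity(self):
        np.testing.assert_allclose(make_rotation([5.0, 0.0]), np.eye(2),
                                   atol=1e-15)

    def test_vertical_vector_gives_quarter_turn(self):
        R = make_rotation([0.0, 2.0])
        np.testing.assert_allclose(R @ [0, 2], [2, 0], atol=1e-15)
        np.testing.assert_allclose(np.linalg.det(R), 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_vectors_via_atan2_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(2) * 5
        R = make_rotation(v)
        th = -np.arctan2(v[1], v[0])
        oracle = np.array([[np.cos(th), -np.sin(th)],
                           [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(R, oracle, atol=1e-12)
        assert np.abs(R @ v - [np.linalg.norm(v), 0]).max() < 1e-12
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            make_rotation([0.0, 0.0])


class TestProjection:
    def test_rest_envelope_maps_to_origin(self, model, quiet_geometry):
        _, null = model.project(quiet_geometry.alpha_rest)
        np.testing.assert_allclose(null, [0, 0], atol=1e-6)

    def test_cocontraction_moves_along_plus_x(self, model, quiet_geometry):
        alpha = quiet_geometry.alpha_rest + \
            0.5 * quiet_geometry.cocontraction_pattern
        force, null = model.project(alpha)
        rest_force, _ = model.project(quiet_geometry.alpha_rest)
        # the added pattern is force-free: only the resting force remains
        np.testing.assert_allclose(force, rest_force, atol=1e-6)
        assert null[0] > 0.1
        assert abs(null[1]) < 1e-6

    def test_matches_matrix_product_oracle(self, model):
        rng = np.random.default_rng(8)
        alpha = rng.uniform(0, 1, 4)
        force, null = model.project(alpha)
        f_oracle = np.array([model.H[i] @ alpha for i in range(2)])
        pre = np.array([(model.kappa * model.N[i]) @ alpha for i in range(2)])
        n_oracle = model.R_c @ (pre - model.n0)
        np.testing.assert_allclose(force, f_oracle, atol=1e-12)
        np.testing.assert_allclose(null, n_oracle, atol=1e-12)

    def test_negative_activation_rejected(self, model):
        with pytest.raises(ValueError, match="non-negative"):
            model.project(np.array([0.1, -0.1, 0.2, 0.3]))

    def test_affine_linearity_in_alpha(self, model):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0, 1, (2, 4))
        lam = 0.3
        f_mix, n_mix = model.project(lam * a + (1 - lam) * b)
        fa, na = model.project(a)
        fb, nb = model.project(b)
        np.testing.assert_allclose(f_mix, lam * fa + (1 - lam) * fb, atol=1e-10)
        np.testing.assert_allclose(n_mix, lam * na + (1 - lam) * nb, atol=1e-10)


class TestModelInvariants:
    def test_algebraic_identities(self, model):
        np.testing.assert_allclose(model.N @ model.N.T, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(model.N @ model.H.T, 0, atol=1e-10)
        np.testing.assert_allclose(model.R_c.T @ model.R_c, np.eye(2),
                                   atol=1e-12)
        assert np.linalg.det(model.R_c) == pytest.approx(1.0)
        rotated = model.R_c @ model.n_c
        assert rotated[0] > 0
        assert abs(rotated[1]) < 1e-9
        assert model.kappa == pytest.approx(
            max(np.linalg.norm(model.H[0]), np.linalg.norm(model.H[1])))

    def test_serialisation_roundtrip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        again = NullspaceModel.from_json(path)
        for attr in ("H", "N", "n0", "n_c", "R_c"):
            np.testing.assert_allclose(getattr(again, attr),
                                       getattr(model, attr), atol=1e-12)
        assert again.kappa == model.kappa
        assert again.smvf == model.smvf


class TestCone:
    def test_extreme_rays_of_half_plane_cone(self, model):
        cone = model.cone_extreme_rays()
        assert not cone.contains_full_plane
        assert cone.rays.shape == (2, 2)
        np.testing.assert_allclose(np.linalg.norm(cone.rays, axis=1), 1.0)

    def test_ray_angles_bound_column_images(self, model):
        cone = model.cone_extreme_rays()
        cols = (model.R_c @ model.N_scaled).T
        lo, hi = cone.rays[0], cone.rays[1]
        for c in cols:
            u = c / np.linalg.norm(c)
            assert lo[0] * u[1] - lo[1] * u[0] >= -1e-9
            assert u[0] * hi[1] - u[1] * hi[0] >= -1e-9

    def test_full_plane_detection(self):
        stub = NullspaceModel.__new__(NullspaceModel)
        stub.R_c = np.eye(2)
        kappa = 1.0
        cols = np.array([[1, 0], [0, 1], [-1, 0.1], [0.2, -1]]).T
        stub.__dict__["kappa"] = kappa
        stub.__dict__["N"] = cols  # only used via N_scaled in the ray op
        cone = NullspaceModel.cone_extreme_rays(stub)
        assert cone.contains_full_plane

    def test_membership_constructive_witness(self, model, quiet_geometry):
        """Images of random non-negative zero-force activations are always
        members, and the feasibility witness projects back onto them."""
        rng = np.random.default_rng(10)
        pattern = quiet_geometry.cocontraction_pattern
        K = rref_kernel(model.H)
        n_checked = 0
        for _ in range(40):
            alpha = rng.uniform(0.2, 2) * pattern + \
                K @ rng.normal(0, 0.05, 2)   # stays in ker(H)
            if (alpha < 0).any():
                continue
            n_checked += 1
            force, null = model.project(alpha)
            assert np.linalg.norm(force) < 1e-8
            ok, witness = model.cone_membership(null, return_witness=True)
            assert ok
            _, back = model.project(witness)
            np.testing.assert_allclose(back, null, atol=1e-6)
        assert n_checked >= 10

    def test_natural_cocontraction_target_is_member(self, model):
        target = np.array([np.linalg.norm(model.n_c), 0.0])
        assert model.cone_membership(target)

    def test_membership_agrees_with_kernel_sign_oracle(self, model):
        """Membership with the zero-force constraint equals non-negativity
        of the unique kernel coefficients (independent RREF kernel)."""
        K = rref_kernel(model.H)
        A = model.N_scaled @ K
        rng = np.random.default_rng(11)
        n_agree = 0
        for _ in range(500):
            target = rng.uniform(-8, 8, 2)
            b = model.R_c.T @ target + model.n0
            alpha = K @ np.linalg.solve(A, b)
            oracle = bool((alpha >= -1e-9).all())
            assert model.cone_membership(target) == oracle
            n_agree += 1
        assert n_agree == 500

    def test_members_lie_in_ray_sector(self, model):
        """Any target accepted by the membership operation falls inside
        the angular sector spanned by the extreme rays (offset removed)."""
        cone = model.cone_extreme_rays()
        lo, hi = cone.rays[0], cone.rays[1]

        def _cross(a, b):
            return a[0] * b[1] - a[1] * b[0]

        rng = np.random.default_rng(12)
        n_members = 0
        for _ in range(200):
            target = rng.uniform(-8, 8, 2)
            if not model.cone_membership(target):
                continue
            v = target + model.R_c @ model.n0
            if np.linalg.norm(v) < 1e-9:
                continue
            n_members += 1
            # the sector from lo to hi (anticlockwise, <= pi wide)
            assert _cross(lo, v) >= -1e-6 * np.linalg.norm(v)
            assert _cross(v, hi) >= -1e-6 * np.linalg.norm(v)
        assert n_members > 10
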