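import numpy as np
import pytest

from paareg import (
    RigidParams,
    Volume,
    align,
    apply_transform,
    brute_force_register,
    compose_rigid,
    compute_centroid,
    compute_inertia,
    extract_euler,
    invert,
    make_pair,
    make_phantom,
    matrix_to_params,
    PhantomSpec,
    principal_axes,
    refine,
    register_paa,
)
from paareg.similarity_metrics import ncc


def gaussian_volume(shape, sigmas, center=None, amplitude=1.0):
    """Axis-aligned anisotropic Gaussian blob (analytic moment oracle)."""
    n = np.asarray(shape, dtype=float)
    c = (n - 1) / 2.0 if center is None else np.asarray(center, dtype=float)
    xs = np.arange(shape[0])[:, None, None]
    ys = np.arange(shape[1])[None, :, None]
    zs = np.arange(shape[2])[None, None, :]
    sx, sy, sz = sigmas
    data = amplitude * np.exp(
        -0.5 * (((xs - c[0]) / sx) ** 2 + ((ys - c[1]) / sy) ** 2 + ((zs - c[2]) / sz) ** 2)
    )
    return Volume(data)


class TestCentroid:
    def test_single_voxel(self):
        data = np.zeros((8, 8, 8))
        data[3, 4, 5] = 7.0
        np.testing.assert_allclose(compute_centroid(Volume(data)), [3, 4, 5])

    def test_uniform_cube_center(self):
        c = compute_centroid(Volume(np.ones((6, 6, 6))))
        np.testing.assert_allclose(c, [2.5, 2.5, 2.5])

    def test_integer_shift_equivariance(self, small_phantom):
        c0 = compute_centroid(small_phantom)
        shifted = np.roll(small_phantom.data, (2, -3, 1), axis=(0, 1, 2))
        c1 = compute_centroid(Volume(shifted))
        # np.roll wraps the faint boundary tails, so equivariance is not exact
        np.testing.assert_allclose(c1 - c0, [2, -3, 1], atol=0.05)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            compute_centroid(Volume(np.zeros((4, 4, 4))))


class TestInertia:
    def test_point_mass_zero_matrix(self):
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 3.0
        np.testing.assert_allclose(compute_inertia(Volume(data)), np.zeros((3, 3)), atol=1e-12)

    def test_two_point_rank_deficiency(self):
        """Two equal masses on the x axis: zero moment about x, equal moments
        about y and z (hand-computed two-point oracle)."""
        data = np.zeros((9, 9, 9))
        data[2, 4, 4] = 1.0
        data[6, 4, 4] = 1.0
        h = compute_inertia(Volume(data))
        # each mass sits 2 voxels from the centroid: normalized Sxx = 4
        expected = np.diag([0.0, 4.0, 4.0])
        np.testing.assert_allclose(h, expected, atol=1e-12)
        evals, evecs = np.linalg.eigh(h)
        assert evals[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(evecs[:, 0]), [1, 0, 0], atol=1e-12)

    def test_uniform_cube_isotropic(self):
        h = compute_inertia(Volume(np.ones((10, 10, 10))))
        evals = np.linalg.eigvalsh(h)
        assert np.ptp(evals) / evals.mean() < 1e-6

    def test_symmetry(self, small_phantom):
        h = compute_inertia(small_phantom)
        np.testing.assert_allclose(h, h.T, atol=1e-9)


class TestPrincipalAxes:
    def test_gaussian_matches_analytic_eigenstructure(self):
        """sigma_x > sigma_y > sigma_z: inertia eigenvalues are the pairwise
        sums of the two smaller variances, axes are the coordinate axes."""
        sigmas = (10.0, 7.0, 5.0)
        pa = principal_axes(gaussian_volume((80, 80, 80), sigmas))
        sx2, sy2, sz2 = (s**2 for s in sigmas)
        expected = np.sort([sy2 + sz2, sx2 + sz2, sx2 + sy2])[::-1]
        np.testing.assert_allclose(pa.eigenvalues, expected, rtol=0.02)
        # descending inertia order puts the axes as (z, y, x)
        expected_axes = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float).T
        for j in range(3):
            cosang = abs(np.dot(pa.axes[:, j], expected_axes[:, j]))
            assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0
        assert np.linalg.det(pa.axes) == pytest.approx(1.0, abs=1e-9)

    def test_rotated_gaussian_axes_conjugate(self):
        v = gaussian_volume((64, 64, 64), (9.0, 6.0, 4.0))
        pa0 = principal_axes(v)
        r = compose_rigid(RigidParams(0, 0, 0, 0.0, 0.0, 0.3), center=tuple(pa0.centroid))
        moved = apply_transform(v, r)
        pa1 = principal_axes(moved)
        np.testing.assert_allclose(pa1.axes, r[:3, :3] @ pa0.axes, atol=0.02)

    def test_sphere_flagged_degenerate(self):
        pa = principal_axes(make_phantom(PhantomSpec(shape=(32, 32, 32), kind="sphere")))
        assert pa.degenerate

    def test_asym_blob_not_degenerate(self, small_phantom):
        pa = principal_axes(small_phantom)
        assert not pa.degenerate
        assert pa.rel_gap > 0.05


class TestEulerExtraction:
    def test_identity(self):
        e = extract_euler(np.eye(3))
        assert tuple(e) == (0.0, 0.0, 0.0)
        assert not e.gimbal_lock

    def test_round_trip_specific_angles(self):
        angles = (0.1, -0.2, 0.3)
        r = compose_rigid(RigidParams(0, 0, 0, *angles))[:3, :3]
        np.testing.assert_allclose(tuple(extract_euler(r)), angles, atol=1e-9)

    def test_gimbal_lock_flagged_and_reconstructs(self):
        r = compose_rigid(RigidParams(0, 0, 0, 0.4, np.pi / 2, 0.25))[:3, :3]
        e = extract_euler(r)
        assert e.gimbal_lock
        assert e.gamma == 0.0
        rebuilt = compose_rigid(RigidParams(0, 0, 0, *e))[:3, :3]
        np.testing.assert_allclose(rebuilt, r, atol=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError, match="rotation"):
            extract_euler(np.diag([1.0, 1.0, 2.0]))

    def test_matrix_to_params_round_trip(self):
        p = RigidParams(4.0, -3.0, 2.0, 0.2, -0.3, 0.4)
        m = compose_rigid(p, center=(16.0, 10.0, 12.0))
        p2 = matrix_to_params(m, center=(16.0, 10.0, 12.0))
        np.testing.assert_allclose(p2.as_array(), p.as_array(), atol=1e-9)


class TestRegisterPaa:
    def test_self_registration_is_identity(self, small_phantom):
        res = register_paa(small_phantom, small_phantom)
        np.testing.assert_allclose(res.params.as_array(), np.zeros(6), atol=1e-6)
        assert res.similarity_after == pytest.approx(res.similarity_before, abs=1e-9)
        assert res.iterations == 1
        assert res.method == "paa"

    def test_pure_translation_recovered(self, standard_phantom):
        ref, flt, truth = make_pair(standard_phantom, RigidParams(4.0, -3.0, 2.0))
        res = register_paa(ref, flt)
        np.testing.assert_allclose(res.params.translation, truth.translation, atol=0.1)
        # residual rotation reflects tail truncation at the field-of-view edge
        assert np.rad2deg(np.abs(res.params.angles)).max() < 0.25

    def test_z_rotation_recovered(self, standard_phantom):
        truth = RigidParams(m6=np.deg2rad(10.0))
        ref, flt, _ = make_pair(standard_phantom, truth)
        res = register_paa(ref, flt)
        assert abs(np.rad2deg(res.params.m6) - 10.0) < 0.5
        assert res.similarity_after >= res.similarity_before

    def test_sphere_falls_back_to_centroid(self):
        sphere = make_phantom(PhantomSpec(shape=(32, 32, 32), kind="sphere"))
        ref, flt, truth = make_pair(sphere, RigidParams(3.0, 0.0, 0.0))
        res = register_paa(ref, flt)
        assert res.method == "centroid"
        np.testing.assert_allclose(res.params.translation, truth.translation, atol=0.2)

    def test_symmetry_of_pairing(self, small_phantom):
        """Registering (A,B) and (B,A) yields mutually inverse matrices."""
        m = compose_rigid(RigidParams(2.0, -1.0, 1.5, 0.1, 0.15, -0.2),
                          center=tuple(compute_centroid(small_phantom)))
        other = apply_transform(small_phantom, m)
        ab = register_paa(small_phantom, other)
        ba = register_paa(other, small_phantom)
        np.testing.assert_allclose(ab.matrix @ ba.matrix, np.eye(4), atol=0.05)

    def test_noise_robustness_curve(self, standard_phantom):
        """Translation error grows gently with noise; no catastrophic failure
        up to 5% of peak (SNR >= 5 regime on the standard phantom)."""
        truth = RigidParams(3.0, -2.0, 1.0, 0.1, -0.05, 0.12)
        peak = standard_phantom.data.max()
        errors = []
        for sigma_pct in (0.0, 1.0, 2.0, 5.0):
            ref, flt, _ = make_pair(standard_phantom, truth,
                                    noise_sigma=sigma_pct / 100 * peak, seed=11)
            res = register_paa(ref, flt)
            errors.append(np.abs(res.params.translation - truth.translation).max())
        assert errors[0] < 0.1
        assert max(errors) < 0.5
        assert errors[0] <= errors[-1] + 1e-6


class TestRefine:
    def test_ground_truth_init_not_degraded(self, small_phantom):
        ref, flt, truth = make_pair(small_phantom, RigidParams(2.0, -1.0, 0.5, 0.1, 0.0, -0.1))
        res = refine(ref, flt, truth, metric="ncc", max_evals=120)
        assert res.similarity_after >= res.similarity_before
        np.testing.assert_allclose(res.params.translation, truth.translation, atol=0.3)
        assert res.method == "paa+refine"

    def test_improves_noisy_paa_init(self, standard_phantom):
        peak = standard_phantom.data.max()
        ref, flt, truth = make_pair(standard_phantom,
                                    RigidParams(4.0, -2.0, 3.0, 0.2, -0.15, 0.25),
                                    noise_sigma=0.05 * peak, seed=3)
        init = register_paa(ref, flt)
        res = refine(ref, flt, init.params, metric="ncc", max_evals=300)
        ncc_init = ncc(ref, align(flt, init.matrix)).value
        assert res.similarity_after >= ncc_init - 1e-6
        assert res.iterations >= 1

    def test_paa_init_beats_cold_start(self, standard_phantom):
        """From a 15-degree rotated pair, the PAA-initialized run reaches at
        least as good a metric with no more evaluations than an all-zero init."""
        truth = RigidParams(2.0, 1.0, -1.0, 0.0, 0.0, np.deg2rad(15.0))
        ref, flt, _ = make_pair(standard_phantom, truth)
        init = register_paa(ref, flt)
        warm = refine(ref, flt, init.params, metric="ncc", max_evals=200)
        cold = refine(ref, flt, RigidParams(), metric="ncc", max_evals=200)
        assert warm.similarity_after >= cold.similarity_after - 1e-6


class TestBruteForce:
    def test_integer_shift_grid_exact(self, small_phantom):
        ref, flt, truth = make_pair(small_phantom, RigidParams(2.0, -1.0, 0.0))
        grid = {"l1": np.arange(-3, 4.0), "l2": np.arange(-3, 4.0)}
        res = brute_force_register(ref, flt, grid, subsample=2)
        np.testing.assert_allclose(res.params.translation[:2], [2, -1], atol=1e-9)
        assert res.method == "brute_force"
        assert res.iterations == 49

    def test_grid_containing_truth_finds_it(self, small_phantom):
        truth = RigidParams(1.0, 0.0, 0.0, 0.0, 0.0, np.deg2rad(6.0))
        ref, flt, _ = make_pair(small_phantom, truth)
        grid = {"l1": [0.0, 1.0, 2.0], "m6": np.deg2rad([0.0, 3.0, 6.0, 9.0])}
        res = brute_force_register(ref, flt, grid)
        assert res.params.l1 == pytest.approx(1.0)
        assert np.rad2deg(res.params.m6) == pytest.approx(6.0)

    def test_empty_grid_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="empty"):
            brute_force_register(small_phantom, small_phantom, {"l1": []})

    def test_unknown_parameter_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="unknown"):
            brute_force_register(small_phantom, small_phantom, {"q7": [0.0]})


class TestEquivariance:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_known_motion_recovered(self, standard_phantom, seed):
        rng = np.random.default_rng(seed)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        truth = RigidParams(*(direction * rng.uniform(0, 8)),
                            *rng.uniform(-np.deg2rad(30), np.deg2rad(30), 3))
        ref, flt, _ = make_pair(standard_phantom, truth)
        res = register_paa(ref, flt)
        assert np.abs(res.params.translation - truth.translation).max() < 0.1
        assert np.rad2deg(np.abs(res.params.angles - truth.angles)).max() < 0.5
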