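"""Wedge-aware alignment, averaging and FSC."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter, shift as ndshift

from pdtomo import stavg
from pdtomo.euler import rotation_matrix
from pdtomo.geometry import ParticleSet
from pdtomo.stavg import (
    AlignmentConstraints,
    FSCCurve,
    WedgeDescriptor,
    average_particles,
    compute_fsc,
    constrained_align,
    exhaustive_align,
    masked_cc,
    resolution_at_threshold,
    wedge_mask,
)
from pdtomo.volume import Volume

VS = 0.76


def random_blob_volume(box=48, n=30, seed=2, sigma=2.0):
    rng = np.random.default_rng(seed)
    d = np.zeros((box,) * 3)
    for _ in range(n):
        p = rng.integers(box // 4, 3 * box // 4, 3)
        d[tuple(p)] = rng.uniform(0.5, 1.0)
    return gaussian_filter(d, sigma)


def particle_table(n, stage="seeded", eulers=None):
    eulers = np.zeros((n, 3)) if eulers is None else np.asarray(eulers)
    return ParticleSet(
        pd.DataFrame(
            {
                "particle_id": np.arange(n),
                "seed_id": np.zeros(n, dtype=int),
                "x_nm": np.zeros(n),
                "y_nm": np.zeros(n),
                "z_nm": np.zeros(n),
                "phi_deg": eulers[:, 0],
                "theta_deg": eulers[:, 1],
                "psi_deg": eulers[:, 2],
                "score": np.zeros(n),
                "stage": stage,
            }
        ),
        stage,
    )


def rot_vol(data, mat):
    from pdtomo.stavg import _rotate_volume

    return _rotate_volume(data, mat)


class TestWedgeMask:
    def test_sixty_degree_mask_keeps_two_thirds_in_sphere(self):
        m = wedge_mask(48, WedgeDescriptor(-60, 60))
        k = np.fft.fftfreq(48)
        kx, ky, kz = np.meshgrid(k, k, k, indexing="ij", sparse=True)
        sphere = kx**2 + ky**2 + kz**2 <= 0.25
        assert m[sphere].mean() == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_near_full_range_keeps_almost_everything(self):
        m = wedge_mask(48, WedgeDescriptor(-89.9, 89.9))
        assert m.mean() > 0.95

    def test_friedel_symmetry(self):
        m = wedge_mask(48, WedgeDescriptor(-45, 60))
        assert np.array_equal(m, np.roll(m[::-1, ::-1, ::-1], 1, axis=(0, 1, 2)))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            WedgeDescriptor(-95, 60)


class TestMaskedCC:
    def test_self_correlation_is_one(self):
        v = random_blob_volume()
        assert masked_cc(v, v) == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance(self):
        v = random_blob_volume()
        assert masked_cc(v, 2.0 * v + 5.0) == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((48, 48, 48))
        b = rng.standard_normal((48, 48, 48))
        assert abs(masked_cc(a, b)) < 0.05

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert masked_cc(np.zeros((16,) * 3), np.ones((16,) * 3)) == 0.0


class TestConstrainedAlign:
    def test_recovers_known_perpendicular_shifts(self):
        base = random_blob_volume()
        true = [(2, 1, 0), (-3, 2, 0), (0, -2, 0), (1, 3, 0)]  # perp to z
        stack = np.stack([ndshift(base, s, order=1) for s in true]).astype(np.float32)
        ps = particle_table(4)
        aligned, _ = constrained_align(
            stack, ps, WedgeDescriptor(-89, 89),
            AlignmentConstraints(max_shift_nm=5 * VS, lowpass_nm=3.0),
            n_iter=4, voxel_size_nm=VS,
        )
        rec = aligned.positions / VS
        rec -= rec.mean(axis=0)
        ts = np.asarray(true, float)
        ts -= ts.mean(axis=0)
        assert np.abs(rec - ts).max() < 0.5

    def test_axial_shift_not_compensated(self):
        base = random_blob_volume()
        stack = np.stack([base, ndshift(base, (0, 0, 3), order=1)]).astype(np.float32)
        ps = particle_table(2)
        aligned, _ = constrained_align(
            stack, ps, WedgeDescriptor(-89, 89),
            AlignmentConstraints(max_shift_nm=5 * VS, lowpass_nm=3.0),
            n_iter=2, voxel_size_nm=VS,
        )
        # shifts along each particle's z axis are outside the allowed subspace
        assert np.abs(aligned.positions[:, 2]).max() < 0.7 * VS

    def test_zero_iterations_scores_against_unaligned_mean(self):
        stack = np.stack([random_blob_volume(seed=s) for s in (1, 2)]).astype(np.float32)
        ps = particle_table(2)
        aligned, _ = constrained_align(
            stack, ps, WedgeDescriptor(-89, 89), n_iter=0, voxel_size_nm=VS
        )
        assert np.allclose(aligned.positions, 0.0)
        assert np.all(np.isfinite(aligned.scores))
        assert aligned.scores.max() > 0.3

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            constrained_align(np.zeros((0, 8, 8, 8)), particle_table(0), WedgeDescriptor())


class TestExhaustiveAlign:
    def test_global_rotation_recovery(self):
        ref = random_blob_volume()
        true_e = (33.0, 40.0, 10.0)
        particle = rot_vol(ref, np.linalg.inv(rotation_matrix(*true_e)))
        ps = particle_table(1, "expanded")
        out = exhaustive_align(
            particle[None].astype(np.float32), ps, Volume(ref.astype(np.float32), VS),
            WedgeDescriptor(-89, 89), angular_step_deg=30, max_shift_nm=3,
            voxel_size_nm=VS, lowpass_nm=None,
        )
        r = out.table.iloc[0]
        R1 = rotation_matrix(*true_e)
        R2 = rotation_matrix(r.phi_deg, r.theta_deg, r.psi_deg)
        ang = np.degrees(np.arccos(np.clip((np.trace(R1.T @ R2) - 1) / 2, -1, 1)))
        assert ang <= 30 / 5 + 1e-6  # within the refinement granularity
        assert r.score > 0.8

    def test_shift_bound_enforced(self):
        ref = random_blob_volume()
        particle = ndshift(ref, (0, 17, 0), order=1)  # 17 vox ~ 13 nm, beyond bound
        ps = particle_table(1, "expanded")
        out = exhaustive_align(
            particle[None].astype(np.float32), ps, Volume(ref.astype(np.float32), VS),
            WedgeDescriptor(-89, 89), angular_step_deg=90, max_shift_nm=11,
            voxel_size_nm=VS, lowpass_nm=None,
        )
        assert np.linalg.norm(out.positions[0]) <= 11.0 + 1e-6

    def test_identity_reference_wins_with_high_score(self):
        ref = random_blob_volume()
        ps = particle_table(1, "expanded")
        out = exhaustive_align(
            ref[None].astype(np.float32), ps, Volume(ref.astype(np.float32), VS),
            WedgeDescriptor(-89.99, 89.99), angular_step_deg=45, max_shift_nm=3,
            voxel_size_nm=VS, lowpass_nm=None,
        )
        r = out.table.iloc[0]
        assert r.score > 0.99
        assert np.linalg.norm(out.positions[0]) < 1e-6
        R = rotation_matrix(r.phi_deg, r.theta_deg, r.psi_deg)
        assert np.allclose(R, np.eye(3), atol=1e-6)

    def test_rejects_bad_step(self):
        with pytest.raises(ValueError):
            exhaustive_align(
                np.zeros((1, 8, 8, 8), dtype=np.float32), particle_table(1),
                np.zeros((8, 8, 8)), WedgeDescriptor(), angular_step_deg=0,
            )


class TestAverageParticles:
    def test_identity_copies_reproduce_the_cube(self):
        cube = random_blob_volume(box=32).astype(np.float32)
        stack = np.stack([cube] * 5)
        avg = average_particles(stack, particle_table(5), WedgeDescriptor(-89.99, 89.99), VS)
        cc = np.corrcoef(avg.data.ravel(), cube.ravel())[0, 1]
        assert cc > 0.999

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        stack = np.stack([random_blob_volume(box=32, seed=s) for s in range(6)]).astype(np.float32)
        eulers = rng.uniform(0, 90, (6, 3))
        ps = particle_table(6, eulers=eulers)
        perm = rng.permutation(6)
        ps_perm = particle_table(6, eulers=eulers[perm])
        a = average_particles(stack, ps, WedgeDescriptor(-60, 60), VS)
        b = average_particles(stack[perm], ps_perm, WedgeDescriptor(-60, 60), VS)
        assert np.allclose(a.data, b.data, atol=1e-4)

    def test_single_particle_rotated_into_reference_frame(self):
        cube = random_blob_volume(box=32)
        eul = (25.0, 30.0, 0.0)
        ps = particle_table(1, eulers=[eul])
        avg = average_particles(cube[None].astype(np.float32), ps, WedgeDescriptor(-89, 89), VS)
        oracle = rot_vol(cube - cube.mean(), rotation_matrix(*eul))
        inner = slice(6, 26)
        cc = np.corrcoef(
            avg.data[inner, inner, inner].ravel(), oracle[inner, inner, inner].ravel()
        )[0, 1]
        assert cc > 0.95

    def test_complementary_wedges_fill_coverage(self):
        cube = random_blob_volume(box=32).astype(np.float32)
        ps = particle_table(2, eulers=[(0, 0, 0), (0, 90, 0)])
        _, cov = average_particles(
            np.stack([cube, cube]), ps, WedgeDescriptor(-60, 60), VS, return_coverage=True
        )
        m = stavg.wedge_mask(32, WedgeDescriptor(-60, 60)).astype(float)
        single = np.fft.fftshift(m)
        k = np.fft.fftfreq(32)
        kx, ky, kz = np.meshgrid(k, k, k, indexing="ij", sparse=True)
        sphere = np.fft.fftshift(kx**2 + ky**2 + kz**2 <= 0.2)
        assert cov[sphere].mean() > single[sphere].mean() * 1.15

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_particles(np.zeros((0, 8, 8, 8)), particle_table(0), WedgeDescriptor())


class TestFSC:
    def test_self_fsc_is_unity(self):
        v = Volume(random_blob_volume().astype(np.float32), VS)
        curve = compute_fsc(v, v)
        assert np.allclose(curve.correlation, 1.0, atol=1e-9)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        a = Volume(rng.standard_normal((48,) * 3).astype(np.float32), VS)
        b = Volume(rng.standard_normal((48,) * 3).astype(np.float32), VS)
        curve = compute_fsc(a, b)
        assert abs(np.mean(curve.correlation[1:])) < 0.05

    def test_threshold_crossing_interpolated(self):
        curve = FSCCurve([0.0, 0.2, 0.25], [1.0, 0.5, 0.1])
        res, reached = resolution_at_threshold(curve, 0.143)
        assert reached
        assert 4.0 < res < 5.0

    def test_never_crossing_flagged(self):
        curve = FSCCurve([0.0, 0.2, 0.4], [1.0, 0.9, 0.8])
        res, reached = resolution_at_threshold(curve, 0.143)
        assert not reached
        assert res == pytest.approx(1 / 0.4)

    def test_mismatched_grids_rejected(self):
        a = Volume(np.zeros((16,) * 3, dtype=np.float32), VS)
        b = Volume(np.zeros((24,) * 3, dtype=np.float32), VS)
        with pytest.raises(ValueError):
            compute_fsc(a, b)

    def test_resolution_improves_with_particle_count(self):
        """Half-set FSC resolution improves monotonically 32 -> 64 -> 128."""
        rng = np.random.default_rng(5)
        signal = random_blob_volume(box=32, n=40, seed=9, sigma=1.5)
        signal /= signal.std()
        wedge = WedgeDescriptor(-60, 60)
        res = []
        for n in (32, 64, 128):
            halves = []
            for half in range(2):
                cubes = signal[None] + 3.0 * rng.standard_normal((n // 2, 32, 32, 32))
                halves.append(
                    average_particles(cubes.astype(np.float32), particle_table(n // 2), wedge, VS)
                )
            r, _ = resolution_at_threshold(compute_fsc(*halves), 0.143)
            res.append(r)
        assert res[0] > res[1] > res[2]
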