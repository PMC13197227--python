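"""Contour sampling, orientation seeding, expansion, filtering, extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from pdtomo import geometry
from pdtomo.euler import euler_aligning_z, rotation_matrix, zaxis_from_euler
from pdtomo.geometry import (
    Contour,
    ParticleSet,
    distance_filter,
    expand_on_tube,
    extract_subvolumes,
    init_orientations,
    sample_contour,
    seed_particles,
)
from pdtomo.volume import Volume


def make_particles(positions, eulers=None, scores=None) -> ParticleSet:
    n = len(positions)
    eulers = np.zeros((n, 3)) if eulers is None else np.asarray(eulers)
    positions = np.asarray(positions, dtype=float)
    return ParticleSet(
        pd.DataFrame(
            {
                "particle_id": np.arange(n),
                "seed_id": np.zeros(n, dtype=int),
                "x_nm": positions[:, 0],
                "y_nm": positions[:, 1],
                "z_nm": positions[:, 2],
                "phi_deg": eulers[:, 0],
                "theta_deg": eulers[:, 1],
                "psi_deg": eulers[:, 2],
                "score": np.zeros(n) if scores is None else np.asarray(scores, float),
                "stage": "seeded",
            }
        ),
        "seeded",
    )


class TestSampleContour:
    def test_straight_segment_counts(self):
        c = Contour([[0, 0, 0], [0, 0, 10]])
        pos, tan = sample_contour(c, 1.0)
        assert len(pos) == 11
        assert np.allclose(tan, [0, 0, 1])

    def test_short_contour_returns_endpoints(self):
        c = Contour([[0, 0, 0], [0, 0, 0.4]])
        pos, _ = sample_contour(c, 1.0)
        assert len(pos) == 2
        assert np.allclose(pos[-1], [0, 0, 0.4])

    def test_right_angle_polyline(self):
        c = Contour([[0, 0, 0], [5, 0, 0], [5, 5, 0]])
        pos, tan = sample_contour(c, 1.0)
        assert len(pos) == 11
        assert np.allclose(tan[0], [1, 0, 0])
        assert np.allclose(tan[-1], [0, 1, 0])
        # arc-length walk oracle: consecutive samples 1 nm apart along arms
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.all(d <= 1.0 + 1e-9)

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError):
            sample_contour(Contour([[0, 0, 0], [0, 0, 1]]), 0.0)


class TestInitOrientations:
    def test_z_tangent_gives_zero_theta(self):
        eul = init_orientations(np.array([[0.0, 0.0, 1.0]]), seed=0)[0]
        assert eul[1] == pytest.approx(0.0, abs=1e-9)

    def test_rotated_z_equals_tangent(self):
        for t in ([1, 0, 0], [0, 1, 0], [0.6, -0.48, 0.64]):
            eul = init_orientations(np.array([t], dtype=float), seed=3)[0]
            assert np.allclose(zaxis_from_euler(*eul), t, atol=1e-6)

    def test_same_seed_reproduces_phi_sequence(self):
        tangents = np.tile([0.0, 0.0, 1.0], (50, 1))
        a = init_orientations(tangents, seed=7)
        b = init_orientations(tangents, seed=7)
        assert np.array_equal(a, b)
        c = init_orientations(tangents, seed=8)
        assert not np.array_equal(a[:, 0], c[:, 0])

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            euler_aligning_z(np.zeros(3))


class TestExpandOnTube:
    def test_eleven_positions_six_nm_thirtythree_degrees(self):
        ps = make_particles([[0, 0, 0]])
        out = expand_on_tube(ps, radial_shift_nm=6.0, n_positions=11)
        assert len(out) == 11
        pos = out.positions
        assert np.allclose(np.linalg.norm(pos, axis=1), 6.0, atol=1e-9)
        ang = np.degrees(np.arctan2(pos[:, 1], pos[:, 0])) % 360
        gaps = np.diff(np.sort(ang))
        assert np.allclose(gaps, 360.0 / 11.0, atol=0.01)  # ~32.7 degrees

    def test_circle_lies_in_normal_plane(self):
        ps = make_particles([[0, 0, 0]])  # z axis = (0,0,1)
        out = expand_on_tube(ps, 6.0, 11)
        assert np.allclose(out.positions[:, 2], 0.0, atol=1e-9)

    def test_new_z_axes_point_radially_outward(self):
        ps = make_particles([[1.0, 2.0, 3.0]])
        out = expand_on_tube(ps, 6.0, 4)
        centre = np.array([1.0, 2.0, 3.0])
        for _, row in out.table.iterrows():
            radial = np.array([row.x_nm, row.y_nm, row.z_nm]) - centre
            radial /= np.linalg.norm(radial)
            z = zaxis_from_euler(row.phi_deg, row.theta_deg, row.psi_deg)
            assert np.allclose(z, radial, atol=1e-6)
        # n=4: pairwise z-axis separations of 90 degrees
        zs = out.zaxes()
        dots = [abs(zs[i] @ zs[j]) for i in range(4) for j in range(i + 1, 4)]
        assert np.allclose(sorted(dots), [0, 0, 0, 0, 1, 1], atol=1e-6)

    def test_seed_ids_preserved_and_counts_multiply(self):
        ps = make_particles(np.random.default_rng(0).uniform(0, 50, (7, 3)))
        ps.table["seed_id"] = np.arange(7)
        out = expand_on_tube(ps, 6.0, 11)
        assert len(out) == 7 * 11
        assert (out.table["seed_id"].value_counts() == 11).all()

    def test_rejects_no_positions(self):
        with pytest.raises(ValueError):
            expand_on_tube(make_particles([[0, 0, 0]]), 6.0, 0)


class TestDistanceFilter:
    def test_close_pair_keeps_higher_score(self):
        ps = make_particles([[0, 0, 0], [0, 0, 5]], scores=[0.9, 0.8])
        out = distance_filter(ps, 8.0)
        assert len(out) == 1
        assert out.table.iloc[0].score == 0.9

    def test_distant_pair_survives(self):
        ps = make_particles([[0, 0, 0], [0, 0, 9]], scores=[0.9, 0.8])
        assert len(distance_filter(ps, 8.0)) == 2

    def test_all_pairs_respect_minimum_distance(self):
        rng = np.random.default_rng(1)
        ps = make_particles(rng.uniform(0, 60, (100, 3)), scores=rng.uniform(0, 1, 100))
        out = distance_filter(ps, 8.0)
        assert len(out) > 1
        assert pdist(out.positions).min() >= 8.0  # exhaustive all-pairs oracle

    def test_idempotent_and_keeps_global_maximum(self):
        rng = np.random.default_rng(2)
        ps = make_particles(rng.uniform(0, 40, (60, 3)), scores=rng.uniform(0, 1, 60))
        once = distance_filter(ps, 8.0)
        twice = distance_filter(once, 8.0)
        assert once.table[["particle_id"]].equals(twice.table[["particle_id"]])
        assert ps.table.score.max() in set(once.table.score)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_filter(make_particles([[0, 0, 0]]), -1.0)


class TestExtractSubvolumes:
    def test_delta_spike_centred_in_cube(self):
        data = np.zeros((32, 32, 32), dtype=np.float32)
        data[20, 14, 17] = 1.0
        vol = Volume(data, 1.0)
        ps = make_particles([[20.0, 14.0, 17.0]])
        stack, kept = extract_subvolumes(vol, ps, 16)
        assert len(kept) == 1
        assert np.unravel_index(np.argmax(stack[0]), stack[0].shape) == (8, 8, 8)

    def test_boundary_particles_dropped_not_padded(self):
        vol = Volume(np.zeros((32, 32, 32), dtype=np.float32), 1.0)
        ps = make_particles([[16, 16, 16], [15, 17, 14], [18, 16, 15], [2, 16, 16]])
        stack, kept = extract_subvolumes(vol, ps, 16)
        assert stack.shape[0] == 3
        assert len(kept) == 3

    def test_stage_seeding_from_contour(self):
        ps = seed_particles(Contour([[5, 5, 0], [5, 5, 20]]), 1.0, seed=0)
        assert ps.stage == "seeded"
        assert len(ps) == 21


class TestParticleIO:
    def test_star_and_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        ps = make_particles(rng.uniform(0, 50, (9, 3)),
                            eulers=rng.uniform(0, 90, (9, 3)),
                            scores=rng.uniform(-1, 1, 9))
        star = tmp_path / "p.star"
        tsv = tmp_path / "p.tsv"
        ps.to_star(star)
        ps.to_tsv(tsv)
        for back in (ParticleSet.from_star(star), ParticleSet.from_tsv(tsv)):
            assert np.allclose(back.positions, ps.positions, atol=1e-4)
            assert np.allclose(back.scores, ps.scores, atol=1e-4)
            assert list(back.table.particle_id) == list(ps.table.particle_id)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_orientation_roundtrip_property(seed):
    """rotation_matrix and euler extraction invert each other."""
    from pdtomo.euler import euler_from_matrix

    rng = np.random.default_rng(seed)
    eul = (rng.uniform(0, 360), rng.uniform(0, 180), rng.uniform(0, 360))
    mat = rotation_matrix(*eul)
    back = rotation_matrix(*euler_from_matrix(mat))
    assert np.allclose(mat, back, atol=1e-9)
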