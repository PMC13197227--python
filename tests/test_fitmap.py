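"""Density simulation, rigid-body fitting and helical tiling."""

import numpy as np
import pytest

from pdtomo import fitmap, lattice, phantom
from pdtomo.beads import BeadModel, Transform
from pdtomo.fitmap import (
    map_cross_correlation,
    rigid_fit,
    simulate_density,
    tile_helical_model,
)
from pdtomo.volume import Volume

# chiral, weight-graded unit: unambiguous to fit at ~3 nm resolution
UNIT = BeadModel(
    [[-3.0, 0.0, 0.0], [0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0], [0.0, 0.0, 3.0]],
    [1.0, 2.0, 1.0, 1.5, 1.0],
    [1.0, 1.0, 1.0, 1.0, 1.0],
    "test_unit",
)


class TestSimulateDensity:
    def test_single_bead_integral_and_maximum(self):
        m = BeadModel([[0, 0, 0]], [1.0], [1.0])
        v = simulate_density(m, 3.3, 0.76, 32)
        assert float(v.data.sum()) == pytest.approx(1.0, rel=0.01)
        assert np.unravel_index(np.argmax(v.data), v.shape) == (15, 15, 15)

    def test_two_separated_beads_give_two_maxima(self):
        m = BeadModel([[-5.0, 0, 0], [5.0, 0, 0]], [1, 1], [1, 1])
        v = simulate_density(m, 3.3, 0.76, 48)
        profile = v.data[:, 23, 23] + v.data[:, 24, 24]
        peaks = [
            i for i in range(1, 47)
            if profile[i] > profile[i - 1] and profile[i] > profile[i + 1]
            and profile[i] > 0.3 * profile.max()
        ]
        assert len(peaks) == 2

    def test_weight_linearity(self):
        m1 = BeadModel([[1, 0, 0], [0, 2, -1]], [1.0, 2.0], [1.0, 1.0])
        m2 = BeadModel([[1, 0, 0], [0, 2, -1]], [2.0, 4.0], [1.0, 1.0])
        v1 = simulate_density(m1, 3.3, 0.76, 32)
        v2 = simulate_density(m2, 3.3, 0.76, 32)
        assert np.allclose(v2.data, 2.0 * v1.data, atol=1e-6)

    def test_bead_outside_box_rejected(self):
        m = BeadModel([[100.0, 0, 0]], [1.0], [1.0])
        with pytest.raises(ValueError, match="outside"):
            simulate_density(m, 3.3, 0.76, 32)


class TestMapCrossCorrelation:
    def test_self_and_negation(self):
        v = simulate_density(UNIT, 3.3, 0.76, 32)
        assert map_cross_correlation(v, v) == pytest.approx(1.0)
        neg = Volume(-v.data, v.voxel_size_nm)
        assert map_cross_correlation(v, neg) == pytest.approx(-1.0)

    def test_rotated_copy_scores_below_self(self):
        v = simulate_density(UNIT.centered(), 3.3, 0.76, 32)
        rot = simulate_density(
            UNIT.centered().transformed(Transform(euler_deg=(90, 0, 0))), 3.3, 0.76, 32
        )
        assert map_cross_correlation(v, rot) < map_cross_correlation(v, v) - 0.05

    def test_equivariance_under_rigid_motion(self):
        """Simulating a transformed model ~ transforming the simulated map."""
        from scipy.ndimage import affine_transform

        from pdtomo.euler import rotation_matrix

        eul = (40.0, 25.0, 10.0)
        direct = simulate_density(
            UNIT.centered().transformed(Transform(euler_deg=eul)), 3.3, 0.76, 32
        )
        base = simulate_density(UNIT.centered(), 3.3, 0.76, 32)
        mat = rotation_matrix(*eul)
        c = (np.array(base.shape) - 1) / 2.0
        inv = np.linalg.inv(mat)
        rotated = affine_transform(
            base.data.astype(float), inv, offset=c - inv @ c, order=1
        )
        assert map_cross_correlation(direct.data, rotated) > 0.99


class TestRigidFit:
    def test_identity_target_recovered(self):
        target = simulate_density(UNIT.centered(), 3.3, 0.76, 32).normalized()
        fit = rigid_fit(UNIT.centered(), target, 3.3, angular_step_deg=45)
        assert fit.score > 0.98
        assert not fit.flagged
        assert np.linalg.norm(fit.transform.translation_nm) < 0.76

    def test_known_rotation_recovered(self):
        t_true = Transform(euler_deg=(20.0, 0.0, 0.0))
        target = simulate_density(UNIT.centered().transformed(t_true), 3.3, 0.76, 32).normalized()
        fit = rigid_fit(UNIT.centered(), target, 3.3, angular_step_deg=15)
        moved = UNIT.centered().transformed(fit.transform)
        truth = UNIT.centered().transformed(t_true)
        rmsd = np.sqrt(np.mean(np.sum((moved.positions_nm - truth.positions_nm) ** 2, axis=1)))
        assert rmsd < 1.0
        assert fit.score > 0.95

    def test_pure_noise_target_flagged(self):
        rng = np.random.default_rng(0)
        noise = Volume(rng.standard_normal((32,) * 3).astype(np.float32), 0.76).normalized()
        fit = rigid_fit(UNIT.centered(), noise, 3.3, angular_step_deg=60, refine=False)
        assert fit.score < 0.3
        assert fit.flagged

    def test_roundtrip_over_seeded_random_transforms(self):
        """20 random rigid motions recovered within search granularity."""
        rng = np.random.default_rng(42)
        failures = 0
        for _ in range(20):
            eul = (rng.uniform(0, 360), rng.uniform(0, 180), rng.uniform(0, 360))
            shift = rng.uniform(-2.5, 2.5, 3)
            t_true = Transform(euler_deg=eul, translation_nm=shift)
            target = simulate_density(
                UNIT.centered().transformed(t_true), 3.3, 0.76, 32
            ).normalized()
            fit = rigid_fit(UNIT.centered(), target, 3.3, angular_step_deg=30)
            moved = UNIT.centered().transformed(fit.transform)
            truth = UNIT.centered().transformed(t_true)
            rmsd = np.sqrt(np.mean(np.sum((moved.positions_nm - truth.positions_nm) ** 2, axis=1)))
            if not (fit.score > 0.9 and rmsd < 1.5):
                failures += 1
        assert failures == 0

    def test_empty_search_rejected(self):
        target = simulate_density(UNIT.centered(), 3.3, 0.76, 32)
        with pytest.raises(ValueError):
            rigid_fit(UNIT.centered(), target, 3.3, angular_step_deg=0)


class TestTileHelicalModel:
    AXIS = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]])

    def test_bead_count_multiplies(self):
        coat = phantom.CoatSpec(n_starts=4, tube_radius_nm=16.0, axial_rise_nm=1.0,
                                subunits_per_turn=10)
        unit = BeadModel(np.zeros((5, 3)) + [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]],
                         np.ones(5), np.ones(5))
        tiled = tile_helical_model(unit, coat, self.AXIS, n_per_wrap=10)
        assert len(tiled) == 5 * 4 * 10

    def test_single_start_single_copy_is_transformed_unit(self):
        coat = phantom.CoatSpec(n_starts=1, tube_radius_nm=16.0, axial_rise_nm=5.0)
        unit = BeadModel([[0, 0, 0], [1.0, 0, 0]], [1, 1], [1, 1])
        tiled = tile_helical_model(unit, coat, self.AXIS, n_per_wrap=1)
        assert len(tiled) == 2
        r = np.hypot(tiled.positions_nm[0][0], tiled.positions_nm[0][1])
        assert r == pytest.approx(16.0, abs=1e-6)

    def test_tiled_map_recovers_four_starts(self):
        """Round trip: tiled model -> simulated map -> lattice analysis."""
        coat = phantom.CoatSpec(n_starts=4, tube_radius_nm=16.0, axial_rise_nm=1.65)
        unit = BeadModel(
            [[-2.8, 0, 0], [-1.4, 0, 0], [0, 0, 0.6], [1.4, 0, 0], [2.8, 0, 0]],
            np.ones(5), np.ones(5),
        )
        axis = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 44.0]])
        tiled = tile_helical_model(unit, coat, axis, n_per_wrap=24)
        centred = BeadModel(
            tiled.positions_nm - [0, 0, 22.0], tiled.weights, tiled.radii_nm
        )
        vol = simulate_density(centred, 3.3, 0.76, 64)
        sheet = lattice.unwrap_cylinder(
            vol, vol.centre_nm(), (0, 0, 1), 16.6, axial_range_nm=(-20, 20)
        )
        res = lattice.estimate_starts_and_pitch(sheet)
        assert res.n_starts == 4

    def test_tiled_map_matches_phantom_coat_density(self):
        """Tiling the correct unit recapitulates the phantom's own coat."""
        spec = phantom.preset(
            "wt_proto", seed=1, noise_snr=np.inf, tilt_range_deg=(-89.9, 89.9),
            amplitudes={"wall": 0.0, "membrane": 0.0, "protein": 1.0},
            tethers=phantom.TetherSpec(density_per_turn=0.0),
        )
        vol, gt = phantom.build_phantom(spec)
        lo, hi = gt.coat_intervals_nm[0]
        axis = np.array([[48.26, 48.26, 0.0], [48.26, 48.26, 96.0]])
        sites = phantom.helical_lattice_points(spec.coat, axis, [(lo, hi)])
        from pdtomo.euler import rotation_matrix

        copies = []
        for pos, eul in sites:
            mat = rotation_matrix(*eul)
            tmpl = spec.coat.subunit_template
            copies.append(BeadModel(tmpl.positions_nm @ mat.T + pos, tmpl.weights, tmpl.radii_nm))
        tiled = BeadModel.concatenate(copies)
        sim = simulate_density(tiled, 3.3, spec.voxel_size_nm, 128, centre_nm=np.zeros(3))
        # mask: cylindrical shell around the coat layer within the interval
        vs = spec.voxel_size_nm
        g = np.indices(vol.shape, dtype=float) * vs
        r = np.hypot(g[0] - 48.26, g[1] - 48.26)
        mask = ((np.abs(r - spec.coat.tube_radius_nm) < 4.0)
                & (g[2] > lo) & (g[2] < hi)).astype(float)
        cc = map_cross_correlation(vol.data, sim.data, mask)
        assert cc > 0.7
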