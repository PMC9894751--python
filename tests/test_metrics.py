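"""Pattern read-outs: order parameter, Pearson agreement, exit bias,
loops, edge currents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nemaglide as ng


class TestOrderParameter:
    @pytest.mark.parametrize(
        "n,v,expected",
        [
            ((1.0, 0.0), (0.2, 0.0), 1.0),     # parallel
            ((1.0, 0.0), (0.0, -0.3), -1.0),   # orthogonal
            (np.pi / 4, (1.0, 0.0), 0.0),      # 45° between v and n
        ],
    )
    def test_reference_values(self, n, v, expected):
        assert np.isclose(ng.order_parameter(n, v), expected)

    def test_zero_velocity_undefined(self):
        with pytest.raises(ValueError):
            ng.order_parameter(0.0, (0.0, 0.0))

    @settings(max_examples=60, derandomize=True)
    @given(
        phi=st.floats(0, np.pi),
        vx=st.floats(-5, 5),
        vy=st.floats(-5, 5),
    )
    def test_bounds_and_gauge_invariance(self, phi, vx, vy):
        if abs(vx) + abs(vy) < 1e-3:
            return
        v = np.array([vx, vy])
        s = ng.order_parameter(phi, v)
        assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9
        assert np.isclose(ng.order_parameter(phi + np.pi, v), s)   # n → −n
        assert np.isclose(ng.order_parameter(phi, -v), s)          # v → −v


class TestPearson:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        img = rng.random((300, 300))
        assert np.isclose(ng.pearson_images(img, img), 1.0)

    def test_inverted_image_minus_one(self):
        rng = np.random.default_rng(1)
        img = rng.random((300, 300))
        assert np.isclose(ng.pearson_images(img, img.max() - img), -1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.random((512, 512))
        b = rng.random((512, 512))
        assert abs(ng.pearson_images(a, b)) < 0.05

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.random((256, 256))
        b = rng.random((256, 256)) + 0.3 * a
        r1 = ng.pearson_images(a, b)
        assert np.isclose(ng.pearson_images(b, a), r1)
        assert np.isclose(ng.pearson_images(a, 3.0 * b + 7.0), r1)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            ng.pearson_images(np.ones((64, 64)), np.random.default_rng(0).random((64, 64)))


class TestDirectionFraction:
    @pytest.mark.parametrize(
        "n1,n2,expected", [(9, 1, 0.9), (5, 5, 0.5), (14, 1, 14 / 15)]
    )
    def test_fraction_values(self, n1, n2, expected):
        res = ng.direction_fraction(ng.DirectionCounts(n1, n2))
        assert np.isclose(res.fraction, expected)

    def test_binomial_p_value(self):
        res = ng.direction_fraction(ng.DirectionCounts(14, 1))
        assert res.p_value < 0.01
        even = ng.direction_fraction(ng.DirectionCounts(5, 5))
        assert even.p_value == 1.0

    def test_empty_counts_undefined(self):
        with pytest.raises(ValueError):
            ng.direction_fraction(ng.DirectionCounts(0, 0))


class TestExits:
    @pytest.fixture(scope="class")
    def skew_run(self):
        fld = ng.make_asymmetric_plus_half(0.4)
        defect = [d for d in ng.detect_defects(fld) if d.charge == 0.5][0]
        params = ng.SimParams(alignment_rate=0.03, n_steps=25000, seed=9)
        trajectories = ng.simulate(fld, 100, params)
        return fld, defect, trajectories

    def test_skewed_defect_biased_exit(self, skew_run):
        fld, defect, trajectories = skew_run
        counts = ng.classify_exits(trajectories, defect)
        res = ng.direction_fraction(counts)
        assert counts.total >= 10
        assert res.fraction > 0.5
        assert res.p_value < 0.05
        # preferred side matches the rotation-minimizing streamline direction
        seed = ng.make_seed(defect, fld)
        cross = defect.axis[0] * seed.direction[1] - defect.axis[1] * seed.direction[0]
        majority_cross = 1.0 if counts.n1 > counts.n2 else -1.0
        assert np.sign(cross) == majority_cross

    def test_mirrored_skew_flips_side(self, skew_run):
        _, _, _ = skew_run
        fld_m = ng.make_asymmetric_plus_half(-0.4)
        defect_m = [d for d in ng.detect_defects(fld_m) if d.charge == 0.5][0]
        params = ng.SimParams(alignment_rate=0.03, n_steps=25000, seed=9)
        trajectories = ng.simulate(fld_m, 100, params)
        counts = ng.classify_exits(trajectories, defect_m)
        assert counts.n1 > counts.n2  # mirror of the skew=+0.4 majority

    def test_symmetric_defect_unbiased(self):
        fld = ng.make_asymmetric_plus_half(0.0)
        defect = [d for d in ng.detect_defects(fld) if d.charge == 0.5][0]
        params = ng.SimParams(alignment_rate=0.03, n_steps=15000, seed=9)
        trajectories = ng.simulate(fld, 60, params)
        counts = ng.classify_exits(trajectories, defect)
        if counts.total >= 5:
            res = ng.direction_fraction(counts)
            assert res.p_value > 0.05

    def test_no_crossings_empty_counts(self, uniform_field):
        fake = ng.Defect(np.array([20.0, 20.0]), 0.5, axis=np.array([1.0, 0.0]))
        t = np.arange(10) * 0.1
        far = ng.Trajectory(t, np.full(10, 35.0), np.full(10, 35.0), np.zeros(10))
        counts = ng.classify_exits([far], fake)
        assert counts.total == 0


class TestLoops:
    def test_explicit_ccw_circle(self):
        t = np.linspace(0, 2 * np.pi, 100)
        pts = np.stack([10 + 3 * np.cos(t), 10 + 3 * np.sin(t)], 1)
        recs = ng.detect_loops([pts], closure_tol=0.5)
        assert len(recs) == 1
        assert recs[0].chirality == "CCW"
        assert recs[0].signed_area > 0

    def test_open_path_no_loop(self):
        pts = np.stack([np.linspace(0, 30, 100), np.full(100, 5.0)], 1)
        assert ng.detect_loops([pts]) == []

    def test_confined_simulation_loop_encloses_plus_one(self):
        fld = ng.make_confined_field(30.0, 2, 0, seed=3)
        dets = ng.detect_defects(fld)
        params = ng.SimParams(alignment_rate=0.03, n_steps=30000, seed=17)
        trajectories = ng.simulate(fld, 15, params)
        ds = [
            ng.Trajectory(t.t[::20], t.x[::20], t.y[::20], t.theta[::20])
            for t in trajectories
        ]
        recs = ng.detect_loops(ds, fld, dets, closure_tol=1.0)
        assert recs
        for rec in recs:
            assert rec.enclosed_charge == 1.0
            assert rec.n_plus - rec.n_minus == 2
            # bookkeeping identity for half-integer defects
            assert np.isclose(rec.enclosed_charge, (rec.n_plus - rec.n_minus) / 2)

    def test_mirror_flips_chirality_preserves_counts(self):
        t = np.linspace(0, 2 * np.pi, 120)
        pts = np.stack([10 + 4 * np.cos(t), 12 + 3 * np.sin(t)], 1)
        rec = ng.detect_loops([pts], closure_tol=0.5)[0]
        mirrored = pts.copy()
        mirrored[:, 1] = 24 - mirrored[:, 1]
        rec_m = ng.detect_loops([mirrored], closure_tol=0.5)[0]
        assert {rec.chirality, rec_m.chirality} == {"CW", "CCW"}
        assert np.isclose(abs(rec.signed_area), abs(rec_m.signed_area), rtol=1e-6)


class TestEdgeStats:
    def test_pure_cw_orbit_counts(self):
        # CW in the image frame = negative tangential sign = negative area
        R, n, n_frames = 20.0, 8, 60
        t = np.arange(n_frames) * 1.0
        trajectories = []
        for k in range(n):
            phase = 2 * np.pi * k / n
            ang = phase - 0.05 * t  # decreasing polar angle: CW
            trajectories.append(
                ng.Trajectory(
                    t, 25 + 19 * np.cos(ang), 25 + 19 * np.sin(ang), np.zeros(n_frames)
                )
            )
        stats = ng.edge_stats(trajectories, R, center=(25.0, 25.0))
        assert np.all(stats.cw_minus_ccw[1:-1] == n)
        assert np.all(stats.n_band == n)

    def test_no_particles_in_band_flagged(self):
        t = np.arange(10) * 1.0
        inner = ng.Trajectory(t, np.full(10, 25.0), np.full(10, 25.0), np.zeros(10))
        stats = ng.edge_stats([inner], 20.0, center=(25.0, 25.0))
        assert stats.empty

    def test_handedness_selection_under_confinement(self):
        # rim-adjacent defects destabilize one circulation direction
        fld = ng.make_confined_field(40.0, 3, 1, seed=3, max_radius_frac=0.9)
        cx, cy = fld.confinement_center
        init = []
        n = 50
        for i in range(n):
            a = 2 * np.pi * i / n
            tang = a + np.pi / 2 if i % 2 == 0 else a - np.pi / 2
            init.append((cx + 37.0 * np.cos(a), cy + 37.0 * np.sin(a), tang))
        params = ng.SimParams(alignment_rate=0.03, n_steps=40000, seed=53)
        trajectories = ng.simulate(fld, n, params, init=init)
        stats = ng.edge_stats(trajectories, 40.0, center=(cx, cy))
        start = abs(stats.cw_minus_ccw[1])
        end = abs(stats.cw_minus_ccw[-1])
        assert start <= 5
        assert end >= 0.5 * stats.n_band[-1]
        # the group that started with the losing handedness moved inward
        winner = "CW" if stats.cw_minus_ccw[-1] > 0 else "CCW"
        loser = "CCW" if winner == "CW" else "CW"
        lose_r = stats.group_mean_radius[loser]["mean"]
        win_r = stats.group_mean_radius[winner]["mean"]
        assert lose_r[-1] < win_r[-1]
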