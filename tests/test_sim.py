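"""Stochastic gliding-particle simulator: integrator contracts, closed
forms, boundary handling and occupancy."""

import numpy as np
import pytest

import nemaglide as ng


class TestStep:
    def test_noise_free_straight_line(self, uniform_field):
        params = ng.SimParams(
            alignment_rate=0.0, persistence_length=np.inf, dt=0.1, n_steps=100, seed=0
        )
        trs = ng.simulate(uniform_field, 1, params, init=[(20.0, 20.0, 0.3)])
        tr = trs[0]
        d = np.hypot(np.diff(tr.x), np.diff(tr.y))
        assert np.allclose(d, params.speed * params.dt, rtol=0, atol=1e-12)
        assert np.allclose(tr.theta, 0.3)

    def test_alignment_closed_form(self, uniform_field):
        # uniform φ=0, noise off: tan θ(t) = tan θ0 · exp(−2At)
        A, dt, th0 = 0.05, 0.01, 0.7
        params = ng.SimParams(
            alignment_rate=A, persistence_length=np.inf, dt=dt, n_steps=2000, seed=0
        )
        trs = ng.simulate(uniform_field, 1, params, init=[(20.0, 20.0, th0)])
        predicted = np.arctan(np.tan(th0) * np.exp(-2 * A * trs[0].t))
        rel = np.abs(trs[0].theta - predicted) / np.abs(predicted)
        assert rel.max() < 1e-3

    def test_convergence_with_halved_dt(self, uniform_field):
        A, th0, t_end = 0.05, 0.7, 10.0
        errs = []
        for dt in (0.1, 0.05):
            params = ng.SimParams(
                alignment_rate=A, persistence_length=np.inf, dt=dt,
                n_steps=int(t_end / dt), seed=0,
            )
            tr = ng.simulate(uniform_field, 1, params, init=[(20.0, 20.0, th0)])[0]
            exact = np.arctan(np.tan(th0) * np.exp(-2 * A * t_end))
            errs.append(abs(tr.theta[-1] - exact))
        assert errs[1] < 0.6 * errs[0]  # ~first-order in dt

    def test_perpendicular_fixed_point(self, uniform_field):
        # θ0 = π/2 in a φ=0 field is an (unstable) torque equilibrium
        params = ng.SimParams(
            alignment_rate=0.1, persistence_length=np.inf, dt=0.1, n_steps=50, seed=0
        )
        tr = ng.simulate(uniform_field, 1, params, init=[(20.0, 20.0, np.pi / 2)])[0]
        assert np.allclose(tr.theta, np.pi / 2)

    def test_single_step_matches_simulate(self, random_six_defect):
        _, fld = random_six_defect
        params = ng.SimParams(alignment_rate=0.05, dt=0.1, n_steps=1, seed=3)
        state = ng.AgentState(np.array([40.0, 55.0]), 1.0)
        rng = np.random.default_rng([3, 0])
        out = ng.step(state, fld, params, rng)
        tr = ng.simulate(fld, 1, params, init=[(40.0, 55.0, 1.0)])[0]
        assert np.allclose(out.position, [tr.x[1], tr.y[1]])
        assert np.isclose(out.theta, tr.theta[1])

    def test_nematic_symmetry_of_torque(self, uniform_field):
        # the torque is π-periodic in θ: flipping the heading by π leaves the
        # angular dynamics identical and point-reflects the path
        params = ng.SimParams(
            alignment_rate=0.05, persistence_length=np.inf, dt=0.1, n_steps=200, seed=0
        )
        a = ng.simulate(uniform_field, 1, params, init=[(20.0, 20.0, 0.8)])[0]
        b = ng.simulate(
            uniform_field, 1, params, init=[(20.0, 20.0, 0.8 + np.pi)]
        )[0]
        assert np.allclose((b.theta - a.theta) % (2 * np.pi), np.pi)
        assert np.allclose(b.x - 20.0, -(a.x - 20.0), atol=1e-12)
        assert np.allclose(b.y - 20.0, -(a.y - 20.0), atol=1e-12)


class TestSimulate:
    def test_same_seed_bit_identical(self, random_six_defect):
        _, fld = random_six_defect
        params = ng.SimParams(alignment_rate=0.03, n_steps=300, seed=9)
        a = ng.simulate(fld, 5, params)
        b = ng.simulate(fld, 5, params)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x)
            assert np.array_equal(ta.theta, tb.theta)

    def test_particle_streams_independent_of_population(self, random_six_defect):
        _, fld = random_six_defect
        params = ng.SimParams(alignment_rate=0.03, n_steps=200, seed=9)
        small = ng.simulate(fld, 2, params)
        large = ng.simulate(fld, 6, params)
        for i in range(2):
            assert np.array_equal(small[i].x, large[i].x)

    def test_rejects_fully_masked_field(self):
        fld = ng.DirectorField(np.zeros((11, 11)), 1.0, mask=np.zeros((11, 11), bool))
        with pytest.raises(ValueError):
            ng.simulate(fld, 1, ng.SimParams(n_steps=10))

    def test_zero_coupling_occupancy_uniform(self, random_six_defect):
        # A = 0: no coupling to the field; final positions spread uniformly
        _, fld = random_six_defect
        params = ng.SimParams(
            alignment_rate=0.0, persistence_length=100.0, dt=0.5, n_steps=4000, seed=2
        )
        trs = ng.simulate(fld, 150, params)
        xf = np.array([tr.x[-1] for tr in trs])
        yf = np.array([tr.y[-1] for tr in trs])
        counts, _, _ = np.histogram2d(xf, yf, bins=3, range=[[0, 100], [0, 100]])
        from scipy import stats

        chi2 = ((counts - 150 / 9) ** 2 / (150 / 9)).sum()
        p = stats.chi2.sf(chi2, df=8)
        assert p > 0.01

    def test_confined_particles_stay_inside(self):
        fld = ng.make_confined_field(20.0, 2, 0, seed=4)
        cx, cy = fld.confinement_center
        params = ng.SimParams(alignment_rate=0.03, n_steps=2000, seed=1)
        trs = ng.simulate(fld, 10, params)
        for tr in trs:
            r = np.hypot(tr.x - cx, tr.y - cy)
            assert r.max() <= 20.0 + 1e-9

    @pytest.mark.parametrize("boundary", ["reflect", "slide"])
    def test_boundary_modes_conserve_speed(self, boundary):
        fld = ng.make_confined_field(15.0, 2, 0, seed=4)
        params = ng.SimParams(
            alignment_rate=0.0, persistence_length=np.inf, dt=0.5,
            n_steps=3000, seed=1, boundary=boundary,
        )
        tr = ng.simulate(fld, 1, params)[0]
        d = np.hypot(np.diff(tr.x), np.diff(tr.y))
        assert np.allclose(d, params.speed * params.dt, atol=1e-12)

    def test_stability_guard(self):
        with pytest.raises(ValueError):
            ng.SimParams(alignment_rate=3.0, dt=0.1)


class TestOccupancy:
    def test_static_particle_single_pixel(self):
        t = np.arange(10) * 0.1
        tr = ng.Trajectory(t, np.full(10, 5.0), np.full(10, 7.5), np.zeros(10))
        img = ng.occupancy_image([tr], (41, 41), 0.5)
        assert img.sum() == 10
        assert img[15, 10] == 10

    def test_total_count_conserved(self, random_six_defect):
        _, fld = random_six_defect
        params = ng.SimParams(alignment_rate=0.03, n_steps=100, seed=5)
        trs = ng.simulate(fld, 4, params)
        img = ng.occupancy_image(trs, fld.shape, fld.pixel_size)
        assert img.sum() == sum(len(tr) for tr in trs)

    def test_straight_mover_one_pixel_line(self):
        t = np.arange(50) * 1.0
        tr = ng.Trajectory(t, 5.0 + 0.5 * t, np.full(50, 10.0), np.zeros(50))
        img = ng.occupancy_image([tr], (61, 61), 0.5)
        rows = np.nonzero(img.sum(axis=1))[0]
        assert list(rows) == [20]


class TestPersistence:
    def test_noise_off_flagged_unreliable(self):
        # wall-free arena: headings never decorrelate without noise
        arena = ng.DirectorField(np.zeros((21, 21)), 50.0)
        params = ng.SimParams(
            alignment_rate=0.0, persistence_length=np.inf, dt=0.1, n_steps=2000, seed=0
        )
        trs = ng.simulate(arena, 5, params, init=[(500.0, 500.0, a) for a in range(5)])
        est = ng.estimate_persistence(trs)
        assert not est.reliable

    def test_short_paths_flagged(self):
        # 10 µm of path cannot constrain L_p = 100 µm
        arena = ng.DirectorField(np.zeros((21, 21)), 20.0)
        params = ng.SimParams(
            alignment_rate=0.0, persistence_length=100.0, dt=0.1, n_steps=1000, seed=0
        )
        trs = ng.simulate(arena, 10, params, init=[(200.0, 200.0, 0.0)] * 10)
        est = ng.estimate_persistence(trs)
        assert not est.reliable
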