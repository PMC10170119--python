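import numpy as np
import pytest

from chaosmorph import rd_core as rc


def cosine_mode_amplitude(profile, x, k):
    c = np.cos(k * x)
    return float(profile @ c) / float(c @ c)


class TestSpatialGrid:
    def test_spacings(self):
        g = rc.SpatialGrid(nx=10, ny=6, Lx=2.0, Ly=1.0)
        assert g.hx == pytest.approx(0.2)
        assert g.hy == pytest.approx(0.2)
        assert len(g.x) == 10 and g.x[-1] < g.Lx  # no duplicated periodic endpoint
        assert g.y[0] == 0.0 and g.y[-1] == g.Ly

    @pytest.mark.parametrize("nx,ny", [(3, 9), (8, 2)])
    def test_too_small_rejected(self, nx, ny):
        with pytest.raises(ValueError):
            rc.SpatialGrid(nx=nx, ny=ny, Lx=1.0, Ly=1.0)


class TestSpecValidation:
    def test_nonpositive_diffusion_rejected(self):
        with pytest.raises(ValueError):
            rc.RDSystemSpec(m=1, D=[0.0], lambdas=[0.0])

    def test_negative_degradation_rejected(self):
        with pytest.raises(ValueError):
            rc.RDSystemSpec(m=1, D=[1.0], lambdas=[-0.1])

    def test_unknown_bc_tag_rejected(self):
        with pytest.raises(ValueError):
            rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.0], bc=[("open", "neumann0")])


class TestSimulateRD:
    def test_analytic_single_mode_decay(self, strip_grid):
        # u_t = d u_xx - lambda u, init cos(kx) -> amplitude exp(-(d k^2 + lambda) t)
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.2])
        X, _ = strip_grid.meshgrid()
        k = 2 * np.pi / strip_grid.Lx
        init = rc.FieldState(0.0, np.cos(k * X)[None])
        dt = 0.9 * rc.stability_dt_bound(spec, strip_grid)
        rec = rc.simulate_rd(spec, strip_grid, init, t_end=1.0, dt=dt, save_every=10 ** 9)
        expected = np.exp(-(1.0 * k ** 2 + 0.2) * rec.times[-1])
        amp = cosine_mode_amplitude(rec.states[-1].values[0][0], strip_grid.x, k)
        assert abs(amp - expected) / expected < 1e-3

    def test_constant_source_fixed_point(self, small_grid):
        # u_t = d lap u - lambda u + c -> u -> c / lambda
        c, lam = 1.2, 0.5
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[lam], sources=[lambda X, Y: np.full_like(X, c)])
        init = rc.FieldState(0.0, np.random.default_rng(0).random((1, small_grid.ny, small_grid.nx)))
        dt = 0.9 * rc.stability_dt_bound(spec, small_grid)
        rec = rc.simulate_rd(spec, small_grid, init, t_end=40.0, dt=dt, save_every=10 ** 9)
        assert np.max(np.abs(rec.states[-1].values - c / lam)) < 1e-6

    def test_dt_over_cfl_rejected(self, small_grid):
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.0])
        init = rc.FieldState(0.0, np.zeros((1, small_grid.ny, small_grid.nx)))
        bad_dt = 2.0 * rc.stability_dt_bound(spec, small_grid)
        with pytest.raises(ValueError, match="stability"):
            rc.simulate_rd(spec, small_grid, init, t_end=1.0, dt=bad_dt)

    def test_blowup_reports_last_finite_time(self, small_grid):
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.0], reaction=lambda u: (u ** 3,))
        init = rc.FieldState(0.0, np.full((1, small_grid.ny, small_grid.nx), 5.0))
        dt = 0.5 * rc.stability_dt_bound(spec, small_grid)
        with pytest.raises(rc.BlowUpError) as err:
            rc.simulate_rd(spec, small_grid, init, t_end=10.0, dt=dt)
        assert np.isfinite(err.value.last_time)

    def test_conservation_trapezoidal_mass(self, small_grid):
        # f = 0, lambda = 0, no source/noise, periodic + Neumann: the
        # trapezoidal y-quadrature of each component is conserved
        spec = rc.RDSystemSpec(m=1, D=[0.7], lambdas=[0.0])
        rng = np.random.default_rng(1)
        init = rc.FieldState(0.0, rng.random((1, small_grid.ny, small_grid.nx)))
        dt = 0.9 * rc.stability_dt_bound(spec, small_grid)
        rec = rc.simulate_rd(spec, small_grid, init, t_end=1.0, dt=dt, save_every=10 ** 9)

        def mass(v):
            w = np.ones(small_grid.ny)
            w[0] = w[-1] = 0.5
            return float(np.sum(w[:, None] * v))

        m0 = mass(rec.states[0].values[0])
        m1 = mass(rec.states[-1].values[0])
        assert abs(m1 - m0) <= 1e-10 * max(1.0, abs(m0))

    def test_second_order_spatial_convergence(self):
        # halving hx and hy reduces the decay-amplitude error ~4x
        errors = []
        for nx, ny in [(32, 5), (64, 9)]:
            grid = rc.SpatialGrid(nx=nx, ny=ny, Lx=2 * np.pi, Ly=1.0)
            spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.2])
            X, _ = grid.meshgrid()
            k = 2 * np.pi / grid.Lx
            init = rc.FieldState(0.0, np.cos(k * X)[None])
            dt = 0.2 * rc.stability_dt_bound(spec, rc.SpatialGrid(nx=64, ny=9, Lx=2 * np.pi, Ly=1.0))
            rec = rc.simulate_rd(spec, grid, init, t_end=1.0, dt=dt, save_every=10 ** 9)
            expected = np.exp(-(k ** 2 + 0.2) * rec.times[-1])
            amp = cosine_mode_amplitude(rec.states[-1].values[0][0], grid.x, k)
            errors.append(abs(amp - expected))
        ratio = errors[0] / errors[1]
        assert 3.0 < ratio < 5.0

    def test_determinism_with_noise(self, small_grid):
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.1], noise_amplitude=0.01)
        init = rc.FieldState(0.0, np.zeros((1, small_grid.ny, small_grid.nx)))
        dt = 0.5 * rc.stability_dt_bound(spec, small_grid)
        r1 = rc.simulate_rd(spec, small_grid, init, t_end=0.5, dt=dt, save_every=20, seed=42)
        r2 = rc.simulate_rd(spec, small_grid, init, t_end=0.5, dt=dt, save_every=20, seed=42)
        assert np.array_equal(r1.times, r2.times)
        for a, b in zip(r1.states, r2.states):
            assert np.array_equal(a.values, b.values)

    def test_noise_scales_with_sqrt_dt(self, small_grid):
        # one Euler-Maruyama step from zero: std of field ~ amplitude * sqrt(dt)
        amp = 0.05
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.0], noise_amplitude=amp)
        init = rc.FieldState(0.0, np.zeros((1, small_grid.ny, small_grid.nx)))
        dt = 0.5 * rc.stability_dt_bound(spec, small_grid)
        rec = rc.simulate_rd(spec, small_grid, init, t_end=dt * 0.999, dt=dt, seed=9)
        observed = np.std(rec.states[-1].values)
        assert observed == pytest.approx(amp * np.sqrt(dt), rel=0.15)


class TestDispersion:
    def test_scalar_closed_form(self):
        spec = rc.RDSystemSpec(m=1, D=[2.0], lambdas=[0.3])
        rates = rc.dispersion_growth_rates(spec, [0.0], [1.0])
        assert rates[0] == pytest.approx(-2.3)

    def test_k_zero_is_reaction_spectrum(self):
        # at k=0 the diffusion term vanishes
        def reaction(u, v):
            return (0.5 * v, -0.2 * u)

        spec = rc.RDSystemSpec(m=2, D=[1.0, 3.0], lambdas=[0.4, 0.1], reaction=reaction)
        rates = rc.dispersion_growth_rates(spec, [0.0, 0.0], [0.0])
        J = np.array([[0.0, 0.5], [-0.2, 0.0]]) - np.diag([0.4, 0.1])
        expected = float(np.max(np.linalg.eigvals(J).real))
        assert rates[0] == pytest.approx(expected, abs=1e-8)

    def test_non_equilibrium_rejected(self):
        spec = rc.RDSystemSpec(m=1, D=[1.0], lambdas=[0.5])
        with pytest.raises(ValueError, match="residual"):
            rc.dispersion_growth_rates(spec, [1.0], [0.0])

    def test_turing_band(self):
        # activator-inhibitor with d_u << D_v: stable at k=0, unstable band at k>0.
        # Oracle: brute-force eigenvalues of the 2x2 linearization over a k grid.
        a, b = 2.0, 3.0

        def brusselator(u, v):
            return (a - (b + 1.0) * u + u ** 2 * v, b * u - u ** 2 * v)

        spec = rc.RDSystemSpec(m=2, D=[0.01, 1.0], lambdas=[0.0, 0.0], reaction=brusselator)
        u0 = [a, b / a]
        ks = np.linspace(0.0, 10.0, 101)
        rates = rc.dispersion_growth_rates(spec, u0, ks)

        J = np.array([[b - 1.0, a * a], [-b, -a * a]])
        oracle = []
        for k in ks:
            A = J - k * k * np.diag([0.01, 1.0])
            oracle.append(np.max(np.linalg.eigvals(A).real))
        oracle = np.asarray(oracle)
        np.testing.assert_allclose(rates, oracle, atol=1e-6)
        assert rates[0] < 0  # homogeneous state stable
        assert np.max(rates[1:]) > 0  # Turing band exists


class TestScreenedPoisson:
    def test_constant_source(self, small_grid):
        src = np.full((small_grid.ny, small_grid.nx), 3.0)
        w = rc.solve_screened_poisson(src, d_w=1.0, b=1.0, grid=small_grid)
        np.testing.assert_allclose(w, -3.0, atol=1e-10)

    def test_single_fourier_mode_b0(self):
        grid = rc.SpatialGrid(nx=128, ny=9, Lx=1.0, Ly=1.0)
        k = 2 * np.pi / grid.Lx
        src = np.tile(np.sin(k * grid.x), (grid.ny, 1))
        w = rc.solve_screened_poisson(src, d_w=1.0, b=0.0, grid=grid)
        expected = -np.sin(k * grid.x) / k ** 2
        # second-order accuracy in hx
        assert np.max(np.abs(w[grid.ny // 2] - expected)) < 5e-4

    def test_b0_nonzero_mean_rejected(self, small_grid):
        src = np.ones((small_grid.ny, small_grid.nx))
        with pytest.raises(ValueError, match="zero-mean"):
            rc.solve_screened_poisson(src, d_w=1.0, b=0.0, grid=small_grid)

    def test_dense_direct_solve_oracle(self):
        # random smooth source on a 32x17 grid vs a dense-matrix solve
        grid = rc.SpatialGrid(nx=32, ny=17, Lx=1.0, Ly=1.0)
        rng = np.random.default_rng(7)
        X, Y = grid.meshgrid()
        src = np.zeros((grid.ny, grid.nx))
        for _ in range(4):
            kx = rng.integers(1, 4)
            src += rng.normal() * np.sin(2 * np.pi * kx * X / grid.Lx) * np.cos(np.pi * Y / grid.Ly)
        d_w, b = 1.0, 0.7
        w = rc.solve_screened_poisson(src, d_w=d_w, b=b, grid=grid)

        # oracle: build the dense operator by probing the discrete Laplacian
        n = grid.ny * grid.nx
        A = np.zeros((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            A[:, j] = (d_w * rc.laplacian(e.reshape(grid.ny, grid.nx), grid,
                                          ("neumann0", "neumann0")) - b * b * e.reshape(grid.ny, grid.nx)).ravel()
        w_dense = np.linalg.solve(A, src.ravel()).reshape(grid.ny, grid.nx)
        np.testing.assert_allclose(w, w_dense, atol=1e-10)

    def test_residual_bound(self, small_grid):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(small_grid.ny, small_grid.nx))
        w = rc.solve_screened_poisson(src, d_w=0.5, b=0.7, grid=small_grid)
        resid = 0.5 * rc.laplacian(w, small_grid, ("neumann0", "neumann0")) - 0.49 * w - src
        assert np.max(np.abs(resid)) < 1e-8 * np.max(np.abs(src))

    def test_dirichlet_rows_pinned(self):
        grid = rc.SpatialGrid(nx=16, ny=9, Lx=1.0, Ly=1.0)
        src = np.ones((grid.ny, grid.nx))
        w = rc.solve_screened_poisson(src, d_w=1.0, b=0.0, grid=grid, bc=("dirichlet0", "dirichlet0"))
        assert np.all(w[0] == 0.0) and np.all(w[-1] == 0.0)
        assert np.any(w[1:-1] != 0.0)


class TestLinearizationConsistency:
    def test_mode_growth_matches_dispersion(self):
        # small perturbation of the Brusselator equilibrium grows at the
        # dispersion rate of its wavenumber (within 5% over a short horizon)
        a, b = 2.0, 3.0

        def brusselator(u, v):
            return (a - (b + 1.0) * u + u ** 2 * v, b * u - u ** 2 * v)

        grid = rc.SpatialGrid(nx=64, ny=3, Lx=2 * np.pi, Ly=1.0)
        spec = rc.RDSystemSpec(m=2, D=[0.01, 1.0], lambdas=[0.0, 0.0], reaction=brusselator)
        u0 = np.array([a, b / a])
        ks = np.arange(0, 8, dtype=float)
        rates = rc.dispersion_growth_rates(spec, u0, ks)
        kidx = int(np.argmax(rates))
        k, rate = ks[kidx], rates[kidx]
        assert rate > 0

        X, _ = grid.meshgrid()
        pert = 1e-4 * np.cos(k * X)
        init = rc.FieldState(0.0, np.stack([u0[0] + pert, u0[1] + pert]))
        dt = 0.9 * rc.stability_dt_bound(spec, grid)
        rec = rc.simulate_rd(spec, grid, init, t_end=3.0, dt=dt, save_every=max(1, int(0.5 / dt)))

        amps = []
        for st in rec.states:
            amps.append(abs(cosine_mode_amplitude(st.values[0][0] - u0[0], grid.x, k)))
        amps = np.asarray(amps)
        # measure on a late window where the dominant eigenmode has taken over
        t0, t1 = rec.times[-3], rec.times[-1]
        measured = np.log(amps[-1] / amps[-3]) / (t1 - t0)
        assert measured == pytest.approx(rate, rel=0.05)
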