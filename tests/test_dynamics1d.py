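import math

import numpy as np
import pytest
from scipy.special import exp1

import parabead as pb
from parabead.dynamics1d import step_base, step_diffusion, step_rebinding
from parabead.fields import ParAField1D, simpson_weights


def centered_bead(field):
    return pb.BeadState(x_p=float(field.grid[field.grid.size // 2]))


class TestRemovalRate:
    def test_kernel_peak_is_one_on_unit_field(self, toy_grid_field):
        x_p = float(toy_grid_field.grid[25])
        rate = pb.removal_rate(toy_grid_field, x_p, c=0.5)
        assert rate[25] == pytest.approx(1.0, rel=1e-12)

    def test_kernel_half_width(self):
        # rate falls to 1/2 at |x - x_p| = c*sqrt(2 ln 2)
        field = pb.init_para_field(1.0, 0.0, 10.0, 0.001, seed=0)
        c = 0.5
        x_p = float(field.grid[field.grid.size // 2])
        rate = pb.removal_rate(field, x_p, c)
        half = np.interp(x_p + c * math.sqrt(2 * math.log(2)), field.grid, rate)
        assert half == pytest.approx(0.5, abs=1e-5)

    def test_zero_where_field_zero(self, toy_grid_field):
        values = toy_grid_field.values.copy()
        values[:10] = 0.0
        field = ParAField1D(toy_grid_field.grid, values)
        rate = pb.removal_rate(field, float(field.grid[25]), c=0.5)
        assert np.all(rate[:10] == 0.0)

    def test_static_bead_exponential_decay(self):
        # with the bead pinned, a(x_p, tau) obeys da/dtau = -a exactly
        c, tau_end = 0.5, 1.0
        results = {}
        for dtau in (0.01, 0.005):
            field = pb.init_para_field(1.0, 0.0, 10.0, 0.1, seed=0)
            mid = field.grid.size // 2
            x_p = float(field.grid[mid])
            numerics = pb.NumericsConfig(dx=0.1, dtau=dtau, tau_max=tau_end)
            for _ in range(int(round(tau_end / dtau))):
                values = field.values - dtau * pb.removal_rate(field, x_p, c)
                field = ParAField1D(field.grid, values)
            results[dtau] = field.values[mid]
        exact = math.exp(-tau_end)
        # first-order convergence: halving dtau roughly halves the error
        err_coarse = abs(results[0.01] - exact)
        err_fine = abs(results[0.005] - exact)
        assert err_fine < 0.6 * err_coarse
        assert results[0.005] == pytest.approx(exact, abs=5e-3)

    def test_invalid_c_rejected(self, toy_grid_field):
        with pytest.raises(ValueError):
            pb.removal_rate(toy_grid_field, 5.0, c=0.0)


class TestBeadSpeed:
    def test_uniform_field_centered_bead_is_exactly_zero(self, toy_grid_field):
        x_p = float(toy_grid_field.grid[toy_grid_field.grid.size // 2])
        assert pb.bead_speed(toy_grid_field, x_p, A0=1.0) == 0.0

    def test_half_plane_matches_exponential_integral(self):
        # a = 0 behind, 1 ahead: v = (e^0.5 / 2) * E1(1/2)
        field = pb.init_para_field(1.0, 0.0, 70.0, 0.02, seed=0)
        mid = field.grid.size // 2
        values = np.where(np.arange(field.grid.size) >= mid, 1.0, 0.0)
        half = ParAField1D(field.grid, values)
        v = pb.bead_speed(half, float(field.grid[mid]), A0=1.0)
        closed_form = 0.5 * math.exp(0.5) * exp1(0.5)
        assert v == pytest.approx(closed_form, abs=1e-4)

    def test_point_mass_single_term_oracle(self, toy_grid_field):
        # mass at offset u=+1 contributes A0 * w_j * exp(-1/2) * (1/2)
        grid = toy_grid_field.grid
        mid = grid.size // 2
        j = mid + 5  # offset 5 * 0.2 = 1.0
        values = np.zeros(grid.size)
        values[j] = 1.0
        field = ParAField1D(grid, values)
        w = simpson_weights(grid.size, field.dx)
        expected = 2.0 * w[j] * math.exp(-0.5) * 1.0 / (1.0 + 1.0)
        v = pb.bead_speed(field, float(grid[mid]), A0=2.0)
        assert v == pytest.approx(expected, rel=1e-12)


class TestStepBase:
    def test_flat_field_never_moves(self, toy_grid_field, default_numerics):
        params = pb.DimensionlessParams(delta_a=0.0)
        numerics = pb.NumericsConfig(dx=0.2)
        field, bead = toy_grid_field, centered_bead(toy_grid_field)
        x0 = bead.x_p
        for _ in range(200):
            field, bead = step_base(field, bead, params, numerics)
        assert bead.x_p == x0  # exact, not approximate

    def test_removal_only_depletion_is_monotone(self):
        field = pb.init_para_field(1.0, 0.1, 10.0, 0.1, seed=3)
        params = pb.DimensionlessParams()
        numerics = pb.NumericsConfig(dx=0.1)
        bead = centered_bead(field)
        prev = field.values.copy()
        for _ in range(50):
            field, bead = step_base(field, bead, params, numerics)
            assert np.all(field.values <= prev + 1e-15)
            prev = field.values.copy()

    def test_euler_convergence_is_first_order(self):
        # halving dtau shrinks the trajectory difference ~linearly
        def run(dtau):
            cfg = pb.SimulationConfig(
                params=pb.DimensionlessParams(A0=1.0, c=0.5, L=10.0, delta_a=0.1),
                numerics=pb.NumericsConfig(dx=0.1, dtau=dtau, tau_max=5.0, seed=9),
            )
            return pb.simulate_1d(cfg).positions[-1]

        # compare each dtau against a fine reference
        ref = run(0.00125)
        err = [abs(run(dt) - ref) for dt in (0.01, 0.005)]
        assert err[1] < 0.75 * err[0]

    def test_one_step_matches_naive_loop_oracle(self, toy_grid_field):
        params = pb.DimensionlessParams(A0=1.3, c=0.5)
        numerics = pb.NumericsConfig(dx=0.2)
        rng = np.random.default_rng(0)
        values = 1.0 + 0.1 * (2 * rng.random(toy_grid_field.grid.size) - 1)
        field = ParAField1D(toy_grid_field.grid, values)
        bead = pb.BeadState(x_p=4.9)  # off-node position
        new_field, new_bead = step_base(field, bead, params, numerics)

        grid = field.grid
        n = grid.size
        w = simpson_weights(n, field.dx)
        force = 0.0
        expected = np.empty(n)
        for i in range(n):
            u = grid[i] - bead.x_p
            removal = math.exp(-u * u / (2 * params.c**2)) * values[i]
            expected[i] = values[i] - numerics.dtau * removal
            force += w[i] * math.exp(-0.5 * u * u) * u / (1 + u * u) * values[i]
        v = params.A0 * force
        assert np.allclose(new_field.values, expected, rtol=0, atol=1e-14)
        assert new_bead.v == pytest.approx(v, abs=1e-13)
        assert new_bead.x_p == pytest.approx(bead.x_p + numerics.dtau * v, abs=1e-14)

    def test_bead_clamped_at_boundary(self, toy_grid_field):
        params = pb.DimensionlessParams()
        numerics = pb.NumericsConfig(dx=0.2)
        values = np.zeros(toy_grid_field.grid.size)
        values[-1] = 50.0  # huge pull to the right
        field = ParAField1D(toy_grid_field.grid, values)
        bead = pb.BeadState(x_p=float(toy_grid_field.grid[-2]))
        for _ in range(2000):
            field, bead = step_base(field, bead, params, numerics)
        assert bead.x_p <= float(toy_grid_field.grid[-1])


class TestStepRebinding:
    @staticmethod
    def setup_state(phi=0.5, k_r=0.25, k_c=0.0, seed=0, L=10.0, dx=0.1):
        sites = pb.init_binding_sites(1.0, 0.05, L, dx, seed=seed)
        field, buffer = pb.equilibrate_surface(
            sites, pb.BufferState.from_phi(phi, 1.0), pb.RebindingParams(k_r, k_c)
        )
        return field, sites, buffer

    def test_zero_rates_reduce_to_base_plus_buffer(self, toy_grid_field):
        params = pb.DimensionlessParams()
        numerics = pb.NumericsConfig(dx=0.2)
        sites = pb.init_binding_sites(2.0, 0.0, 10.0, 0.2, seed=0)
        buffer = pb.BufferState(a_b=0.3, A_s=0.3, phi=0.15)
        bead = centered_bead(toy_grid_field)
        rb = pb.RebindingParams(0.0, 0.0)
        f_rb, b_rb, buf2 = step_rebinding(
            toy_grid_field, bead, buffer, sites, rb, params, numerics
        )
        f_base, b_base = step_base(toy_grid_field, bead, params, numerics)
        assert np.array_equal(f_rb.values, f_base.values)
        assert b_rb.x_p == b_base.x_p
        # buffer accumulates exactly the removed ParA / L
        w = simpson_weights(toy_grid_field.grid.size, toy_grid_field.dx)
        removed = w @ pb.removal_rate(toy_grid_field, bead.x_p, params.c)
        assert buf2.a_b == pytest.approx(
            buffer.a_b + numerics.dtau * removed / toy_grid_field.L, rel=1e-12
        )

    def test_total_para_is_conserved(self):
        field, sites, buffer = self.setup_state(phi=1.1)
        params = pb.DimensionlessParams(L=10.0)
        numerics = pb.NumericsConfig(dx=0.1)
        rb = pb.RebindingParams(0.25, 0.0)
        bead = centered_bead(field)
        w = simpson_weights(field.grid.size, field.dx)
        total0 = w @ field.values + field.L * buffer.a_b
        for _ in range(500):
            field, bead, buffer = step_rebinding(
                field, bead, buffer, sites, rb, params, numerics
            )
        total = w @ field.values + field.L * buffer.a_b
        assert total == pytest.approx(total0, rel=1e-12)

    def test_saturated_equilibration_fills_sites(self):
        field, sites, buffer = self.setup_state(phi=1.1)
        assert np.allclose(field.values, sites.values, atol=1e-5)
        assert buffer.a_b > 0

    def test_capacity_violation_rejected(self, toy_grid_field):
        sites = pb.init_binding_sites(0.5, 0.0, 10.0, 0.2, seed=0)
        buffer = pb.BufferState(a_b=0.1, A_s=0.1, phi=0.2)
        with pytest.raises(ValueError, match="capacity"):
            step_rebinding(
                toy_grid_field,  # a = 1 > d = 0.5
                centered_bead(toy_grid_field),
                buffer,
                sites,
                pb.RebindingParams(0.25, 0.0),
                pb.DimensionlessParams(),
                pb.NumericsConfig(dx=0.2),
            )

    def test_one_step_matches_naive_loop_oracle(self):
        field, sites, buffer = self.setup_state(phi=0.8, k_r=0.5, k_c=2.0)
        params = pb.DimensionlessParams(A0=1.0, c=0.5, L=10.0)
        numerics = pb.NumericsConfig(dx=0.1)
        bead = pb.BeadState(x_p=5.03)
        new_field, new_bead, new_buffer = step_rebinding(
            field, bead, buffer, sites, pb.RebindingParams(0.5, 2.0), params, numerics
        )
        grid, a, d = field.grid, field.values, sites.values
        n = grid.size
        w = simpson_weights(n, field.dx)
        expected = np.empty(n)
        flux = 0.0
        for i in range(n):
            u = grid[i] - bead.x_p
            removal = math.exp(-u * u / (2 * params.c**2)) * a[i]
            gain = buffer.a_b * (d[i] - a[i]) * (0.5 + 2.0 * a[i])
            expected[i] = a[i] + numerics.dtau * (gain - removal)
            flux += w[i] * (removal - gain)
        assert np.allclose(new_field.values, expected, rtol=0, atol=1e-14)
        assert new_buffer.a_b == pytest.approx(
            buffer.a_b + numerics.dtau * flux / field.L, rel=1e-12
        )


class TestEquilibrateSurface:
    def test_undersaturated_buffer_empties_onto_surface(self):
        sites = pb.init_binding_sites(1.0, 0.05, 10.0, 0.1, seed=1)
        field, buffer = pb.equilibrate_surface(
            sites, pb.BufferState.from_phi(0.5, 1.0), pb.RebindingParams(0.25, 0.0)
        )
        assert buffer.a_b < 1e-5
        # mass balance: surface holds (almost) all initial buffer ParA
        assert field.total() == pytest.approx(field.L * 0.5, rel=1e-3)

    def test_uniform_fractional_occupancy_without_cooperativity(self):
        # with k_c = 0 the occupancy a/d relaxes uniformly, so a = phi * d
        sites = pb.init_binding_sites(1.0, 0.05, 10.0, 0.1, seed=2)
        field, _ = pb.equilibrate_surface(
            sites, pb.BufferState.from_phi(0.6, 1.0), pb.RebindingParams(0.5, 0.0)
        )
        ratio = field.values / sites.values
        assert np.ptp(ratio) < 1e-6

    def test_no_binding_channel_is_an_error(self):
        sites = pb.init_binding_sites(1.0, 0.05, 10.0, 0.1, seed=0)
        with pytest.raises(ValueError, match="k_r"):
            pb.equilibrate_surface(
                sites, pb.BufferState.from_phi(0.5, 1.0), pb.RebindingParams(0.0, 0.0)
            )


class TestStepDiffusion:
    def test_diffusion_term_vanishes_when_a_proportional_to_d(self):
        sites = pb.init_binding_sites(1.0, 0.05, 10.0, 0.1, seed=4)
        field = ParAField1D(sites.grid, 0.7 * sites.values)
        params = pb.DimensionlessParams(A0=1.0, c=0.5)
        numerics = pb.NumericsConfig(dx=0.1)
        bead = centered_bead(field)
        with_diff, _ = step_diffusion(
            field, bead, sites, pb.DiffusionParams(kappa=0.2), params, numerics
        )
        without, _ = step_diffusion(
            field, bead, sites, pb.DiffusionParams(kappa=0.0), params, numerics
        )
        assert np.allclose(with_diff.values, without.values, atol=1e-13)

    def test_gaussian_pulse_spreads_with_heat_kernel_variance(self):
        # uniform capacity: the flux reduces to kappa*D0*a'' — variance grows
        # by 2*kappa*D0*tau.  Bead parked far away so removal is negligible.
        L, dx, kappa, D0 = 20.0, 0.1, 0.4, 1.0
        sites = pb.init_binding_sites(D0, 0.0, L, dx, seed=0)
        grid = sites.grid
        sigma0 = 0.5
        a0 = 0.5 * np.exp(-((grid - 10.0) ** 2) / (2 * sigma0**2))
        field = ParAField1D(grid, a0)
        params = pb.DimensionlessParams(A0=1.0, c=0.5)
        numerics = pb.NumericsConfig(dx=dx, dtau=0.01)
        bead = pb.BeadState(x_p=0.0)
        tau = 0.5
        for _ in range(int(tau / numerics.dtau)):
            field, bead = step_diffusion(
                field, bead, sites, pb.DiffusionParams(kappa), params, numerics
            )

        def variance(values):
            mass = np.trapezoid(values, grid)
            mu = np.trapezoid(grid * values, grid) / mass
            return np.trapezoid((grid - mu) ** 2 * values, grid) / mass

        grown = variance(field.values) - variance(a0)
        assert grown == pytest.approx(2 * kappa * D0 * tau, rel=0.02)

    def test_cfl_violation_rejected(self):
        sites = pb.init_binding_sites(1.0, 0.0, 10.0, 0.1, seed=0)
        field = ParAField1D(sites.grid, 0.5 * sites.values)
        with pytest.raises(ValueError, match="CFL"):
            step_diffusion(
                field,
                centered_bead(field),
                sites,
                pb.DiffusionParams(kappa=1.0),
                pb.DimensionlessParams(),
                pb.NumericsConfig(dx=0.1, dtau=0.01),
            )

    def test_one_step_matches_naive_loop_oracle(self):
        sites = pb.init_binding_sites(1.0, 0.05, 10.0, 0.1, seed=5)
        rngvals = 0.8 * sites.values * (0.9 + 0.1 * np.cos(sites.grid))
        field = ParAField1D(sites.grid, rngvals)
        params = pb.DimensionlessParams(A0=1.0, c=0.5)
        numerics = pb.NumericsConfig(dx=0.1)
        kappa = 0.3
        bead = pb.BeadState(x_p=5.07)
        new_field, _ = step_diffusion(
            field, bead, sites, pb.DiffusionParams(kappa), params, numerics
        )
        grid, a, d = field.grid, field.values, sites.values
        n = grid.size
        dx2 = field.dx**2

        def second(arr, i):
            if i == 0:
                return 2 * (arr[1] - arr[0]) / dx2
            if i == n - 1:
                return 2 * (arr[-2] - arr[-1]) / dx2
            return (arr[i - 1] - 2 * arr[i] + arr[i + 1]) / dx2

        expected = np.empty(n)
        for i in range(n):
            u = grid[i] - bead.x_p
            removal = math.exp(-u * u / (2 * params.c**2)) * a[i]
            diff = kappa * (d[i] * second(a, i) - a[i] * second(d, i))
            expected[i] = a[i] + numerics.dtau * (diff - removal)
        assert np.allclose(new_field.values, expected, rtol=0, atol=1e-13)


class TestSimulate1D:
    def test_zero_noise_symmetry_is_exact(self):
        cfg = pb.SimulationConfig(
            params=pb.DimensionlessParams(L=10.0, delta_a=0.0),
            numerics=pb.NumericsConfig(dx=0.1, tau_max=10.0),
        )
        traj = pb.simulate_1d(cfg)
        assert np.all(traj.positions == traj.positions[0])
        assert np.all(traj.speeds == 0.0)

    def test_noisy_run_shows_lag_then_steady_motion(self):
        cfg = pb.SimulationConfig(
            params=pb.DimensionlessParams(A0=1.0, c=0.5, L=30.0, delta_a=0.05),
            numerics=pb.NumericsConfig(tau_max=60.0, seed=4),
            stop_displacement=10.0,
        )
        traj = pb.simulate_1d(cfg)
        fit = pb.fit_speed(traj)
        assert fit.lag_time > 0.5
        assert fit.speed > 0.1
        assert fit.r_squared > 0.999

    def test_same_seed_reproduces_trajectory_bitwise(self):
        cfg = pb.SimulationConfig(
            params=pb.DimensionlessParams(L=10.0, delta_a=0.05),
            numerics=pb.NumericsConfig(dx=0.1, tau_max=5.0, seed=11),
        )
        t1 = pb.simulate_1d(cfg)
        t2 = pb.simulate_1d(cfg)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.speeds, t2.speeds)

    def test_snapshots_recorded_at_requested_times(self):
        cfg = pb.SimulationConfig(
            params=pb.DimensionlessParams(L=10.0, delta_a=0.05),
            numerics=pb.NumericsConfig(dx=0.1, tau_max=2.0, seed=0),
            snapshot_taus=(0.0, 1.0),
        )
        traj = pb.simulate_1d(cfg)
        assert set(traj.snapshots) == {0.0, 1.0}
        assert traj.snapshots[0.0].shape == traj.grid.shape

    def test_rebinding_wavefront_grows_when_undersaturated(self):
        # phi < 1: the wavefront amplitude (and the speed) keep rising
        cfg = pb.SimulationConfig(
            mode="rebinding",
            phi=0.5,
            params=pb.DimensionlessParams(A0=1.0, c=0.5, L=70.0),
            rebinding=pb.RebindingParams(k_r=0.25),
            numerics=pb.NumericsConfig(tau_max=100.0, seed=3),
            snapshot_taus=(60.0, 100.0),
        )
        traj = pb.simulate_1d(cfg)
        assert traj.snapshots[100.0].max() > traj.snapshots[60.0].max()
        v = np.abs(traj.speeds)
        n = len(v)
        assert v[int(0.8 * n) :].mean() > v[int(0.4 * n) : int(0.6 * n)].mean()
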