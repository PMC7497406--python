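"""Finite-volume solver: geometry, conservation, oracle agreement, monotonicity."""

from dataclasses import replace

import numpy as np
import pytest

from gelrelease import (
    SolverConfig,
    TransportParams,
    advance,
    analytic_slab_release,
    build_geometry,
    build_grid,
    initial_state,
    run_release_experiment,
)
from gelrelease.solver import FieldState, layer_masses, total_mass

HOUR = 3600.0


class TestGeometry:
    def test_twelve_well_layer_thicknesses(self):
        geom = build_geometry(1.5e-6, 1.5e-6, 3.8e-4)
        assert geom.gel_thickness_m == pytest.approx(3.947e-3, rel=1e-3)
        assert geom.media_thickness_m == geom.gel_thickness_m

    def test_equal_volumes_give_equal_thicknesses(self):
        geom = build_geometry(2.2e-6, 2.2e-6, 5e-4)
        assert geom.gel_thickness_m == geom.media_thickness_m

    @pytest.mark.parametrize("args", [(0, 1e-6, 1e-4), (1e-6, 1e-6, 0.0),
                                      (1e-6, -1e-6, 1e-4)])
    def test_degenerate_geometry_rejected(self, args):
        with pytest.raises(ValueError):
            build_geometry(*args)


class TestAdvance:
    def test_homogeneous_uniform_field_is_stationary(self, reference):
        params = TransportParams(bound_fraction=0.0, porosity=1.0)
        config = SolverConfig(n_cells_gel=10, n_cells_media=10, dt_s=600.0)
        grid = build_grid(params, reference.geometry, config)
        state = FieldState(0.0, np.full(grid.n_cells, 3e7))
        out = advance(state, grid, config, 12 * HOUR)
        np.testing.assert_allclose(out.concentration_ng_m3, 3e7, rtol=1e-12)

    def test_partitioned_equilibrium_is_stationary(self, reference):
        # uniform free aqueous concentration across both layers = equilibrium
        config = SolverConfig(n_cells_gel=10, n_cells_media=10, dt_s=600.0)
        grid = build_grid(reference.params, reference.geometry, config)
        state = FieldState(0.0, grid.capacity * 2e5)
        out = advance(state, grid, config, 12 * HOUR)
        np.testing.assert_allclose(
            out.concentration_ng_m3, state.concentration_ng_m3, rtol=1e-10
        )

    def test_mass_conserved_under_sealed_boundaries(self, reference, coarse_config):
        grid = build_grid(reference.params, reference.geometry, coarse_config)
        state = initial_state(reference.params, grid)
        m0 = total_mass(state, grid)
        out = advance(state, grid, coarse_config, 24 * HOUR)
        assert abs(total_mass(out, grid) - m0) / m0 < 1e-8

    def test_crank_nicolson_agrees_with_implicit(self, reference):
        results = []
        for scheme in ("implicit", "crank-nicolson"):
            config = SolverConfig(
                n_cells_gel=30, n_cells_media=30, dt_s=300.0, scheme=scheme
            )
            grid = build_grid(reference.params, reference.geometry, config)
            out = advance(
                initial_state(reference.params, grid), grid, config, 24 * HOUR
            )
            results.append(layer_masses(out, grid)[1])
        assert results[0] == pytest.approx(results[1], rel=5e-3)

    def test_invalid_duration_rejected(self, reference, coarse_config):
        grid = build_grid(reference.params, reference.geometry, coarse_config)
        state = initial_state(reference.params, grid)
        with pytest.raises(ValueError):
            advance(state, grid, coarse_config, 0.0)


class TestAnalyticOracle:
    def test_limits(self):
        assert analytic_slab_release(1e-10, 1e-3, 0.0) == 0.0
        assert analytic_slab_release(1e-10, 1e-3, 1e12) == pytest.approx(1.0)

    def test_early_time_square_root_law(self):
        # tau = D t / L^2 = 0.0318 -> released ~ 2 sqrt(tau / pi)
        L, D = 1e-3, 1e-10
        tau = 0.0318
        released = analytic_slab_release(D, L, tau * L**2 / D)
        assert released == pytest.approx(2 * np.sqrt(tau / np.pi), rel=0.01)

    def test_monotone_in_time(self):
        t = np.linspace(0, 1e6, 50)
        rel = analytic_slab_release(1e-11, 2e-3, t)
        assert np.all(np.diff(rel) >= -1e-15)

    def test_solver_matches_slab_series_under_perfect_sink(self, reference):
        """No binding, unit porosity, interface clamped to zero: the numeric
        release curve must track the classical slab series within 1%."""
        params = TransportParams(bound_fraction=0.0, porosity=1.0)
        config = SolverConfig(
            n_cells_gel=160, n_cells_media=8, dt_s=120.0, perfect_sink=True
        )
        grid = build_grid(params, reference.geometry, config)
        state = initial_state(params, grid)
        m0 = state.concentration_ng_m3[grid.is_gel].sum()
        D = params.diffusion_coefficients().d_water
        L = reference.geometry.gel_thickness_m
        t = 0.0
        for step_h in (6.0, 18.0, 48.0):
            state = advance(state, grid, config, step_h * HOUR)
            t += step_h * HOUR
            numeric = 1 - state.concentration_ng_m3[grid.is_gel].sum() / m0
            analytic = analytic_slab_release(D, L, t)
            assert numeric == pytest.approx(analytic, rel=0.01)


class TestConvergenceAndMonotonicity:
    def test_grid_convergence_of_retention(self, reference):
        """Doubling both cell counts and halving the step moves the 72 h
        retention by less than 0.1 percentage points."""
        base = reference.solver
        fine = replace(
            base,
            n_cells_gel=2 * base.n_cells_gel,
            n_cells_media=2 * base.n_cells_media,
            dt_s=base.dt_s / 2,
        )
        vals = [
            run_release_experiment(
                reference.params, reference.geometry, reference.protocol, cfg,
                output_dt_s=None,
            ).retained_percent[-1]
            for cfg in (base, fine)
        ]
        assert abs(vals[0] - vals[1]) < 0.1

    def test_retention_monotone_in_binding_thickness_and_diffusivity(
        self, reference, coarse_config
    ):
        def retention(params=None, geometry=None):
            curve = run_release_experiment(
                params or reference.params,
                geometry or reference.geometry,
                reference.protocol,
                coarse_config,
                output_dt_s=None,
            )
            return curve.retained_percent[-1]

        by_binding = [
            retention(params=reference.params.with_bound_fraction(f))
            for f in (0.9, 0.99, 0.999)
        ]
        assert by_binding == sorted(by_binding)

        by_thickness = [
            retention(geometry=build_geometry(v, 1.5e-6, 3.8e-4))
            for v in (0.75e-6, 1.5e-6, 3.0e-6)
        ]
        assert by_thickness == sorted(by_thickness)

        # higher viscosity -> lower free diffusivity -> higher retention
        by_viscosity = [
            retention(params=replace_viscosity(reference.params, mu))
            for mu in (3.5e-4, 6.913e-4, 1.4e-3)
        ]
        assert by_viscosity == sorted(by_viscosity)

    def test_release_monotone_in_time(self, reference, coarse_config):
        curve = run_release_experiment(
            reference.params, reference.geometry, reference.protocol,
            coarse_config, output_dt_s=3600.0,
        )
        assert np.all(np.diff(curve.cumulative_released_percent) >= -1e-12)
        # retained may only decrease between exchanges and is unchanged by them
        assert np.all(np.diff(curve.retained_percent) <= 1e-9)


def replace_viscosity(params, mu):
    from dataclasses import replace as _r

    return _r(params, viscosity_Pa_s=mu)


class TestSolverConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_cells_gel": 2},
            {"dt_s": 0.0},
            {"scheme": "explicit"},
            {"media_mode": "magic"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
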