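"""Shear rate, wall shear stress, Poiseuille references, summaries."""

import numpy as np
import pytest

import dopplerwss as dw
from dopplerwss.velocity_decode import PixelMask, VelocityField
from dopplerwss.wss_core import ShearRates


def _column_field(speeds_top_down, d=0.05):
    """One-column field: wall, len(speeds) flow pixels, wall."""
    n = len(speeds_top_down)
    v = np.zeros((n + 2, 1))
    valid = np.zeros((n + 2, 1), dtype=bool)
    v[1 : n + 1, 0] = speeds_top_down
    valid[1 : n + 1, 0] = True
    field = VelocityField(v, valid, spacing_axial=d, spacing_lateral=d)
    boundary = dw.WallBoundary(
        columns=[0], upper_row=[0], lower_row=[n + 1], d=d
    )
    return field, boundary


class TestNearWallGradient:
    def test_uniform_layer_gives_zero(self):
        field, boundary = _column_field([2.0, 2.0, 2.0, 2.0])
        rates = dw.near_wall_gradient(field, boundary)
        assert rates.gamma_upper[0] == 0.0
        assert rates.gamma_lower[0] == 0.0

    def test_direct_two_layer_evaluation(self):
        # V_slow = 0.5 cm/s at the wall-adjacent pixel, V_fast = 2.0 one layer
        # in, d = 0.05 cm: gamma = (2.0 - 0.5)/0.05 = 30 1/s
        field, boundary = _column_field([0.5, 2.0, 3.0, 2.0, 0.5], d=0.05)
        rates = dw.near_wall_gradient(field, boundary)
        assert rates.gamma_upper[0] == pytest.approx(30.0)
        assert rates.gamma_lower[0] == pytest.approx(30.0)

    def test_speeds_enter_as_magnitudes_with_direction_flag(self):
        field, boundary = _column_field([-0.5, -2.0, -3.0, -2.0, -0.5], d=0.05)
        rates = dw.near_wall_gradient(field, boundary)
        assert rates.gamma_upper[0] == pytest.approx(30.0)
        assert rates.flow_direction[0] == -1

    def test_boundary_zero_variant(self):
        field, boundary = _column_field([0.5, 2.0, 3.0, 2.0, 0.5], d=0.05)
        rates = dw.near_wall_gradient(field, boundary, use_boundary_zero=True)
        assert rates.gamma_upper[0] == pytest.approx(0.5 / 0.05)

    def test_poiseuille_wall_gradient_within_five_percent(self, decoded_phantom):
        spec, _, truth, mask, field, _ = decoded_phantom
        boundary = dw.detect_wall_boundary(mask, field)
        rates = dw.near_wall_gradient(field, boundary)
        gamma_true = 2 * spec.u_M / spec.R  # 133.33 1/s
        assert np.mean(rates.gamma_upper) == pytest.approx(gamma_true, rel=0.05)
        assert np.mean(rates.gamma_lower) == pytest.approx(gamma_true, rel=0.05)

    def test_invalid_layer_drops_column(self):
        field, boundary = _column_field([0.5, 2.0, 3.0, 2.0, 0.5])
        field.valid[2, 0] = False  # V_fast layer of the upper wall
        rates = dw.near_wall_gradient(field, boundary)
        assert rates.columns.size == 0


class TestWallShearStress:
    def test_tau_is_mu_times_gamma(self):
        rates = ShearRates(
            columns=[0], gamma_upper=[30.0], gamma_lower=[10.0],
            flow_direction=[1], d=0.05,
        )
        # 3 cP blood: tau = 0.03 * 30 = 0.9 dyne/cm2
        wmap = dw.wall_shear_stress(rates, dw.FluidParams(mu=0.03))
        assert wmap.tau_upper[0] == pytest.approx(0.9)
        assert wmap.tau_lower[0] == pytest.approx(0.3)

    def test_zero_gamma_zero_tau(self):
        rates = ShearRates([0], [0.0], [0.0], [0], 0.05)
        wmap = dw.wall_shear_stress(rates, dw.FluidParams(mu=0.03))
        assert wmap.tau_upper[0] == 0.0

    def test_linearity_in_mu_and_velocity(self, decoded_phantom):
        _, _, _, mask, field, _ = decoded_phantom
        boundary = dw.detect_wall_boundary(mask, field)
        rates = dw.near_wall_gradient(field, boundary)
        tau1 = dw.wall_shear_stress(rates, dw.FluidParams(mu=0.03)).tau_upper
        tau2 = dw.wall_shear_stress(rates, dw.FluidParams(mu=0.06)).tau_upper
        np.testing.assert_array_equal(tau2, 2.0 * tau1)
        scaled = VelocityField(
            3.0 * field.v, field.valid, field.spacing_axial, field.spacing_lateral
        )
        rates3 = dw.near_wall_gradient(scaled, boundary)
        tau3 = dw.wall_shear_stress(rates3, dw.FluidParams(mu=0.03)).tau_upper
        np.testing.assert_allclose(tau3, 3.0 * tau1, rtol=1e-12)


class TestPoiseuilleReferences:
    def test_flowrate_form_direct_value(self):
        geom = dw.VesselGeometry(R=0.2, Q=1.0)
        tau = dw.poiseuille_wss_flowrate(geom, dw.FluidParams(mu=0.03))
        assert tau == pytest.approx(4 * 0.03 * 1.0 / (np.pi * 0.2**3))
        assert tau == pytest.approx(4.7746, abs=1e-4)

    def test_maxvel_form_direct_value(self):
        geom = dw.VesselGeometry(R=0.3, u_M=20.0)
        assert dw.poiseuille_wss_maxvel(geom, dw.FluidParams(mu=0.03)) == pytest.approx(4.0)

    def test_zero_flow_zero_stress(self):
        assert dw.poiseuille_wss_flowrate(
            dw.VesselGeometry(R=0.2, Q=0.0), dw.FluidParams(mu=0.03)
        ) == 0.0
        assert dw.poiseuille_wss_maxvel(
            dw.VesselGeometry(R=0.2, u_M=0.0), dw.FluidParams(mu=0.03)
        ) == 0.0

    def test_cubic_radius_law(self):
        fl = dw.FluidParams(mu=0.03)
        t1 = dw.poiseuille_wss_flowrate(dw.VesselGeometry(R=0.1, Q=1.0), fl)
        t2 = dw.poiseuille_wss_flowrate(dw.VesselGeometry(R=0.2, Q=1.0), fl)
        assert t1 == pytest.approx(8.0 * t2)

    def test_forms_agree_under_parabolic_flow_rate(self):
        # Q = pi R^2 u_M / 2 makes both forms identical
        rng = np.random.default_rng(2)
        fl = dw.FluidParams(mu=0.03)
        for _ in range(20):
            R = rng.uniform(0.05, 0.5)
            u_M = rng.uniform(1.0, 80.0)
            Q = np.pi * R**2 * u_M / 2
            t_q = dw.poiseuille_wss_flowrate(dw.VesselGeometry(R=R, Q=Q), fl)
            t_u = dw.poiseuille_wss_maxvel(dw.VesselGeometry(R=R, u_M=u_M), fl)
            assert t_q == pytest.approx(t_u, rel=1e-14)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            dw.poiseuille_wss_flowrate(dw.VesselGeometry(R=0.0, Q=1.0), dw.FluidParams())


class TestSummaryAndSurface:
    def _map(self, tau_upper, tau_lower, columns=None):
        tau_upper = np.asarray(tau_upper, dtype=float)
        columns = np.arange(tau_upper.size) if columns is None else columns
        return dw.WSSMap(
            columns=columns,
            gamma_upper=tau_upper / 0.03,
            gamma_lower=np.asarray(tau_lower) / 0.03,
            tau_upper=tau_upper,
            tau_lower=tau_lower,
            mu=0.03,
        )

    def test_single_column_mean_and_max(self):
        s = dw.wss_summary(self._map([1.0], [3.0]))
        assert s.mean_tau == pytest.approx(2.0)
        assert s.max_tau == pytest.approx(3.0)
        assert s.n_columns == 1

    def test_uniform_phantom_mean_close_to_max(self, decoded_phantom):
        spec, _, _, mask, field, _ = decoded_phantom
        boundary = dw.detect_wall_boundary(mask, field)
        rates = dw.near_wall_gradient(field, boundary)
        s = dw.wss_summary(dw.wall_shear_stress(rates, dw.FluidParams(mu=0.03)))
        assert s.mean_tau == pytest.approx(s.max_tau, rel=0.05)

    def test_two_frames_time_average(self):
        m1 = self._map([1.0, 1.0], [1.0, 1.0])
        m2 = self._map([2.0, 2.0], [2.0, 2.0])
        s = dw.wss_summary(m1, [m1, m2])
        assert s.mean_tau == pytest.approx(1.5)
        assert s.per_frame_mean == (1.0, 2.0)

    def test_surface_grid_matches_and_max_consistent(self, tmp_path):
        m = self._map([1.0, 2.0, 3.0], [0.5, 2.5, 1.0])
        grid = dw.wss_surface_export(m, path=tmp_path / "surface.csv")
        assert grid.shape == (3, 1)
        np.testing.assert_allclose(grid["frame_0"], [1.0, 2.5, 3.0])
        s = dw.wss_summary(m)
        assert grid.to_numpy().max() == pytest.approx(s.max_tau)
        assert (tmp_path / "surface.csv").exists()

    def test_missing_columns_are_nan_gaps(self):
        m1 = self._map([1.0, 2.0], [1.0, 2.0], columns=np.array([0, 1]))
        m2 = self._map([3.0], [3.0], columns=np.array([1]))
        grid = dw.wss_surface_export([m1, m2])
        assert np.isnan(grid.loc[0, "frame_1"])
        assert grid.loc[1, "frame_1"] == 3.0

    def test_convergence_and_accuracy_over_spacings(self, fine_cmap):
        # |mean_tau - 2 mu u_M / R| / truth decreases monotonically with
        # finer pixels and is <= 5% at R/100
        errs = []
        for div in (10, 25, 50, 100):
            spec = dw.PhantomSpec(spacing=0.3 / div, n_columns=24)
            frame, truth = dw.generate_poiseuille_frame(spec, fine_cmap)
            res = dw.WallShearStress(frame, colormap=fine_cmap, mu=0.03).fit(angle=0.0)
            tau_true = truth.analytic_tau(0.03)
            errs.append(abs(res.mean_tau - tau_true) / tau_true)
        assert all(e1 > e2 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] <= 0.05

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            dw.wss_summary(self._map(np.array([]), np.array([])))
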