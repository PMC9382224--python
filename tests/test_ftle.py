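"""FTLE engine: seeding, advection, differentiation, series, extraction."""

import numpy as np
import pytest

from ftleforage.flowfield import interp_velocity
from ftleforage.ftle import (
    FTLEField,
    FTLESeries,
    compute_ftle_field,
    compute_ftle_series,
    extract_ftle_at,
    integrate_flow_map,
    load_ftle_series,
    save_ftle_series,
    seed_tracers,
)
from ftleforage.synthetic import FlowSpec, degrade_field, gen_analytic_field


class TestSeeding:
    def test_refinement_10_gives_600m_from_6km(self):
        spec = FlowSpec(kind="uniform", domain=(0, 60, 0, 30), grid_spacing_km=6,
                        duration_hours=2)
        f = gen_analytic_field(spec)
        tr = seed_tracers(f, 10)
        assert np.diff(tr.x)[0] == pytest.approx(0.6)
        assert np.diff(tr.y)[0] == pytest.approx(0.6)

    def test_refinement_1_reproduces_parent_nodes(self):
        f = gen_analytic_field(FlowSpec(kind="uniform", duration_hours=2))
        tr = seed_tracers(f, 1)
        np.testing.assert_allclose(tr.x, f.x)
        np.testing.assert_allclose(tr.y, f.y)

    def test_fencepost_count(self):
        # 10 x 10 cells (11 nodes), refinement 2 -> 21 x 21 seeds
        spec = FlowSpec(kind="uniform", domain=(0, 100, 0, 100),
                        grid_spacing_km=10, duration_hours=2)
        f = gen_analytic_field(spec)
        tr = seed_tracers(f, 2)
        assert tr.shape == (21, 21)

    def test_refinement_below_one_rejected(self):
        f = gen_analytic_field(FlowSpec(kind="uniform", duration_hours=2))
        with pytest.raises(ValueError, match="refinement"):
            seed_tracers(f, 0)


class TestIntegration:
    def test_uniform_backward_displacement(self, uniform_field):
        # u0 = 0.1 m/s over -48 h -> 17.28 km opposite the flow
        _, f = uniform_field
        tr = seed_tracers(f, 2)
        t0 = f.times[0] + np.timedelta64(50, "h")
        fm = integrate_flow_map(f, tr, t0, -48, rel_tol=1e-6)
        X = np.meshgrid(tr.x, tr.y)[0]
        disp = (fm.final_x - X)[~fm.exited]
        np.testing.assert_allclose(disp, -17.28, rtol=1e-9)

    def test_saddle_closed_form_trajectory(self, saddle_field):
        # x(t) = xc + (x0 - xc) e^{a t}: backward 48 h at a = 0.5/day -> e^-1
        _, f = saddle_field
        tr = seed_tracers(f, 2)
        t0 = f.times[0] + np.timedelta64(50, "h")
        fm = integrate_flow_map(f, tr, t0, -48, rel_tol=1e-8)
        X, Y = np.meshgrid(tr.x, tr.y)
        keep = ~fm.exited
        np.testing.assert_allclose(
            fm.final_x[keep] - 100.0, (X[keep] - 100.0) * np.exp(-1.0), rtol=1e-6)
        np.testing.assert_allclose(
            fm.final_y[keep] - 50.0, (Y[keep] - 50.0) * np.exp(1.0), rtol=1e-6)

    def test_adaptive_matches_fixed_step_rk4_oracle(self, double_gyre_spec):
        # brute-force fixed-step RK4 through the same gridded interpolant
        f = gen_analytic_field(double_gyre_spec)
        xs = np.linspace(40, 160, 4)
        ys = np.linspace(20, 80, 3)
        X, Y = np.meshgrid(xs, ys)
        horizon_h = -12.0
        t0 = f.times[0] + np.timedelta64(50, "h")
        tr = _grid_tracers(xs, ys)
        fm = integrate_flow_map(f, tr, t0, horizon_h, rel_tol=1e-7, atol_m=0.01)
        px, py = X.ravel().copy(), Y.ravel().copy()
        t_sec = f.seconds_of(t0)
        dt = -2.0
        for _ in range(int(abs(horizon_h) * 3600 / abs(dt))):
            px, py = _rk4_step(f, px, py, t_sec, dt)
            t_sec += dt
        err_m = np.hypot(fm.final_x.ravel() - px,
                         fm.final_y.ravel() - py) * 1000
        assert err_m.max() < 10.0

    def test_insufficient_coverage_rejected(self, uniform_field):
        _, f = uniform_field
        tr = seed_tracers(f, 1)
        with pytest.raises(ValueError, match="before field start"):
            integrate_flow_map(f, tr, f.times[0] + np.timedelta64(10, "h"), -48)


def _grid_tracers(xs, ys):
    """A small explicit TracerGrid for trajectory tests."""
    from ftleforage.ftle import TracerGrid

    return TracerGrid(x=np.asarray(xs, dtype=float), y=np.asarray(ys, dtype=float),
                      valid=np.ones((len(ys), len(xs)), dtype=bool), refinement=1)


def _rk4_step(f, px, py, t_sec, dt):
    """One fixed RK4 step through the same gridded interpolant (km units)."""
    def rates(x, y, t):
        u, v, _ = interp_velocity(f, x, y, t)
        return u / 1000.0, v / 1000.0

    k1x, k1y = rates(px, py, t_sec)
    k2x, k2y = rates(px + 0.5 * dt * k1x, py + 0.5 * dt * k1y, t_sec + 0.5 * dt)
    k3x, k3y = rates(px + 0.5 * dt * k2x, py + 0.5 * dt * k2y, t_sec + 0.5 * dt)
    k4x, k4y = rates(px + dt * k3x, py + dt * k3y, t_sec + dt)
    return (px + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x),
            py + dt / 6 * (k1y + 2 * k2y + 2 * k3y + k4y))


class TestFTLEValues:
    def test_uniform_flow_ftle_zero(self, uniform_field):
        _, f = uniform_field
        tr = seed_tracers(f, 2)
        t0 = f.times[0] + np.timedelta64(50, "h")
        ff = compute_ftle_field(integrate_flow_map(f, tr, t0, -48, rel_tol=1e-6))
        assert np.nanmax(np.abs(ff.values[ff.valid])) < 1e-6

    def test_saddle_ftle_equals_strain_rate(self, saddle_field):
        _, f = saddle_field
        tr = seed_tracers(f, 2)
        t0 = f.times[0] + np.timedelta64(50, "h")
        ff = compute_ftle_field(integrate_flow_map(f, tr, t0, -48, rel_tol=1e-6))
        v = ff.values[ff.valid]
        assert v.size > 50
        np.testing.assert_allclose(v, 0.5, rtol=0.02)

    def test_translation_invariance_on_linear_flows(self, saddle_field):
        _, f = saddle_field
        tr = seed_tracers(f, 2)
        t0 = f.times[0] + np.timedelta64(50, "h")
        ff1 = compute_ftle_field(integrate_flow_map(f, tr, t0, -48, rel_tol=1e-6))
        f2 = f.replace(u=f.u + 0.05, v=f.v + 0.03)
        ff2 = compute_ftle_field(integrate_flow_map(f2, tr, t0, -48, rel_tol=1e-6))
        both = ff1.valid & ff2.valid
        assert both.sum() > 50
        assert np.nanmax(np.abs(ff1.values[both] - ff2.values[both])) < 1e-8

    def test_lambda_max_closed_form_vs_eigensolver(self, double_gyre_spec):
        f = gen_analytic_field(double_gyre_spec)
        tr = seed_tracers(f, 2)
        t0 = f.times[0] + np.timedelta64(50, "h")
        fm = integrate_flow_map(f, tr, t0, -48, rel_tol=1e-5)
        ff = compute_ftle_field(fm)
        # recompute via explicit eigendecomposition of C at interior seeds
        m_lon = m_lat = 1000.0
        fx, fy = fm.final_x * m_lon, fm.final_y * m_lat
        x0, y0 = tr.x * m_lon, tr.y * m_lat
        f11 = np.gradient(fx, x0, axis=1)
        f12 = np.gradient(fx, y0, axis=0)
        f21 = np.gradient(fy, x0, axis=1)
        f22 = np.gradient(fy, y0, axis=0)
        F = np.stack([np.stack([f11, f12], -1), np.stack([f21, f22], -1)], -2)
        C = np.einsum("...ki,...kj->...ij", F, F)
        lam = np.linalg.eigvalsh(C)[..., -1]
        ftle_eig = np.log(lam) / (2 * 2.0)
        sel = ff.valid
        np.testing.assert_allclose(ff.values[sel], ftle_eig[sel], rtol=1e-12)

    def test_stepper_convergence_under_tolerance_halving(self, double_gyre_spec):
        f = gen_analytic_field(double_gyre_spec)
        tr = seed_tracers(f, 1)
        t0 = f.times[0] + np.timedelta64(50, "h")
        fields = [
            compute_ftle_field(integrate_flow_map(f, tr, t0, -48, rel_tol=rt))
            for rt in (1e-3, 5e-4, 2.5e-4)
        ]
        m = fields[0].valid & fields[1].valid & fields[2].valid
        d1 = np.nanmax(np.abs(fields[0].values[m] - fields[1].values[m]))
        d2 = np.nanmax(np.abs(fields[1].values[m] - fields[2].values[m]))
        assert d2 <= d1 + 1e-12

    def test_gap_mask_monotonicity(self, double_gyre_spec):
        f = gen_analytic_field(double_gyre_spec)
        tr = seed_tracers(f, 1)
        t0 = f.times[0] + np.timedelta64(50, "h")
        valid_prev = None
        for frac in (0.0, 0.15, 0.4):
            g = degrade_field(f, frac, 0.0, seed=9) if frac else f
            ff = compute_ftle_field(integrate_flow_map(g, tr, t0, -48, rel_tol=1e-3))
            if valid_prev is not None:
                # increasing gaps never turn an invalid cell valid
                assert not (ff.valid & ~valid_prev).any()
            valid_prev = ff.valid


class TestSeries:
    def test_coverage_rule_skips_early_hours(self):
        spec = FlowSpec(kind="saddle", params={"a": 0.3}, domain=(0, 100, 0, 100),
                        grid_spacing_km=20, duration_hours=72)
        f = gen_analytic_field(spec)
        hours = f.times[::12]
        with pytest.warns(UserWarning, match="insufficient"):
            series = compute_ftle_series(f, hours, refinement=1)
        got = set(series.times.astype("datetime64[h]").astype(str))
        skipped = set(np.array(series.skipped).astype("datetime64[h]").astype(str))
        for h in hours:
            t_h = (h - f.times[0]) / np.timedelta64(1, "h")
            if t_h >= 48:
                assert str(h.astype("datetime64[h]")) in got
            else:
                assert str(h.astype("datetime64[h]")) in skipped

    def test_stationary_flow_gives_identical_hourly_fields(self):
        spec = FlowSpec(kind="saddle", params={"a": 0.3}, domain=(0, 100, 0, 100),
                        grid_spacing_km=10, duration_hours=53)
        f = gen_analytic_field(spec)
        series = compute_ftle_series(f, f.times[48:52], refinement=1, rel_tol=1e-6)
        ref = series.fields[0].values
        for fld in series.fields[1:]:
            m = series.fields[0].valid & fld.valid
            assert m.sum() > 10
            assert np.nanmax(np.abs(fld.values[m] - ref[m])) < 1e-9

    def test_periodic_flow_gives_periodic_fields(self):
        # double gyre with 6 h period: FTLE(t) == FTLE(t + 6 h)
        spec = FlowSpec(kind="double_gyre",
                        params={"A": 0.1, "eps": 0.25, "omega": 2 * np.pi / 6},
                        domain=(0, 200, 0, 100), grid_spacing_km=10,
                        duration_hours=60, step_hours=1.0)
        f = gen_analytic_field(spec)
        hours = [f.times[48], f.times[54]]
        series = compute_ftle_series(f, hours, refinement=1, rel_tol=1e-6)
        a, b = series.fields
        m = a.valid & b.valid
        rms = np.sqrt(np.nanmean((a.values[m] - b.values[m]) ** 2))
        assert rms < 1e-6

    def test_netcdf_round_trip(self, tmp_path, saddle_field):
        _, f = saddle_field
        series = compute_ftle_series(f, [f.times[50]], refinement=1, rel_tol=1e-4)
        p = tmp_path / "ftle.nc"
        save_ftle_series(series, p)
        loaded = load_ftle_series(p)
        np.testing.assert_allclose(
            series.fields[0].values[series.fields[0].valid],
            loaded.fields[0].values[loaded.fields[0].valid])


class TestExtraction:
    def _series(self):
        x = np.arange(0.0, 10.0)
        y = np.arange(0.0, 8.0)
        fields = []
        for k in range(3):
            t = np.datetime64("2020-01-01T00") + np.timedelta64(k, "h")
            vals = np.full((8, 10), float(k))
            fields.append(FTLEField(time=t, x=x, y=y, values=vals,
                                    valid=np.ones((8, 10), bool),
                                    horizon_hours=-48, geographic=False))
        return FTLESeries(fields=fields, skipped=[])

    def test_exact_cell_and_hour(self):
        s = self._series()
        assert extract_ftle_at(s, 3.0, 2.0, np.datetime64("2020-01-01T01")) == 1.0

    def test_29_minutes_uses_nearest_hour(self):
        s = self._series()
        t = np.datetime64("2020-01-01T02:00") + np.timedelta64(29, "m")
        assert extract_ftle_at(s, 3.0, 2.0, t) == 2.0

    def test_31_minutes_is_missing(self):
        s = self._series()
        t = np.datetime64("2020-01-01T02:31")
        assert np.isnan(extract_ftle_at(s, 3.0, 2.0, t))

    def test_invalid_cell_falls_back_to_neighbour(self):
        s = self._series()
        s.fields[0].values[2, 3] = np.nan
        v = extract_ftle_at(s, 3.0, 2.0, np.datetime64("2020-01-01T00"))
        assert v == 0.0  # neighbour in the same field
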