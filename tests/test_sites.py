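"""Feeding-probability model, CRW parameterisation and null models."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint, Point, box

from ftleforage.biologging import Deployment
from ftleforage.ftle import FTLEField, FTLESeries
from ftleforage.sites import (
    CRWParams,
    SeparationError,
    _wrapped_cauchy_sample,
    estimate_crw_params,
    fit_feeding_model,
    simulate_crw_tracks,
    time_shift_extract,
)
from ftleforage.synthetic import simulate_feeding_series


class TestFeedingModel:
    def test_single_individual_independence_matches_glm(self):
        import statsmodels.api as sm

        df = simulate_feeding_series(n_individuals=1, n_dives=800, slope=0.6,
                                     noise_sd=0.0, noise_ar=0.0,
                                     random_intercept_sd=0.0, seed=3)
        fit = fit_feeding_model(df, correlation="independence")
        glm = sm.GLM(df["feeding"].astype(int),
                     sm.add_constant(df["ftle"].to_numpy()),
                     family=sm.families.Binomial()).fit()
        assert fit.slope == pytest.approx(glm.params.iloc[1], abs=1e-6)
        assert fit.intercept == pytest.approx(glm.params.iloc[0], abs=1e-6)

    def test_ar1_fit_recovers_positive_slope(self):
        df = simulate_feeding_series(n_individuals=5, n_dives=400, slope=0.45,
                                     seed=4)
        fit = fit_feeding_model(df, correlation="ar1")
        assert fit.slope > 0.2
        assert fit.p_value < 0.01
        assert fit.n_individuals == 5

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({
            "individual_id": "w", "t_hours": np.arange(40) * 0.25,
            "ftle": np.r_[np.zeros(20), np.ones(20)],
            "feeding": np.r_[np.zeros(20), np.ones(20)].astype(bool),
        })
        with pytest.raises(SeparationError):
            fit_feeding_model(df, correlation="independence")


class TestCRWParams:
    def test_straight_track_r_is_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = estimate_crw_params(np.linspace(0, 1, 50), np.zeros(50))
        assert p.r == 1.0

    def test_uniform_turns_r_near_zero(self):
        rng = np.random.default_rng(1)
        ang = np.cumsum(rng.uniform(-np.pi, np.pi, 10000))
        x = np.cumsum(np.cos(ang)) / 100
        y = np.cumsum(np.sin(ang)) / 100
        p = estimate_crw_params(x, y, geographic=False)
        assert p.r < 0.05

    def test_known_r_recovered(self):
        turns = _wrapped_cauchy_sample(np.random.default_rng(2), 0.7, 5000)
        head = np.cumsum(turns)
        x = np.cumsum(np.cos(head)) / 100
        y = np.cumsum(np.sin(head)) / 100
        p = estimate_crw_params(x, y, geographic=False)
        assert p.r == pytest.approx(0.7, abs=0.03)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CRWParams(h=-1, r=0.5)
        with pytest.raises(ValueError):
            CRWParams(h=1, r=1.5)


def _crw_deployment(n=2000, r=0.6, seed=5):
    """A deployment whose track is itself a known CRW (planar km in lon/lat slots)."""
    rng = np.random.default_rng(seed)
    turns = _wrapped_cauchy_sample(rng, r, n - 1)
    head = np.cumsum(np.r_[rng.uniform(-np.pi, np.pi), turns])
    steps = rng.lognormal(np.log(0.4), 0.3, n - 1)  # km
    x = np.r_[0, np.cumsum(steps * np.cos(head[1:]))]
    y = np.r_[0, np.cumsum(steps * np.sin(head[1:]))]
    dives = pd.DataFrame({
        "individual_id": "crw-src",
        "start": pd.date_range("2017-09-01", periods=n, freq="10min"),
        "lon": x, "lat": y,
        "feeding": rng.random(n) < 0.5,
        "ftle": rng.normal(0.3, 0.4, n),
    })
    dives["end"] = dives["start"] + pd.Timedelta(minutes=9)
    return Deployment(individual_id="crw-src", dives=dives)


class TestCRWTracks:
    def test_labels_timestamps_and_shape_preserved(self, simulated_deployments,
                                                   random_ftle_series):
        dep = simulated_deployments[0]
        tracks = simulate_crw_tracks(dep, n_tracks=10, seed=1,
                                     ftle_series=random_ftle_series)
        loc = dep.dives[dep.dives["lon"].notna()]
        assert len(tracks) == 10
        for t in tracks:
            assert len(t) == len(loc)
            np.testing.assert_array_equal(t["feeding"].to_numpy(),
                                          loc["feeding"].to_numpy())
            np.testing.assert_array_equal(t["start"].to_numpy(),
                                          loc["start"].to_numpy())

    def test_starts_inside_mcp(self, simulated_deployments):
        dep = simulated_deployments[1]
        loc = dep.dives[dep.dives["lon"].notna()]
        mcp = MultiPoint(list(zip(loc["lon"], loc["lat"]))).convex_hull
        tracks = simulate_crw_tracks(dep, n_tracks=10, seed=2)
        for t in tracks:
            assert mcp.buffer(1e-9).contains(Point(t["lon"].iloc[0], t["lat"].iloc[0]))

    def test_no_points_on_land(self, simulated_deployments):
        dep = simulated_deployments[2]
        loc = dep.dives[dep.dives["lon"].notna()]
        land = box(loc["lon"].mean(), loc["lat"].mean(),
                   loc["lon"].mean() + 0.5, loc["lat"].mean() + 0.5)
        tracks = simulate_crw_tracks(dep, n_tracks=3, seed=3, land_mask=land)
        for t in tracks:
            for lon, lat in zip(t["lon"], t["lat"]):
                assert not land.contains(Point(lon, lat))

    def test_step_and_turn_distributions_preserved(self):
        from scipy.stats import ks_2samp

        from ftleforage.sites import _track_steps

        dep = _crw_deployment()
        tracks = simulate_crw_tracks(dep, n_tracks=5, seed=4, geographic=False)
        obs_steps, obs_head = _track_steps(dep.dives["lon"], dep.dives["lat"],
                                           geographic=False)
        obs_turns = np.angle(np.exp(1j * np.diff(obs_head)))
        null_steps, null_turns = [], []
        for t in tracks:
            s, h = _track_steps(t["lon"], t["lat"], geographic=False)
            null_steps.append(s)
            null_turns.append(np.angle(np.exp(1j * np.diff(h))))
        assert ks_2samp(obs_steps, np.concatenate(null_steps)).pvalue > 0.01
        assert ks_2samp(obs_turns, np.concatenate(null_turns)).pvalue > 0.01

    def test_r_zero_gives_uniform_headings(self):
        from ftleforage.sites import _track_steps

        dep = _crw_deployment(n=1500)
        tracks = simulate_crw_tracks(dep, params=CRWParams(h=400.0, r=0.0),
                                     n_tracks=3, seed=6, geographic=False)
        heads = np.concatenate([
            _track_steps(t["lon"], t["lat"], geographic=False)[1] for t in tracks])
        # Rayleigh test: under uniformity z = n R^2, p ~ exp(-z)
        n = heads.size
        R = np.abs(np.mean(np.exp(1j * heads)))
        p = np.exp(-n * R ** 2)
        assert p > 0.01


def _constant_series(value=0.5, n_hours=400, period_hours=None, seed=0):
    """Synthetic FTLE series: constant, or repeating with a given period."""
    rng = np.random.default_rng(seed)
    x = np.linspace(-123.0, -122.0, 21)
    y = np.linspace(35.5, 36.5, 21)
    times = (np.datetime64("2017-09-01T00")
             + np.arange(n_hours).astype("timedelta64[h]"))
    if period_hours is None:
        frames = [np.full((21, 21), value)] * n_hours
    else:
        base = [rng.normal(0.3, 0.3, (21, 21)) for _ in range(period_hours)]
        frames = [base[k % period_hours] for k in range(n_hours)]
    fields = [
        FTLEField(time=t, x=x, y=y, values=frames[k],
                  valid=np.ones((21, 21), bool), horizon_hours=-48,
                  geographic=True)
        for k, t in enumerate(times)
    ]
    return FTLESeries(fields=fields, skipped=[])


class TestTimeShift:
    def _deployment(self, n=100):
        rng = np.random.default_rng(9)
        dives = pd.DataFrame({
            "individual_id": "w",
            "start": pd.date_range("2017-09-01", periods=n, freq="30min"),
            "lon": rng.uniform(-122.9, -122.1, n),
            "lat": rng.uniform(35.6, 36.4, n),
            "feeding": rng.random(n) < 0.5,
            "ftle": np.nan,
        })
        dives["end"] = dives["start"] + pd.Timedelta(minutes=10)
        return Deployment(individual_id="w", dives=dives)

    def test_zero_shift_is_identity(self):
        series = _constant_series(period_hours=48)
        dep = self._deployment()
        from ftleforage.ftle import extract_ftle_at

        base = extract_ftle_at(series, dep.dives["lon"].to_numpy(),
                               dep.dives["lat"].to_numpy(),
                               dep.dives["start"].to_numpy())
        shifted, miss = time_shift_extract(dep, 0, series)
        np.testing.assert_allclose(shifted["ftle"].to_numpy(), base)
        assert miss == 0

    def test_time_invariant_series_unchanged_by_shift(self):
        series = _constant_series(value=0.7)
        dep = self._deployment()
        a, _ = time_shift_extract(dep, 0, series)
        b, _ = time_shift_extract(dep, 24, series)
        np.testing.assert_allclose(a["ftle"], b["ftle"])

    def test_periodicity_determines_shift_sensitivity(self):
        dep = self._deployment()
        s24 = _constant_series(period_hours=24, seed=1)
        a, _ = time_shift_extract(dep, 0, s24)
        b, _ = time_shift_extract(dep, 24, s24)
        np.testing.assert_allclose(a["ftle"], b["ftle"])
        s48 = _constant_series(period_hours=48, seed=2)
        c, _ = time_shift_extract(dep, 0, s48)
        d, _ = time_shift_extract(dep, 24, s48)
        assert np.max(np.abs(c["ftle"].to_numpy() - d["ftle"].to_numpy())) > 0.01

    def test_coverage_shortfall_counted(self):
        series = _constant_series(value=0.7, n_hours=50)
        dep = self._deployment()
        shifted, miss = time_shift_extract(dep, 192, series)
        assert miss > 0
        assert shifted["ftle"].isna().sum() == miss


class TestNullComparison:
    def test_crw_null_slope_smaller_than_real(self, random_ftle_series):
        """Coupled simulation: real slope exceeds pooled CRW-null slope."""
        from ftleforage.synthetic import WhaleSimSpec, simulate_whale_deployments

        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            spec = WhaleSimSpec(n_individuals=2, duration_days=3.0,
                                seed=1000 + rep)
            deps = simulate_whale_deployments(spec, random_ftle_series)
            real = pd.concat([d.dives for d in deps], ignore_index=True)
            fit_real = fit_feeding_model(real, correlation="independence")
            tracks = []
            for k, dep in enumerate(deps):
                tracks += simulate_crw_tracks(dep, n_tracks=5, seed=rep * 10 + k,
                                              ftle_series=random_ftle_series)
            nulls = pd.concat(tracks, ignore_index=True)
            fit_null = fit_feeding_model(nulls, correlation="independence")
            wins += abs(fit_null.slope) < abs(fit_real.slope)
        assert wins >= int(0.9 * n_rep)

    def test_zero_coupling_simulation_slope_ci_covers_zero(self, random_ftle_series):
        """Full-simulation null calibration: decoupled feeding, CI covers 0."""
        from ftleforage.synthetic import (
            WhaleSimSpec,
            default_state_coefficients,
            simulate_whale_deployments,
        )

        beta0 = default_state_coefficients(0.0)
        cover = 0
        for rep in range(20):
            spec = WhaleSimSpec(n_individuals=3, duration_days=2.0,
                                state_coefficients=beta0, seed=4000 + rep)
            deps = simulate_whale_deployments(spec, random_ftle_series)
            dives = pd.concat([d.dives for d in deps], ignore_index=True)
            fit = fit_feeding_model(dives, correlation="independence")
            lo, hi = fit.slope_ci
            cover += lo <= 0.0 <= hi
        assert cover >= 18
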