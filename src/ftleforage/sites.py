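"""Fourth-order selection: the feeding-vs-FTLE model and its null models.

The probability that a dive is a feeding dive is modelled on the FTLE value
at the dive with a binomial (logit) marginal model fit by generalized
estimating equations: individuals are the correlation groups and the
working correlation decays exponentially with the time gap between dives
(the continuous-time first-order autocorrelation the tag data exhibit).

Two null-model families put the fitted slope in context.  Correlated-
random-walk (CRW) tracks — parameterised per individual by the step-length
scale h and the turning-angle concentration r, started uniformly inside
the deployment's minimum convex polygon, keeping the real timestamps and
feeding labels, and never on land — simulate non-selecting individuals.
Time-shifted tracks keep positions and labels but move all timestamps
forward by 24/48/96/192 h before re-extracting FTLE, probing how long the
selected features persist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from .biologging import Deployment
from .flowfield import EARTH_RADIUS_M
from .ftle import FTLESeries, extract_ftle_at

__all__ = [
    "FeedingModelFit",
    "CRWParams",
    "SeparationError",
    "fit_feeding_model",
    "estimate_crw_params",
    "simulate_crw_tracks",
    "time_shift_extract",
    "TIME_SHIFTS_HOURS",
]

M_PER_DEG_LAT = EARTH_RADIUS_M * np.pi / 180.0

#: forward time shifts probing feature persistence
TIME_SHIFTS_HOURS = (24, 48, 96, 192)


class SeparationError(RuntimeError):
    """Complete separation: the binomial fit is unbounded."""


@dataclass
class FeedingModelFit:
    """A fitted feeding-probability model (logit scale)."""

    slope: float
    slope_se: float
    p_value: float
    intercept: float
    intercept_se: float
    corr_param: float
    n_dives: int
    n_individuals: int
    correlation: str

    @property
    def slope_ci(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)


def fit_feeding_model(
    dives: pd.DataFrame,
    correlation: str = "ar1",
    feeding_col: str = "feeding",
    covariate_col: str = "ftle",
    group_col: str = "individual_id",
    time_col: str = "t_hours",
) -> FeedingModelFit:
    """GEE logit regression of feeding presence on FTLE.

    ``correlation`` is ``"ar1"`` (working correlation decaying with the
    within-individual time gap) or ``"independence"`` (then the point
    estimates equal plain logistic regression).  Rows with missing FTLE or
    feeding are dropped.  Complete separation raises
    :class:`SeparationError` with a diagnostic.
    """
    import statsmodels.api as sm
    from statsmodels.genmod.cov_struct import Autoregressive, Independence

    df = dives.dropna(subset=[covariate_col]).copy()
    df = df[np.isfinite(df[covariate_col])]
    y = df[feeding_col].astype(int).to_numpy()
    x = df[covariate_col].to_numpy(dtype=float)
    if df[group_col].nunique() < 1 or np.ptp(x) == 0:
        raise ValueError("need a non-degenerate FTLE covariate")
    if y.min() == y.max():
        raise SeparationError("response is constant: all dives share one label")

    exog = sm.add_constant(x)
    groups = df[group_col].to_numpy()
    if correlation == "ar1":
        cov = Autoregressive(grid=False)
        t = df[time_col].to_numpy(dtype=float)[:, None]
        model = sm.GEE(y, exog, groups=groups, time=t,
                       family=sm.families.Binomial(), cov_struct=cov)
    elif correlation == "independence":
        cov = Independence()
        model = sm.GEE(y, exog, groups=groups,
                       family=sm.families.Binomial(), cov_struct=cov)
    else:
        raise ValueError(f"unknown correlation {correlation!r}")

    # bias-reduced (Mancl-DeRouen) covariance: the plain sandwich is biased
    # low with few clusters (~10 individuals); with < 3 clusters no sandwich
    # estimator is meaningful, so use the model-based covariance there
    cov_type = "bias_reduced" if df[group_col].nunique() >= 3 else "naive"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, cov_type=cov_type)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        raise SeparationError(
            f"unbounded estimates {params}: likely complete separation of "
            "feeding on the covariate"
        )
    dep = getattr(res.cov_struct, "dep_params", np.nan)
    return FeedingModelFit(
        slope=float(params[1]),
        slope_se=float(bse[1]),
        p_value=float(res.pvalues[1]),
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        corr_param=float(np.atleast_1d(dep)[0]) if dep is not None else np.nan,
        n_dives=int(y.size),
        n_individuals=int(df[group_col].nunique()),
        correlation=correlation,
    )


# ---------------------------------------------------------------------------
# correlated random walks
# ---------------------------------------------------------------------------

@dataclass
class CRWParams:
    """Step-length scale h (metres) and turning-angle concentration r."""

    h: float
    r: float

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must be in [0, 1]")


def _track_steps(lon, lat, geographic=True):
    """Step lengths (m) and headings (rad) of an ordered track."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if geographic:
        m_lat = M_PER_DEG_LAT
        m_lon = m_lat * np.cos(np.deg2rad(0.5 * (lat[:-1] + lat[1:])))
    else:
        m_lon = m_lat = 1000.0
    dx = np.diff(lon) * m_lon
    dy = np.diff(lat) * m_lat
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def estimate_crw_params(lon, lat, geographic: bool = True) -> CRWParams:
    """(h, r) of a track: mean step length and mean resultant length.

    r is the mean resultant length of the observed turning angles (0 =
    uniform headings, 1 = straight line); h is the mean step length in
    metres.  A degenerate straight/collinear track returns r = 1 with a
    warning.
    """
    lon = np.asarray(lon, dtype=float)
    if lon.size < 3:
        raise ValueError("need >= 3 locations to estimate turning angles")
    steps, headings = _track_steps(lon, lat, geographic)
    moving = steps > 0
    turns = np.diff(headings[moving])
    if turns.size == 0 or np.allclose(turns, 0.0):
        warnings.warn("track is degenerate/collinear (no turning); returning r = 1")
        return CRWParams(h=float(max(steps.mean(), 1e-9)), r=1.0)
    r = float(np.abs(np.mean(np.exp(1j * turns))))
    return CRWParams(h=float(steps.mean()), r=min(r, 1.0))


def _wrapped_cauchy_sample(rng, r, size):
    if r <= 0:
        return rng.uniform(-np.pi, np.pi, size)
    if r >= 1:
        return np.zeros(size)
    u = rng.random(size)
    v = np.cos(2 * np.pi * u)
    c = 2 * r / (1 + r ** 2)
    ang = np.arccos(np.clip((v + c) / (1 + c * v), -1, 1))
    return np.where(rng.random(size) < 0.5, ang, -ang)


def _sample_in_polygon(rng, poly, cap=10000):
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(cap):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.contains(p) or poly.touches(p):
            return p.x, p.y
    raise RuntimeError("could not sample a start point inside the MCP")


def simulate_crw_tracks(
    deployment: Deployment,
    params: CRWParams | None = None,
    n_tracks: int = 10,
    land_mask=None,
    seed: int = 0,
    ftle_series: FTLESeries | None = None,
    geographic: bool = True,
    reject_cap: int = 100,
) -> list[pd.DataFrame]:
    """Null tracks for one deployment: CRW with the real times and labels.

    Each of the ``n_tracks`` tracks starts at a uniform point inside the
    minimum convex polygon (convex hull of the located dive positions),
    resamples the deployment's observed step lengths scaled to ``params.h``
    and draws turning angles from a wrapped Cauchy with concentration
    ``params.r``.  Steps landing on ``land_mask`` (a shapely geometry, may
    be None) are redrawn up to ``reject_cap`` times, after which the track
    restarts from a fresh MCP start (counted in the frame's attrs).  If an
    FTLE series is given, values are extracted under the standard 30-min
    nearest-cell rule.
    """
    d = deployment.dives
    loc = d[d["lon"].notna()].reset_index(drop=True)
    if len(loc) < 3:
        raise ValueError("deployment needs >= 3 located dives")
    if params is None:
        params = estimate_crw_params(loc["lon"], loc["lat"], geographic)
    obs_steps, _ = _track_steps(loc["lon"].to_numpy(), loc["lat"].to_numpy(), geographic)
    obs_steps = obs_steps[obs_steps > 0]
    if obs_steps.size == 0:
        raise ValueError("track has no nonzero steps")
    scale = params.h / obs_steps.mean()
    mcp = MultiPoint(list(zip(loc["lon"], loc["lat"]))).convex_hull
    n_steps = len(loc) - 1
    rng = np.random.default_rng(seed)

    tracks = []
    for k in range(n_tracks):
        restarts = 0
        while True:
            x = np.empty(len(loc))
            y = np.empty(len(loc))
            x[0], y[0] = _sample_in_polygon(rng, mcp)
            heading = rng.uniform(-np.pi, np.pi)
            failed = False
            for i in range(n_steps):
                for attempt in range(reject_cap):
                    turn = float(_wrapped_cauchy_sample(rng, params.r, 1)[0])
                    cand_heading = heading + turn
                    step_m = float(rng.choice(obs_steps)) * scale
                    if geographic:
                        m_lat = M_PER_DEG_LAT
                        m_lon = m_lat * np.cos(np.deg2rad(y[i]))
                    else:
                        m_lon = m_lat = 1000.0
                    cx = x[i] + step_m * np.cos(cand_heading) / m_lon
                    cy = y[i] + step_m * np.sin(cand_heading) / m_lat
                    if land_mask is None or not land_mask.contains(Point(cx, cy)):
                        x[i + 1], y[i + 1] = cx, cy
                        heading = cand_heading
                        break
                else:
                    failed = True
                    break
                continue
            if not failed:
                break
            restarts += 1
        null = loc.copy()
        null["lon"] = x
        null["lat"] = y
        null["individual_id"] = f"{deployment.individual_id}-crw{k:02d}"
        if ftle_series is not None:
            null["ftle"] = extract_ftle_at(
                ftle_series, x, y, pd.to_datetime(null["start"]).to_numpy()
            )
        null.attrs["restarts"] = restarts
        null.attrs["source_individual"] = deployment.individual_id
        tracks.append(null)
    return tracks


def time_shift_extract(
    deployment: Deployment,
    shift_hours: float,
    ftle_series: FTLESeries,
) -> tuple[pd.DataFrame, int]:
    """Re-extract FTLE with all timestamps shifted forward by ``shift_hours``.

    Positions and feeding labels are unchanged; returns the shifted dive
    table and the number of dives left without FTLE by the coverage
    shortfall.
    """
    d = deployment.dives.copy()
    shifted = pd.to_datetime(d["start"]) + pd.Timedelta(hours=float(shift_hours))
    has_loc = d["lon"].notna()
    vals = np.full(len(d), np.nan)
    vals[has_loc.to_numpy()] = extract_ftle_at(
        ftle_series,
        d.loc[has_loc, "lon"].to_numpy(),
        d.loc[has_loc, "lat"].to_numpy(),
        shifted[has_loc].to_numpy(),
    )
    d["ftle"] = vals
    d["shift_hours"] = float(shift_hours)
    n_missing = int((has_loc.to_numpy() & ~np.isfinite(vals)).sum())
    return d, n_missing
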