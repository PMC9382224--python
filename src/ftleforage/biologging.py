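"""From raw tag streams to located, FTLE-matched dive records.

The sampling unit of the whole analysis is the dive: an excursion below 10 m
in the 1 Hz depth trace.  Each dive carries its lunge count (lunges are
identified upstream in the tag's kinematic data and arrive as timestamps), a
GPS-interpolated start location when the surrounding fix gap is short enough,
the matched FTLE value, and a dive-cycle feeding rate

    feeding rate = n_lunges / (dive duration + post-dive surface duration)

in lunges per hour, which accounts for transit to the prey and the surface
recovery the dive requires.  Feeding rates are normalised per individual by
percentile rank (FR_pct) and cut at the 25th/75th percentiles into four
behavioural states: non-feeding, light, moderate and heavy feeding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "Deployment",
    "detect_dives",
    "count_lunges",
    "filter_gps_speed",
    "assign_dive_locations",
    "compute_feeding_rates",
    "normalize_and_label_states",
    "haversine_m",
    "STATES",
]

STATES = ("non-feeding", "light", "moderate", "heavy")

EARTH_RADIUS_M = 6371008.8

#: canonical dive-table columns
DIVE_COLUMNS = [
    "individual_id", "start", "end", "duration_s", "max_depth_m",
    "surface_duration_s", "lunges", "feeding", "lon", "lat", "ftle",
    "feeding_rate", "fr_pct", "state", "t_hours",
]


@dataclass
class Deployment:
    """One individual's ordered dives, GPS track and metadata."""

    individual_id: str
    dives: pd.DataFrame
    gps: pd.DataFrame = dc_field(default_factory=lambda: pd.DataFrame(
        columns=["timestamp", "lon", "lat"]))
    region: str = ""
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.dives
        if len(d) > 1:
            starts = pd.to_datetime(d["start"]).to_numpy()
            ends = pd.to_datetime(d["end"]).to_numpy()
            if not (np.diff(starts.astype("int64")) > 0).all():
                raise ValueError("dives must be time-ordered")
            if (ends[:-1] > starts[1:]).any():
                raise ValueError("dives must not overlap")

    @property
    def start_time(self):
        return pd.to_datetime(self.dives["start"]).iloc[0]

    @property
    def length_days(self) -> float:
        d = self.dives
        span = pd.to_datetime(d["end"]).iloc[-1] - pd.to_datetime(d["start"]).iloc[0]
        return span.total_seconds() / 86400.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# dive detection
# ---------------------------------------------------------------------------

def detect_dives(depth: pd.DataFrame, threshold_m: float = 10.0) -> pd.DataFrame:
    """Detect dives as excursions to depth greater than ``threshold_m``.

    ``depth`` has columns ``timestamp`` (strictly increasing, ~1 Hz) and
    ``depth_m``.  A dive runs from the first sample exceeding the threshold
    to the first subsequent sample back at or above it; an excursion still
    open at the end of the trace is incomplete and dropped.  The post-dive
    surface duration is the time from the dive's end to the next dive's
    start; the final dive's is missing.
    """
    t = pd.to_datetime(depth["timestamp"]).to_numpy()
    z = np.asarray(depth["depth_m"], dtype=float)
    if len(t) > 1 and not (np.diff(t.astype("int64")) > 0).all():
        i = int(np.argmax(np.diff(t.astype("int64")) <= 0))
        raise ValueError(f"depth timestamps not strictly increasing at {t[i + 1]}")
    deep = z > threshold_m
    edges = np.diff(deep.astype(np.int8))
    downs = np.flatnonzero(edges == 1) + 1   # first sample below threshold depth
    ups = np.flatnonzero(edges == -1) + 1    # first sample back above threshold
    if deep.size and deep[0]:
        downs = np.insert(downs, 0, 0)
    # pair each down-crossing with the next up-crossing; drop incomplete tail
    rows = []
    j = 0
    for i0 in downs:
        while j < ups.size and ups[j] <= i0:
            j += 1
        if j >= ups.size:
            break
        i1 = ups[j]
        rows.append(
            {
                "start": t[i0],
                "end": t[i1],
                "duration_s": (t[i1] - t[i0]) / np.timedelta64(1, "s"),
                "max_depth_m": float(z[i0:i1].max()),
            }
        )
    dives = pd.DataFrame(rows, columns=["start", "end", "duration_s", "max_depth_m"])
    # surface duration runs to the next down-crossing, complete dive or not
    surf = np.full(len(dives), np.nan)
    for k in range(len(dives)):
        later = downs[t[downs] > dives["end"].iloc[k]]
        if later.size:
            surf[k] = (t[later[0]] - dives["end"].iloc[k]) / np.timedelta64(1, "s")
    dives["surface_duration_s"] = surf
    return dives


def count_lunges(dives: pd.DataFrame, lunge_times) -> pd.DataFrame:
    """Attach per-dive lunge counts from lunge-event timestamps.

    A lunge belongs to the dive whose [start, end) interval contains it;
    lunges outside any dive are ignored (surface events do not occur in
    these data).
    """
    lt = np.sort(pd.to_datetime(pd.Series(lunge_times)).to_numpy())
    out = dives.copy()
    starts = pd.to_datetime(out["start"]).to_numpy()
    ends = pd.to_datetime(out["end"]).to_numpy()
    out["lunges"] = [
        int(((lt >= s) & (lt < e)).sum()) for s, e in zip(starts, ends)
    ]
    return out


# ---------------------------------------------------------------------------
# GPS
# ---------------------------------------------------------------------------

def _pairwise_speed_ok(gps: pd.DataFrame, i: int, j: int, max_speed: float,
                       geographic: bool) -> bool:
    dt = (gps["timestamp"].iloc[j] - gps["timestamp"].iloc[i]).total_seconds()
    if dt <= 0:
        return False
    if geographic:
        d = float(haversine_m(gps["lon"].iloc[i], gps["lat"].iloc[i],
                              gps["lon"].iloc[j], gps["lat"].iloc[j]))
    else:
        d = 1000.0 * float(np.hypot(gps["lon"].iloc[j] - gps["lon"].iloc[i],
                                    gps["lat"].iloc[j] - gps["lat"].iloc[i]))
    return d / dt <= max_speed


def filter_gps_speed(
    gps: pd.DataFrame, max_speed: float = 6.0, geographic: bool = True
) -> pd.DataFrame:
    """Remove fixes implying unrealistic speeds (> ``max_speed`` m s-1).

    Retains the largest time-ordered subset of fixes in which every pair of
    consecutive retained fixes implies a great-circle speed at or below the
    limit (minimal-removal rule); among equally large subsets the earliest
    fixes win.  The first and last fixes have no special retention right.
    Fewer than 2 fixes are returned unchanged.
    """
    gps = gps.sort_values("timestamp").reset_index(drop=True)
    gps["timestamp"] = pd.to_datetime(gps["timestamp"])
    n = len(gps)
    if n < 2:
        return gps
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok[i, j] = _pairwise_speed_ok(gps, i, j, max_speed, geographic)
    # longest chain from each node, right to left
    R = np.ones(n, dtype=int)
    for i in range(n - 2, -1, -1):
        succ = np.flatnonzero(ok[i, i + 1:]) + i + 1
        if succ.size:
            R[i] = 1 + R[succ].max()
    target = int(R.max())
    # lexicographically earliest maximal chain
    chain: list[int] = []
    last = -1
    remaining = target
    for i in range(n):
        if remaining == 0:
            break
        if (last < 0 or ok[last, i]) and R[i] >= remaining:
            chain.append(i)
            last = i
            remaining -= 1
    return gps.iloc[chain].reset_index(drop=True)


def assign_dive_locations(
    deployment: Deployment, max_gap_min: float = 15.0
) -> Deployment:
    """Interpolate dive-start locations from the filtered GPS track.

    A dive whose start time falls between two fixes closer than
    ``max_gap_min`` minutes gets the linearly interpolated position; a dive
    coincident with a fix gets that fix exactly; otherwise the location is
    missing and the dive is excluded from downstream location-based
    statistics.
    """
    gps = deployment.gps.sort_values("timestamp").reset_index(drop=True)
    dives = deployment.dives.copy()
    ft = pd.to_datetime(gps["timestamp"]).to_numpy().astype("datetime64[ns]")
    ds = pd.to_datetime(dives["start"]).to_numpy().astype("datetime64[ns]")
    lon = np.full(len(dives), np.nan)
    lat = np.full(len(dives), np.nan)
    if len(gps):
        glon = gps["lon"].to_numpy(dtype=float)
        glat = gps["lat"].to_numpy(dtype=float)
        idx = np.searchsorted(ft, ds)
        for k, (t, i) in enumerate(zip(ds, idx)):
            exact = np.flatnonzero(ft == t)
            if exact.size:
                lon[k], lat[k] = glon[exact[0]], glat[exact[0]]
                continue
            if i == 0 or i == len(ft):
                continue
            gap_min = (ft[i] - ft[i - 1]) / np.timedelta64(1, "m")
            if gap_min < max_gap_min:
                w = (t - ft[i - 1]) / (ft[i] - ft[i - 1])
                lon[k] = glon[i - 1] + w * (glon[i] - glon[i - 1])
                lat[k] = glat[i - 1] + w * (glat[i] - glat[i - 1])
    dives["lon"] = lon
    dives["lat"] = lat
    return Deployment(
        individual_id=deployment.individual_id, dives=dives, gps=gps,
        region=deployment.region, meta=deployment.meta,
    )


# ---------------------------------------------------------------------------
# feeding rates and states
# ---------------------------------------------------------------------------

def compute_feeding_rates(dives: pd.DataFrame) -> pd.DataFrame:
    """Dive-cycle feeding rate in lunges per hour.

    rate = lunges / (dive duration + post-dive surface duration) * 3600.
    A dive with no lunges is non-feeding with rate 0; the final dive of a
    deployment (missing surface duration) has an undefined rate and is
    flagged via NaN.
    """
    out = dives.copy()
    cycle = out["duration_s"] + out["surface_duration_s"]
    rate = out["lunges"] / cycle * 3600.0
    rate = np.where(out["lunges"] == 0, 0.0, rate)
    rate = np.where(cycle.isna(), np.nan, rate)
    out["feeding"] = out["lunges"] >= 1
    out["feeding_rate"] = rate
    return out


def normalize_and_label_states(dives: pd.DataFrame) -> pd.DataFrame:
    """Per-individual percentile-rank normalisation (FR_pct) and 4 states.

    FR_pct of a feeding dive is the percentage of that individual's feeding
    dives with rate at or below its own (average rank for ties); non-feeding
    dives are pinned at 0.  States: non-feeding; light (FR_pct <= 25);
    moderate (25 < FR_pct < 75); heavy (FR_pct >= 75).
    """
    out = dives.copy()
    fr_pct = np.zeros(len(out))
    state = np.full(len(out), "non-feeding", dtype=object)
    feeding = (out["feeding"].to_numpy(dtype=bool)
               & out["feeding_rate"].notna().to_numpy())
    rates_all = out["feeding_rate"].to_numpy(dtype=float)
    for ind, pos in out.groupby("individual_id", sort=False).indices.items():
        feed = pos[feeding[pos]]
        n = feed.size
        if n == 0:
            continue
        if n < 4:
            warnings.warn(
                f"individual {ind}: only {n} feeding dives; FR_pct is coarse"
            )
        pct = rankdata(rates_all[feed], method="average") / n * 100.0
        fr_pct[feed] = pct
        state[feed] = np.where(
            pct >= 75.0, "heavy", np.where(pct <= 25.0, "light", "moderate"))
    out["fr_pct"] = fr_pct
    out["state"] = pd.Categorical(state, categories=list(STATES))
    return out
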