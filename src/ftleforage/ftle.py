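"""Backward-in-time finite-time Lyapunov exponent (FTLE) fields.

The Lagrangian feature proxy: for each analysis hour, a refined grid of
tracers (default 10x the velocity-grid resolution, i.e. 600 m from a 6 km
grid) is advected backward over a fixed horizon (default 48 h) through the
gridded surface currents with an adaptive Runge-Kutta-Fehlberg 4(5) scheme.
The spatial gradient of the resulting flow map gives the Cauchy-Green tensor
C = (dPhi)^T (dPhi); FTLE = ln(lambda_max(C)) / (2|T|), reported in day^-1.
Ridges of the backward FTLE mark attracting, aggregative transport structures
(fronts, eddy boundaries) that concentrate material at the surface.

Policies the upstream data products leave open, chosen here and recorded in
output metadata: tracers that exit the grid hull freeze at the exit point and
are flagged; tracers entering a data gap use the nearest valid cell's
velocity if one lies within one parent-grid cell, else freeze; FTLE cells
whose finite-difference stencil touches a frozen tracer are masked invalid;
one-sided differences at the grid edge are kept but flagged lower-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from .flowfield import (
    STATUS_OK,
    VelocityField,
    _free_slip_fill,
    interp_velocity,
    metres_per_unit,
)

__all__ = [
    "TracerGrid",
    "FlowMap",
    "FTLEField",
    "FTLESeries",
    "seed_tracers",
    "integrate_flow_map",
    "compute_ftle_field",
    "compute_ftle_series",
    "extract_ftle_at",
    "save_ftle_series",
    "load_ftle_series",
]

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0

# Fehlberg 4(5) tableau
_A = [
    (),
    (1 / 4,),
    (3 / 32, 9 / 32),
    (1932 / 2197, -7200 / 2197, 7296 / 2197),
    (439 / 216, -8.0, 3680 / 513, -845 / 4104),
    (-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40),
]
_C = np.array([0, 1 / 4, 3 / 8, 12 / 13, 1, 1 / 2])
_B5 = np.array([16 / 135, 0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55])
_B4 = np.array([25 / 216, 0, 1408 / 2565, 2197 / 4104, -1 / 5, 0])


@dataclass
class TracerGrid:
    """Regular refined seed grid covering the velocity grid's water domain."""

    x: np.ndarray  # (nx,) seed x coordinates
    y: np.ndarray  # (ny,)
    valid: np.ndarray  # (ny, nx); False for seeds over land
    refinement: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.size, self.x.size


@dataclass
class FlowMap:
    """Final tracer positions after integration over a signed horizon."""

    tracers: TracerGrid
    t0: np.datetime64
    horizon_hours: float
    final_x: np.ndarray  # (ny, nx)
    final_y: np.ndarray
    exited: np.ndarray  # (ny, nx) left the hull or froze in a persistent gap
    n_steps: int = 0
    n_rejected: int = 0
    geographic: bool = True


@dataclass
class FTLEField:
    """One hourly FTLE scalar grid in day^-1 at tracer resolution."""

    time: np.datetime64
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # (ny, nx), day^-1
    valid: np.ndarray  # (ny, nx)
    horizon_hours: float
    edge_flag: np.ndarray | None = None  # one-sided-difference cells
    geographic: bool = True
    metadata: dict = dc_field(default_factory=dict)


@dataclass
class FTLESeries:
    """Hourly FTLE fields on a common grid, plus a manifest of skipped hours."""

    fields: list
    skipped: list

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.fields], dtype="datetime64[ns]")

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_tracers(field: VelocityField, refinement: int = 10) -> TracerGrid:
    """Seed a regular tracer grid at ``refinement`` x the velocity resolution.

    Fencepost rule: a parent grid with n nodes per axis (n - 1 cells) yields
    (n - 1) * refinement + 1 seeds spanning the same extent, so seed spacing
    is exactly the parent spacing / refinement and refinement 1 reproduces
    the parent nodes.
    """
    if refinement < 1:
        raise ValueError(f"refinement must be >= 1, got {refinement}")
    refinement = int(refinement)
    sx = np.linspace(field.x[0], field.x[-1], (field.x.size - 1) * refinement + 1)
    sy = np.linspace(field.y[0], field.y[-1], (field.y.size - 1) * refinement + 1)
    # a seed over land (nearest parent node is land) is invalid
    ix = np.clip(np.rint((sx - field.x[0]) / field.dx).astype(int), 0, field.x.size - 1)
    iy = np.clip(np.rint((sy - field.y[0]) / field.dy).astype(int), 0, field.y.size - 1)
    valid = ~field.land_mask[np.ix_(iy, ix)]
    return TracerGrid(x=sx, y=sy, valid=valid, refinement=refinement)


# ---------------------------------------------------------------------------
# advection
# ---------------------------------------------------------------------------

def _gap_filled_uv(field: VelocityField) -> tuple[np.ndarray, np.ndarray]:
    """Free-slip land fill plus one-parent-cell nearest fill of data gaps.

    A gap cell takes the mean of valid water cells in its 3x3 neighbourhood
    (within one parent-grid cell); cells with no valid neighbour stay NaN and
    act as persistent gaps that freeze tracers.
    """
    u = field.u.copy()
    v = field.v.copy()
    gap = field.gap_mask
    if gap.any():
        for arr in (u, v):
            padded = np.pad(arr, ((0, 0), (1, 1), (1, 1)), constant_values=np.nan)
            stack = [
                padded[:, 1 + dy: padded.shape[1] - 1 + dy,
                       1 + dx: padded.shape[2] - 1 + dx]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if not (dx == 0 and dy == 0)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                neigh = np.nanmean(np.stack(stack), axis=0)
            arr[gap] = neigh[gap]
    return _free_slip_fill(u, v, field.land_mask)


def _coord_rates(field, px, py, t_sec, uv):
    """d(coord)/dt for tracers at (px, py): velocity converted to grid units."""
    xc = np.clip(px, field.x[0], field.x[-1])
    yc = np.clip(py, field.y[0], field.y[-1])
    u, v, status = interp_velocity(field, xc, yc, t_sec, uv_override=uv)
    if field.geographic:
        m_lat = 6371008.8 * np.pi / 180.0
        m_lon = m_lat * np.cos(np.deg2rad(yc))
    else:
        m_lon = m_lat = 1000.0
    return u / m_lon, v / m_lat, status


def integrate_flow_map(
    field: VelocityField,
    tracers: TracerGrid,
    t0,
    horizon_hours: float = -48.0,
    rel_tol: float = 1e-4,
    atol_m: float = 1.0,
    max_step_s: float = 3600.0,
) -> FlowMap:
    """Advect tracers from ``t0`` over a signed horizon with adaptive RKF4(5).

    A negative horizon integrates backward in time (dt < 0 through the same
    velocity field).  Step size is shared across tracers and controlled by
    the worst per-tracer embedded 4th/5th-order error estimate in metres,
    against tolerance ``atol_m + rel_tol * step_displacement``.
    """
    t0 = np.datetime64(t0, "ns")
    t_start = field.seconds_of(t0)
    t_end = t_start + horizon_hours * SECONDS_PER_HOUR
    ts = field.t_seconds
    if not (ts[0] - 1e-6 <= min(t_start, t_end) and max(t_start, t_end) <= ts[-1] + 1e-6):
        need_h = (ts[0] - min(t_start, t_end)) / SECONDS_PER_HOUR
        raise ValueError(
            f"integration window [{min(t_start, t_end) / 3600:.1f}, "
            f"{max(t_start, t_end) / 3600:.1f}] h exceeds field coverage "
            f"[{ts[0] / 3600:.1f}, {ts[-1] / 3600:.1f}] h "
            f"(shortfall {max(need_h, 0):.1f} h before field start)"
        )
    if horizon_hours == 0:
        raise ValueError("horizon must be nonzero")

    uv = _gap_filled_uv(field)
    ny, nx = tracers.shape
    X, Y = np.meshgrid(tracers.x, tracers.y)
    px = X.ravel().astype(float)
    py = Y.ravel().astype(float)
    active = tracers.valid.ravel().copy()
    frozen = np.zeros_like(active)

    y_ref = 0.5 * (field.y[0] + field.y[-1])
    m_lon, m_lat = metres_per_unit(field, y_ref)

    sign = np.sign(t_end - t_start)
    dt = sign * min(max_step_s, abs(t_end - t_start))
    t = t_start
    n_steps = n_rejected = 0
    max_iter = 100000

    while sign * (t_end - t) > 1e-9 and active.any() and n_steps + n_rejected < max_iter:
        if sign * (t + dt - t_end) > 0:
            dt = t_end - t
        ks = []
        bad = np.zeros(px.shape, dtype=bool)
        for i in range(6):
            dx = sum(a * k[0] for a, k in zip(_A[i], ks)) if i else 0.0
            dy = sum(a * k[1] for a, k in zip(_A[i], ks)) if i else 0.0
            kx, ky, status = _coord_rates(
                field, px + dt * dx, py + dt * dy, t + _C[i] * dt, uv
            )
            bad |= active & (status != STATUS_OK) & np.isnan(kx)
            ks.append((np.nan_to_num(kx), np.nan_to_num(ky)))
        x5 = px + dt * sum(b * k[0] for b, k in zip(_B5, ks))
        y5 = py + dt * sum(b * k[1] for b, k in zip(_B5, ks))
        x4 = px + dt * sum(b * k[0] for b, k in zip(_B4, ks))
        y4 = py + dt * sum(b * k[1] for b, k in zip(_B4, ks))
        err_m = np.hypot((x5 - x4) * m_lon, (y5 - y4) * m_lat)
        disp_m = np.hypot((x5 - px) * m_lon, (y5 - py) * m_lat)
        tol = atol_m + rel_tol * disp_m
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.nanmax(np.where(active, err_m / tol, 0.0))
        if not np.isfinite(ratio):
            ratio = 2.0
        if ratio <= 1.0:
            # freeze tracers that hit a persistent gap this step
            newly_gapped = active & bad
            frozen |= newly_gapped
            active &= ~newly_gapped
            px = np.where(active, x5, px)
            py = np.where(active, y5, py)
            # freeze tracers that left the hull, at the (clipped) exit point
            out = active & (
                (px < field.x[0]) | (px > field.x[-1])
                | (py < field.y[0]) | (py > field.y[-1])
            )
            px = np.clip(px, field.x[0], field.x[-1])
            py = np.clip(py, field.y[0], field.y[-1])
            frozen |= out
            active &= ~out
            t += dt
            n_steps += 1
        else:
            n_rejected += 1
        fac = 0.9 * ratio ** -0.2 if ratio > 0 else 5.0
        dt = dt * min(5.0, max(0.2, fac))
        if abs(dt) > max_step_s:
            dt = sign * max_step_s
        if abs(dt) < 1e-6:
            dt = sign * 1e-6

    return FlowMap(
        tracers=tracers,
        t0=t0,
        horizon_hours=float(horizon_hours),
        final_x=px.reshape(ny, nx),
        final_y=py.reshape(ny, nx),
        exited=(frozen | ~tracers.valid.ravel()).reshape(ny, nx),
        n_steps=n_steps,
        n_rejected=n_rejected,
        geographic=field.geographic,
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _grad_axis(a: np.ndarray, spacing: np.ndarray, axis: int) -> np.ndarray:
    """np.gradient wrapper: central interior, one-sided at edges."""
    return np.gradient(a, spacing, axis=axis)


def compute_ftle_field(flowmap: FlowMap, horizon_hours: float | None = None) -> FTLEField:
    """FTLE (day^-1) from a flow map by central-difference Cauchy-Green.

    The flow-map gradient is taken over the 4 grid neighbours of each seed
    (one-sided at grid edges, flagged in ``edge_flag``); lambda_max of the
    2x2 Cauchy-Green tensor comes from its closed-form quadratic; cells with
    any exited or invalid tracer in the stencil are masked invalid.
    """
    if horizon_hours is None:
        horizon_hours = flowmap.horizon_hours
    tr = flowmap.tracers
    y_ref = 0.5 * (tr.y[0] + tr.y[-1])
    if flowmap.geographic:
        m_lat = 6371008.8 * np.pi / 180.0
        m_lon = m_lat * np.cos(np.deg2rad(y_ref))
    else:
        m_lon = m_lat = 1000.0
    fx = flowmap.final_x * m_lon
    fy = flowmap.final_y * m_lat
    x0 = tr.x * m_lon
    y0 = tr.y * m_lat

    f11 = _grad_axis(fx, x0, axis=1)
    f12 = _grad_axis(fx, y0, axis=0)
    f21 = _grad_axis(fy, x0, axis=1)
    f22 = _grad_axis(fy, y0, axis=0)

    # C = F^T F (2x2 symmetric): closed-form largest eigenvalue
    c11 = f11 * f11 + f21 * f21
    c12 = f11 * f12 + f21 * f22
    c22 = f12 * f12 + f22 * f22
    half_tr = 0.5 * (c11 + c22)
    disc = np.sqrt(np.maximum(0.25 * (c11 - c22) ** 2 + c12 ** 2, 0.0))
    lam_max = half_tr + disc

    T_days = abs(horizon_hours) / HOURS_PER_DAY
    with np.errstate(divide="ignore", invalid="ignore"):
        ftle = np.log(np.maximum(lam_max, 1e-300)) / (2.0 * T_days)

    bad = flowmap.exited | ~tr.valid
    # any bad stencil neighbour (including self) invalidates the cell
    grow = bad.copy()
    grow[1:, :] |= bad[:-1, :]
    grow[:-1, :] |= bad[1:, :]
    grow[:, 1:] |= bad[:, :-1]
    grow[:, :-1] |= bad[:, 1:]
    valid = ~grow & np.isfinite(ftle)
    ftle = np.where(valid, ftle, np.nan)

    edge = np.zeros_like(valid)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True

    return FTLEField(
        time=flowmap.t0,
        x=tr.x,
        y=tr.y,
        values=ftle,
        valid=valid,
        horizon_hours=float(horizon_hours),
        edge_flag=edge,
        geographic=flowmap.geographic,
        metadata={
            "exit_policy": "freeze-at-exit",
            "gap_policy": "nearest-valid-within-one-parent-cell-else-freeze",
            "n_steps": flowmap.n_steps,
            "n_rejected": flowmap.n_rejected,
        },
    )


# ---------------------------------------------------------------------------
# hourly series
# ---------------------------------------------------------------------------

def compute_ftle_series(
    field: VelocityField,
    hours,
    horizon_hours: float = -48.0,
    refinement: int = 10,
    rel_tol: float = 1e-4,
) -> FTLESeries:
    """One backward FTLE field per requested hour, independent across hours.

    Hours without full antecedent velocity coverage are skipped with a
    warning and listed in the returned manifest.
    """
    tracers = seed_tracers(field, refinement)
    ts = field.t_seconds
    fields, skipped = [], []
    for h in np.asarray(hours, dtype="datetime64[ns]"):
        t0 = field.seconds_of(h)
        lo, hi = sorted((t0, t0 + horizon_hours * SECONDS_PER_HOUR))
        if lo < ts[0] - 1e-6 or hi > ts[-1] + 1e-6:
            warnings.warn(f"skipping {h}: insufficient velocity coverage")
            skipped.append(h)
            continue
        fm = integrate_flow_map(field, tracers, h, horizon_hours, rel_tol=rel_tol)
        fields.append(compute_ftle_field(fm))
    return FTLESeries(fields=fields, skipped=skipped)


def extract_ftle_at(series: FTLESeries, x, y, t, max_dt_minutes: float = 30.0):
    """FTLE at positions/times by nearest valid cell of the nearest field.

    The temporally nearest hourly field is used when within ``max_dt_minutes``
    (default 30 min) of the query; the spatially nearest grid cell supplies
    the value, falling back to the nearest valid cell in its 3x3
    neighbourhood; otherwise NaN (missing, not an error).  Scalar inputs give
    a scalar; arrays are vectorised.
    """
    scalar = np.isscalar(x) or (np.ndim(x) == 0)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype="datetime64[ns]"))
    out = np.full(x.shape, np.nan)
    if len(series) == 0:
        return float(out[0]) if scalar else out
    ftimes = series.times.astype("int64")
    tq = t.astype("int64")
    idx = np.clip(np.searchsorted(ftimes, tq), 0, ftimes.size - 1)
    idx_lo = np.clip(idx - 1, 0, ftimes.size - 1)
    choose_lo = np.abs(tq - ftimes[idx_lo]) <= np.abs(ftimes[idx] - tq)
    nearest = np.where(choose_lo, idx_lo, idx)
    dt_min = np.abs(tq - ftimes[nearest]) / 1e9 / 60.0
    ok = dt_min <= max_dt_minutes + 1e-9
    for k in np.unique(nearest[ok]):
        f = series.fields[int(k)]
        sel = ok & (nearest == k)
        dxs = f.x[1] - f.x[0]
        dys = f.y[1] - f.y[0]
        ix = np.rint((x[sel] - f.x[0]) / dxs).astype(int)
        iy = np.rint((y[sel] - f.y[0]) / dys).astype(int)
        inside = (ix >= 0) & (ix < f.x.size) & (iy >= 0) & (iy < f.y.size)
        vals = np.full(ix.shape, np.nan)
        ixc = np.clip(ix, 0, f.x.size - 1)
        iyc = np.clip(iy, 0, f.y.size - 1)
        vals[inside] = f.values[iyc[inside], ixc[inside]]
        # nearest valid cell within the 3x3 neighbourhood
        need = inside & ~np.isfinite(vals)
        if need.any():
            best = np.full(need.sum(), np.nan)
            bestd = np.full(need.sum(), np.inf)
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    jx = np.clip(ixc[need] + dx, 0, f.x.size - 1)
                    jy = np.clip(iyc[need] + dy, 0, f.y.size - 1)
                    cand = f.values[jy, jx]
                    d2 = (jx - (x[sel][need] - f.x[0]) / dxs) ** 2 + (
                        jy - (y[sel][need] - f.y[0]) / dys
                    ) ** 2
                    take = np.isfinite(cand) & (d2 < bestd)
                    best = np.where(take, cand, best)
                    bestd = np.where(take, d2, bestd)
            vals[need] = best
        out[sel] = vals
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_ftle_series(series: FTLESeries, path) -> None:
    """Write the series as NetCDF (time/y/x grid, variable ``ftle``, day^-1)."""
    if len(series) == 0:
        raise ValueError("empty series")
    f0 = series.fields[0]
    xname, yname = ("lon", "lat") if f0.geographic else ("x", "y")
    vals = np.stack([f.values for f in series.fields])
    ds = xr.Dataset(
        {"ftle": (("time", yname, xname), vals)},
        coords={"time": series.times, yname: f0.y, xname: f0.x},
    )
    ds["ftle"].attrs.update(units="day-1", horizon_hours=f0.horizon_hours)
    ds.attrs["geographic"] = int(f0.geographic)
    ds.attrs.update({k: str(v) for k, v in f0.metadata.items()})
    ds.to_netcdf(path, engine="scipy")


def load_ftle_series(path) -> FTLESeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    geographic = bool(ds.attrs.get("geographic", 1))
    xname, yname = ("lon", "lat") if "lon" in ds.coords else ("x", "y")
    horizon = float(ds["ftle"].attrs.get("horizon_hours", -48.0))
    fields = []
    for i, t in enumerate(ds["time"].values):
        vals = ds["ftle"].values[i]
        fields.append(
            FTLEField(
                time=t,
                x=ds[xname].values,
                y=ds[yname].values,
                values=vals,
                valid=np.isfinite(vals),
                horizon_hours=horizon,
                geographic=geographic,
            )
        )
    return FTLESeries(fields=fields, skipped=[])
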