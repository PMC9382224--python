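"""Gridded surface-current fields: validation, I/O and space-time interpolation.

The Eulerian input to the Lagrangian analysis is an hourly sequence of surface
current vector grids (u, v in m s-1) of the kind produced by coastal HF-radar
networks (~6 km, hourly).  This module owns the container (:class:`VelocityField`),
its NetCDF / long-CSV round trip, and the velocity lookup contract the tracer
advection engine relies on: bilinear interpolation in space, linear in time,
with a free-slip treatment of land so that tracers slide along a coast instead
of penetrating it.

Coordinates are either geographic (WGS84 lon/lat degrees) or planar kilometres;
all metric arithmetic uses a local equirectangular tangent projection, whose
error is negligible at the <=100 km scales this analysis works at.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "VelocityField",
    "OutOfDomainError",
    "STATUS_OK",
    "STATUS_MISSING",
    "STATUS_OUT_OF_DOMAIN",
    "load_velocity_grid",
    "save_velocity_grid",
    "velocity_at",
    "interp_velocity",
    "metres_per_unit",
]

EARTH_RADIUS_M = 6371008.8

#: status codes returned by :func:`interp_velocity`
STATUS_OK = 0
STATUS_MISSING = 1
STATUS_OUT_OF_DOMAIN = 2


class OutOfDomainError(ValueError):
    """Query outside the grid hull or time span (distinct from a data gap)."""


class FieldValidationError(ValueError):
    """The file or arrays do not form a valid velocity grid."""


def _check_axis(name: str, coords: np.ndarray) -> None:
    if coords.ndim != 1 or coords.size < 2:
        raise FieldValidationError(f"{name} axis must be 1-D with >= 2 points")
    d = np.diff(coords)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0))
        raise FieldValidationError(
            f"{name} axis not strictly ascending at index {i} (value {coords[i + 1]!r})"
        )
    # grid spacing constant per axis within 1%
    if np.max(d) - np.min(d) > 0.01 * np.mean(d):
        raise FieldValidationError(f"{name} axis spacing varies by more than 1%")


@dataclass
class VelocityField:
    """A time-stamped gridded surface-current vector field.

    Parameters
    ----------
    x, y : 1-D ascending coordinate arrays. Longitude/latitude degrees when
        ``geographic`` is true, planar kilometres otherwise.
    times : strictly increasing ``datetime64[ns]`` timestamps (hourly frames,
        each the instantaneous solution at that time).
    u, v : float arrays of shape (time, y, x) in m s-1; NaN marks a data gap.
    land_mask : boolean (y, x) grid, True over land.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray | None = None
    geographic: bool = True
    _filled: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        _check_axis("x", self.x)
        _check_axis("y", self.y)
        if self.times.ndim != 1 or self.times.size < 1:
            raise FieldValidationError("time axis must be 1-D and non-empty")
        dt = np.diff(self.times.astype("int64"))
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise FieldValidationError(
                f"time axis not strictly increasing at {self.times[i + 1]}"
            )
        shape = (self.times.size, self.y.size, self.x.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise FieldValidationError(
                f"u/v shape {self.u.shape}/{self.v.shape} != (time, y, x) {shape}"
            )
        if not np.array_equal(np.isnan(self.u), np.isnan(self.v)):
            raise FieldValidationError("u and v must share their missing-value mask")
        if self.land_mask is None:
            self.land_mask = np.zeros(shape[1:], dtype=bool)
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
            if self.land_mask.shape != shape[1:]:
                raise FieldValidationError("land_mask shape must be (y, x)")

    # -- derived geometry -------------------------------------------------
    @property
    def dx(self) -> float:
        return float(np.mean(np.diff(self.x)))

    @property
    def dy(self) -> float:
        return float(np.mean(np.diff(self.y)))

    @property
    def t_seconds(self) -> np.ndarray:
        """Frame times as float seconds since the first frame."""
        return (self.times - self.times[0]).astype("timedelta64[ns]").astype(
            float
        ) / 1e9

    def seconds_of(self, t) -> float:
        """Convert a timestamp to seconds since the first frame."""
        t = np.datetime64(t, "ns")
        return float((t - self.times[0]).astype("timedelta64[ns]").astype(float) / 1e9)

    @property
    def gap_mask(self) -> np.ndarray:
        """(time, y, x) True where a water cell has missing data."""
        return np.isnan(self.u) & ~self.land_mask[None, :, :]

    def replace(self, **kw) -> "VelocityField":
        kw.setdefault("_filled", None)
        return dataclasses.replace(self, **kw)

    # -- free-slip / gap handling -----------------------------------------
    def filled_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """u, v with land nodes replaced by free-slip values.

        A land node adjacent to water across a vertical coast edge gets the
        tangential (v) velocity of its water neighbours and zero normal (u)
        velocity, and symmetrically for horizontal edges, so that bilinear
        interpolation at the coast yields zero flow through it.  Data gaps
        (NaN over water) are preserved.  Cached.
        """
        if self._filled is None:
            self._filled = _free_slip_fill(self.u, self.v, self.land_mask)
        return self._filled


def _neighbour_mean(arr: np.ndarray, valid: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean of the two along-`axis` neighbours of each node, over valid ones."""
    num = np.zeros_like(arr)
    cnt = np.zeros(arr.shape, dtype=float)
    for shift in (1, -1):
        a = np.roll(arr, shift, axis=axis)
        m = np.roll(valid, shift, axis=axis)
        # edge rolls wrap; zero them out
        sl = [slice(None)] * arr.ndim
        sl[axis] = 0 if shift == 1 else -1
        m = m.copy()
        m[tuple(sl)] = False
        num += np.where(m, np.nan_to_num(a), 0.0)
        cnt += m
    with np.errstate(invalid="ignore"):
        mean = num / cnt
    return mean, cnt > 0


def _free_slip_fill(u: np.ndarray, v: np.ndarray, land: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uf = u.copy()
    vf = v.copy()
    if not land.any():
        return uf, vf
    land3 = np.broadcast_to(land[None, :, :], u.shape)
    water_valid = ~land3 & ~np.isnan(u)
    # water neighbour across x => vertical coast edge: normal is u
    _, has_x = _neighbour_mean(u, water_valid, axis=2)
    vx_mean, _ = _neighbour_mean(v, water_valid, axis=2)
    # water neighbour across y => horizontal coast edge: normal is v
    uy_mean, has_y = _neighbour_mean(u, water_valid, axis=1)
    uf[land3] = 0.0
    vf[land3] = 0.0
    coast_x = land3 & has_x
    coast_y = land3 & has_y
    # tangential component slides: take it from the adjacent water nodes
    vf[coast_x] = np.nan_to_num(vx_mean[coast_x])
    uf[coast_y & ~coast_x] = np.nan_to_num(uy_mean[coast_y & ~coast_x])
    # a concave corner node (water on both axes) suppresses both components
    uf[coast_x & coast_y] = 0.0
    vf[coast_x & coast_y] = 0.0
    return uf, vf


def metres_per_unit(field: VelocityField, y_ref: float) -> tuple[float, float]:
    """Metres per coordinate unit (x, y) at reference latitude ``y_ref``.

    Local equirectangular projection for geographic fields; constant 1000 for
    planar-kilometre fields.
    """
    if field.geographic:
        m_lat = EARTH_RADIUS_M * np.pi / 180.0
        m_lon = m_lat * np.cos(np.deg2rad(y_ref))
        return float(m_lon), float(m_lat)
    return 1000.0, 1000.0


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _bilinear_frame(uf: np.ndarray, vf: np.ndarray, xg, yg, xq, yq):
    """Vectorised bilinear sample of one (y, x) frame pair. NaN propagates."""
    ix = np.clip(np.searchsorted(xg, xq, side="right") - 1, 0, xg.size - 2)
    iy = np.clip(np.searchsorted(yg, yq, side="right") - 1, 0, yg.size - 2)
    fx = (xq - xg[ix]) / (xg[ix + 1] - xg[ix])
    fy = (yq - yg[iy]) / (yg[iy + 1] - yg[iy])
    w00 = (1 - fx) * (1 - fy)
    w10 = fx * (1 - fy)
    w01 = (1 - fx) * fy
    w11 = fx * fy
    out = []
    for a in (uf, vf):
        out.append(
            w00 * a[iy, ix]
            + w10 * a[iy, ix + 1]
            + w01 * a[iy + 1, ix]
            + w11 * a[iy + 1, ix + 1]
        )
    return out[0], out[1]


def interp_velocity(
    field: VelocityField,
    xq: np.ndarray,
    yq: np.ndarray,
    t,
    uv_override: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolated (u, v, status) at positions ``(xq, yq)`` and time ``t``.

    Bilinear within the enclosing cell, linear between the two bracketing
    hourly frames.  ``status`` distinguishes a data gap (NaN result,
    ``STATUS_MISSING``) from a query outside the grid hull or time span
    (``STATUS_OUT_OF_DOMAIN``).  ``t`` may be a timestamp or float seconds
    since the first frame.  ``uv_override`` substitutes preprocessed (e.g.
    gap-filled) u/v arrays while keeping the field's geometry.
    """
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    yq = np.atleast_1d(np.asarray(yq, dtype=float))
    ts = field.t_seconds
    t_sec = field.seconds_of(t) if not isinstance(t, (int, float, np.floating)) else float(t)

    status = np.zeros(xq.shape, dtype=np.int8)
    oob = (
        (xq < field.x[0]) | (xq > field.x[-1]) | (yq < field.y[0]) | (yq > field.y[-1])
    )
    if t_sec < ts[0] - 1e-9 or t_sec > ts[-1] + 1e-9:
        status[:] = STATUS_OUT_OF_DOMAIN
        return np.full_like(xq, np.nan), np.full_like(xq, np.nan), status
    status[oob] = STATUS_OUT_OF_DOMAIN

    uall, vall = uv_override if uv_override is not None else field.filled_uv()
    k = int(np.clip(np.searchsorted(ts, t_sec, side="right") - 1, 0, ts.size - 1))
    if k == ts.size - 1:
        k = max(k - 1, 0)
    if ts.size == 1:
        u0, v0 = _bilinear_frame(uall[0], vall[0], field.x, field.y, xq, yq)
        u, v = u0, v0
    else:
        wt = (t_sec - ts[k]) / (ts[k + 1] - ts[k])
        u0, v0 = _bilinear_frame(uall[k], vall[k], field.x, field.y, xq, yq)
        u1, v1 = _bilinear_frame(uall[k + 1], vall[k + 1], field.x, field.y, xq, yq)
        u = (1 - wt) * u0 + wt * u1
        v = (1 - wt) * v0 + wt * v1
    miss = np.isnan(u) & (status == STATUS_OK)
    status[miss] = STATUS_MISSING
    u = np.where(status == STATUS_OK, u, np.nan)
    v = np.where(status == STATUS_OK, v, np.nan)
    return u, v, status


def velocity_at(field: VelocityField, x: float, y: float, t) -> tuple[float, float]:
    """Scalar convenience wrapper: (u, v) at one position and time.

    Raises :class:`OutOfDomainError` outside the hull/span; returns NaNs at a
    data gap (missing is a value, not an error).
    """
    u, v, status = interp_velocity(field, [x], [y], t)
    if status[0] == STATUS_OUT_OF_DOMAIN:
        raise OutOfDomainError(
            f"query ({x}, {y}) at {t} outside grid hull or time span"
        )
    return float(u[0]), float(v[0])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def to_dataset(field: VelocityField) -> xr.Dataset:
    xname, yname = ("lon", "lat") if field.geographic else ("x", "y")
    ds = xr.Dataset(
        {
            "u": (("time", yname, xname), field.u),
            "v": (("time", yname, xname), field.v),
            "land_mask": ((yname, xname), field.land_mask.astype(np.int8)),
        },
        coords={"time": field.times, yname: field.y, xname: field.x},
    )
    ds["u"].attrs["units"] = "m s-1"
    ds["v"].attrs["units"] = "m s-1"
    ds.attrs["geographic"] = int(field.geographic)
    return ds


def save_velocity_grid(field: VelocityField, path) -> None:
    """Write a CF-style NetCDF file (scipy backend, NetCDF3 classic)."""
    to_dataset(field).to_netcdf(path, engine="scipy")


def _from_dataset(ds: xr.Dataset) -> VelocityField:
    geographic = bool(ds.attrs.get("geographic", 1))
    xname, yname = ("lon", "lat") if "lon" in ds.coords else ("x", "y")
    for name in (xname, yname, "time"):
        if name not in ds.coords:
            raise FieldValidationError(f"missing coordinate variable {name!r}")
    if "u" not in ds or "v" not in ds:
        raise FieldValidationError("missing velocity variable 'u' or 'v'")
    land = (
        ds["land_mask"].values.astype(bool)
        if "land_mask" in ds
        else None
    )
    return VelocityField(
        x=ds[xname].values,
        y=ds[yname].values,
        times=ds["time"].values,
        u=ds["u"].values,
        v=ds["v"].values,
        land_mask=land,
        geographic=geographic,
    )


def load_velocity_grid(path, format: str = "netcdf") -> VelocityField:
    """Load and validate a velocity grid from NetCDF or long-format CSV.

    The CSV long format has one row per (time, lat, lon) node with columns
    ``time, lat, lon, u, v`` (or ``x, y`` for planar fields).
    """
    if format == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            return _from_dataset(ds.load())
    if format == "csv_long":
        df = pd.read_csv(path)
        if "lat" in df.columns:
            xname, yname, geographic = "lon", "lat", True
        else:
            xname, yname, geographic = "x", "y", False
        for col in ("time", yname, xname, "u", "v"):
            if col not in df.columns:
                raise FieldValidationError(f"CSV missing column {col!r}")
        df["time"] = pd.to_datetime(df["time"])
        dup = df.duplicated(subset=["time", yname, xname])
        if dup.any():
            bad = df.loc[dup.idxmax(), "time"]
            raise FieldValidationError(f"repeated timestamp {bad} for a grid node")
        times = np.sort(df["time"].unique())
        xs = np.sort(df[xname].unique())
        ys = np.sort(df[yname].unique())
        piv_u = df.pivot_table(index=["time", yname], columns=xname, values="u", dropna=False)
        piv_v = df.pivot_table(index=["time", yname], columns=xname, values="v", dropna=False)
        shape = (times.size, ys.size, xs.size)
        u = piv_u.to_numpy().reshape(shape)
        v = piv_v.to_numpy().reshape(shape)
        return VelocityField(
            x=xs, y=ys, times=times.astype("datetime64[ns]"), u=u, v=v,
            geographic=geographic,
        )
    raise ValueError(f"unknown format {format!r}")
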