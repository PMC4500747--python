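"""Activation-time detection and conduction-velocity/anisotropy estimation.

Activation time is the time of maximum dV/dt of the upstroke (central
differences).  Conduction velocities are estimated from on-axis rays
through the pacing origin of an :class:`ActivationMap`: activation time is
regressed against distance along the longitudinal (x) and transverse (y)
axes, excluding a configurable near-field ring around the origin, and
CV is the inverse slope.  The anisotropy ratio is AR = CV_L / CV_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationError

MM_PER_MS_TO_CM_PER_S = 100.0


class EstimationError(RuntimeError):
    """Raised when too few activated sites are available for a CV fit."""


@dataclass
class ActivationMap:
    """Grid of activation times (ms) with spatial calibration.

    ``times[row, col]`` maps to physical position
    ``x = col * spacing_x_mm`` (longitudinal), ``y = row * spacing_y_mm``
    (transverse).  Sites that never activated are NaN.
    """

    times: np.ndarray
    spacing_x_mm: float
    spacing_y_mm: float
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.times.ndim != 2:
            raise ConfigurationError("activation map must be 2-D")
        if self.spacing_x_mm <= 0 or self.spacing_y_mm <= 0:
            raise ConfigurationError("site spacings must be > 0")
        r, c = self.origin
        nr, nc = self.times.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ConfigurationError("pacing origin lies outside the grid")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of sites with a finite activation time."""
        return np.isfinite(self.times)

    def transposed(self) -> "ActivationMap":
        """Swap the two axes (and their calibrations)."""
        return ActivationMap(self.times.T, self.spacing_y_mm,
                             self.spacing_x_mm, (self.origin[1], self.origin[0]))

    def to_csv(self, path) -> None:
        header = (f"spacing_x_mm={self.spacing_x_mm},"
                  f"spacing_y_mm={self.spacing_y_mm},"
                  f"origin={self.origin[0]}:{self.origin[1]}")
        np.savetxt(path, self.times, delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path) -> "ActivationMap":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        meta = dict(item.split("=") for item in header.split(","))
        orow, ocol = meta["origin"].split(":")
        times = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(np.atleast_2d(times), float(meta["spacing_x_mm"]),
                   float(meta["spacing_y_mm"]), (int(orow), int(ocol)))


@dataclass(frozen=True)
class CVResult:
    """Longitudinal and transverse conduction velocity (cm/s) and their ratio."""

    cv_l: float
    cv_t: float

    @property
    def ar(self) -> float:
        return self.cv_l / self.cv_t

    def to_dict(self) -> dict:
        return {"cv_l_cm_per_s": self.cv_l, "cv_t_cm_per_s": self.cv_t,
                "anisotropy_ratio": self.ar}


def activation_time(trace: np.ndarray, dt: float, *, t0: float = 0.0,
                    min_amplitude: float = 1.0) -> float:
    """Time (ms) of maximum dV/dt of an upstroke, or NaN if not activated.

    The derivative is computed by central differences (one-sided at the
    ends); ties are broken toward the earliest time.  A trace whose total
    excursion is below ``min_amplitude`` (mV) is reported as not activated.
    """
    v = np.asarray(trace, float)
    if v.ndim != 1 or v.size < 3:
        raise ConfigurationError("trace must be 1-D with >= 3 samples")
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    if np.ptp(v) < min_amplitude:
        return float("nan")
    dv = np.gradient(v, dt)
    return float(t0 + np.argmax(dv) * dt)


def activation_times(v: np.ndarray, dt: float, *, t0: float = 0.0,
                     min_amplitude: float = 1.0) -> np.ndarray:
    """Vectorized :func:`activation_time` over the columns of ``v``.

    ``v`` has shape (n_samples, n_sites); returns one time per site.
    """
    v = np.asarray(v, float)
    if v.ndim != 2:
        raise ConfigurationError("expected a (n_samples, n_sites) array")
    dv = np.gradient(v, dt, axis=0)
    t = t0 + np.argmax(dv, axis=0) * dt
    return np.where(np.ptp(v, axis=0) >= min_amplitude, t, np.nan)


def _ray_cv(times: np.ndarray, coords_mm: np.ndarray, origin_index: int,
            exclude_near: int, min_sites: int, axis_name: str) -> float:
    keep = np.isfinite(times)
    keep &= np.abs(np.arange(times.size) - origin_index) >= exclude_near
    if keep.sum() < min_sites:
        raise EstimationError(
            f"only {int(keep.sum())} activated sites on the {axis_name} ray "
            f"(need >= {min_sites})")
    d = np.abs(coords_mm[keep] - coords_mm[origin_index])
    slope, _ = np.polyfit(d, times[keep], 1)
    if slope <= 0:
        raise EstimationError(
            f"non-positive time-distance slope on the {axis_name} ray")
    return MM_PER_MS_TO_CM_PER_S / slope


def compute_cv(amap: ActivationMap, *, exclude_near: int = 2,
               min_sites: int = 5) -> CVResult:
    """CV_L, CV_T and AR from on-axis rays through the pacing origin.

    Activation time is regressed on distance from the origin along the
    origin's row (longitudinal) and column (transverse); sites within
    ``exclude_near`` grid steps of the origin are excluded from the fits.
    """
    orow, ocol = amap.origin
    cv_l = _ray_cv(amap.times[orow, :],
                   np.arange(amap.times.shape[1]) * amap.spacing_x_mm,
                   ocol, exclude_near, min_sites, "longitudinal")
    cv_t = _ray_cv(amap.times[:, ocol],
                   np.arange(amap.times.shape[0]) * amap.spacing_y_mm,
                   orow, exclude_near, min_sites, "transverse")
    return CVResult(cv_l, cv_t)


def cv_from_simulation(result, direction: str, *, exclude_near: int = 2,
                       min_sites: int = 5, min_amplitude: float = 40.0) -> float:
    """CV (cm/s) along one axis of a simulated sheet.

    Fits activation time against position for the cells of the middle row
    (``direction="longitudinal"``, x coordinate) or middle column
    (``direction="transverse"``, y coordinate) of the sheet, excluding
    ``exclude_near`` cells at each end of the ray (stimulus near field and
    boundary).  ``result`` is a :class:`~perinexus.solver.ProtocolResult`.
    """
    if direction == "longitudinal":
        sel = result.rows == result.rows.max() // 2
        coord = result.cell_xy[:, 0]
    elif direction == "transverse":
        sel = result.cols == result.cols.max() // 2
        coord = result.cell_xy[:, 1]
    else:
        raise ConfigurationError(
            "direction must be 'longitudinal' or 'transverse'")
    idx = np.flatnonzero(sel)
    idx = idx[np.argsort(coord[idx])]
    if idx.size - 2 * exclude_near < min_sites:
        raise EstimationError("sheet too small for the requested ray fit")
    dt = float(result.times[1] - result.times[0])
    t_act = activation_times(result.v_cells[:, idx], dt,
                             t0=float(result.times[0]),
                             min_amplitude=min_amplitude)
    inner = slice(exclude_near, idx.size - exclude_near)
    t_in, d_in = t_act[inner], coord[idx][inner] * 1e-3  # um -> mm
    if not np.all(np.isfinite(t_in)):
        raise EstimationError("conduction block inside the fit window")
    slope, _ = np.polyfit(d_in, t_in, 1)
    if slope <= 0:
        raise EstimationError(f"non-positive slope on the {direction} ray")
    return MM_PER_MS_TO_CM_PER_S / slope
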