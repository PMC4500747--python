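"""Ground-truth generators for the analysis pipelines.

Three generators mirror the three analysis stages:

* :func:`make_localization_image` renders two-channel cluster imagery
  (filled ellipses, optional Gaussian blur and noise) with a per-cluster
  truth table, for the cluster-association pipeline;
* :func:`make_activation_map` produces analytic elliptical activation
  maps with known CV_L/CV_T, for the wavefront estimators;
* :func:`make_upstroke_trace` produces sigmoidal upstrokes with known
  inflection time, for activation-time detection.

All generators are bit-deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ConfigurationError
from .cluster_analysis import CalibratedImage, OVERLAPPING, PERINEXAL, DISTAL
from .wavefront import ActivationMap, CVResult

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548


class GenerationError(RuntimeError):
    """Raised when a feasible placement cannot be found."""


# ---------------------------------------------------------------------------
# localization imagery

@dataclass(frozen=True)
class LocalizationImageSpec:
    """Two-channel synthetic gSTED-like field specification.

    Each Cx43 cluster receives ``n_overlapping``/``n_perinexal``/
    ``n_distal`` Nav1.5 partners; perinexal and distal partners are placed
    at the stated edge-to-edge distances (nm).  Cluster diameters are drawn
    uniformly from the given (low, high) ranges; ``elongation`` is the
    (low, high) range of the ellipse axis ratio.
    """

    shape_px: tuple = (768, 768)
    pixel_size_nm: float = 10.0
    n_cx43: int = 10
    cx43_diameter_nm: tuple = (150.0, 250.0)
    nav_diameter_nm: tuple = (80.0, 140.0)
    n_overlapping: int = 1
    n_perinexal: int = 1
    n_distal: int = 1
    perinexal_distance_nm: float = 100.0
    distal_distance_nm: float = 400.0
    elongation: tuple = (1.0, 1.0)
    blur_fwhm_nm: float = 0.0
    noise_sigma: float = 0.0       # fraction of peak amplitude
    amplitude: float = 200.0
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self):
        if self.pixel_size_nm <= 0 or self.amplitude <= 0:
            raise ConfigurationError("pixel size and amplitude must be > 0")
        if min(self.n_overlapping, self.n_perinexal, self.n_distal) < 0:
            raise ConfigurationError("partner counts must be >= 0")
        if self.n_cx43 < 0:
            raise ConfigurationError("n_cx43 must be >= 0")
        for lo, hi in (self.cx43_diameter_nm, self.nav_diameter_nm,
                       self.elongation):
            if not (0 < lo <= hi):
                raise ConfigurationError("ranges must satisfy 0 < low <= high")
        if not (0 < self.perinexal_distance_nm < self.distal_distance_nm):
            raise ConfigurationError(
                "need 0 < perinexal_distance < distal_distance")


def _ellipse_mask(shape, center, semi_axes_px, angle):
    a, b = semi_axes_px
    r = max(a, b) + 2.0
    r0 = max(int(np.floor(center[0] - r)), 0)
    r1 = min(int(np.ceil(center[0] + r)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - r)), 0)
    c1 = min(int(np.ceil(center[1] + r)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.zeros((0, 2), int)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rr, cc = np.nonzero(inside)
    return np.column_stack([rr + r0, cc + c0])


def _min_edge_px(pix_a, pix_b, shape):
    """(min EDT - 1) between two pixel sets, in pixels (>= 0)."""
    box = np.zeros(shape, bool)
    box[pix_a[:, 0], pix_a[:, 1]] = True
    edt = ndimage.distance_transform_edt(~box)
    return max(0.0, float(edt[pix_b[:, 0], pix_b[:, 1]].min()) - 1.0)


def make_localization_image(spec: LocalizationImageSpec):
    """Render the two channels and return (cx43, nav, truth table).

    The truth table lists every placed cluster with its channel, centroid,
    diameter, intended class, and intended/realized edge distances (nm,
    realized measured on the rasterized masks with the same edge-to-edge
    convention the analysis uses).
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_nm
    shape = tuple(spec.shape_px)
    d_hi = spec.cx43_diameter_nm[1] / px
    nav_hi = spec.nav_diameter_nm[1] / px
    # farthest a partner can sit from its home-cluster center
    reach = 0.5 * d_hi + spec.distal_distance_nm / px + nav_hi
    margin = reach + 4.0
    # any partner must stay distal (> perinexal width) to every foreign
    # Cx43 cluster, hence the center separation bound
    min_sep = (reach + 0.5 * d_hi
               + (spec.perinexal_distance_nm
                  + spec.distal_distance_nm) / (2 * px) + nav_hi + 6.0)

    if shape[0] - 2 * margin <= 1 or shape[1] - 2 * margin <= 1:
        raise GenerationError("field too small for the requested distances")

    records = []
    cx_pixel_sets, nav_pixel_sets = [], []

    centers = []
    for i in range(spec.n_cx43):
        for attempt in range(spec.max_retries + 1):
            c = rng.uniform([margin, margin],
                            [shape[0] - margin, shape[1] - margin])
            if all(np.hypot(*(c - o)) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise GenerationError(
                f"could not place Cx43 cluster {i} after "
                f"{spec.max_retries} retries")

    for i, center in enumerate(centers):
        d_cx = rng.uniform(*spec.cx43_diameter_nm)
        elong = rng.uniform(*spec.elongation)
        angle = rng.uniform(0, np.pi)
        # semi-axes with the same area as a d_cx-diameter circle
        a = 0.5 * d_cx / px * np.sqrt(elong)
        b = 0.5 * d_cx / px / np.sqrt(elong)
        cx_pix = _ellipse_mask(shape, center, (a, b), angle)
        if cx_pix.shape[0] == 0:
            raise GenerationError("degenerate Cx43 cluster rasterization")
        cx_pixel_sets.append(cx_pix)
        records.append({"channel": "cx43", "cluster_id": i, "home_cx43_id": i,
                        "row": center[0], "col": center[1],
                        "diameter_nm": d_cx, "cls": "",
                        "intended_edge_distance_nm": np.nan,
                        "realized_edge_distance_nm": np.nan})

        placements = ([(OVERLAPPING, 0.0)] * spec.n_overlapping
                      + [(PERINEXAL, spec.perinexal_distance_nm)]
                      * spec.n_perinexal
                      + [(DISTAL, spec.distal_distance_nm)] * spec.n_distal)
        for cls, gap_nm in placements:
            d_nav = rng.uniform(*spec.nav_diameter_nm)
            r_nav = 0.5 * d_nav / px
            phi = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.sin(phi), np.cos(phi)])
            if cls == OVERLAPPING:
                nav_center = center + direction * (0.25 * min(a, b))
                nav_pix = _ellipse_mask(shape, nav_center, (r_nav, r_nav), 0.0)
                realized = _min_edge_px(cx_pix, nav_pix, shape) * px
                if not (set(map(tuple, cx_pix)) & set(map(tuple, nav_pix))):
                    raise GenerationError("overlap placement failed")
            else:
                # iterate the center distance until the rasterized
                # edge-to-edge distance matches the intended gap
                s = max(a, b) + gap_nm / px + r_nav + 1.0
                nav_pix, realized = None, None
                for _ in range(12):
                    nav_center = center + direction * s
                    nav_pix = _ellipse_mask(shape, nav_center,
                                            (r_nav, r_nav), 0.0)
                    if nav_pix.shape[0] == 0:
                        raise GenerationError("partner left the field")
                    realized = _min_edge_px(cx_pix, nav_pix, shape) * px
                    err = gap_nm - realized
                    if abs(err) <= 0.5 * px:
                        break
                    s += err / px
            nav_pixel_sets.append(nav_pix)
            records.append({"channel": "nav", "cluster_id": len(nav_pixel_sets) - 1,
                            "home_cx43_id": i,
                            "row": nav_center[0], "col": nav_center[1],
                            "diameter_nm": d_nav, "cls": cls,
                            "intended_edge_distance_nm": gap_nm,
                            "realized_edge_distance_nm": realized})

    def render(pixel_sets):
        img = np.zeros(shape)
        for pix in pixel_sets:
            img[pix[:, 0], pix[:, 1]] = spec.amplitude
        if spec.blur_fwhm_nm > 0:
            img = ndimage.gaussian_filter(
                img, spec.blur_fwhm_nm * FWHM_TO_SIGMA / px)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma * spec.amplitude,
                                   size=shape)
        return np.clip(img, 0.0, None)

    cx_img = CalibratedImage(render(cx_pixel_sets), px, "cx43")
    nav_img = CalibratedImage(render(nav_pixel_sets), px, "nav1.5")
    truth = pd.DataFrame(records, columns=[
        "channel", "cluster_id", "home_cx43_id", "row", "col", "diameter_nm",
        "cls", "intended_edge_distance_nm", "realized_edge_distance_nm"])
    return cx_img, nav_img, truth


# ---------------------------------------------------------------------------
# activation maps and traces

@dataclass(frozen=True)
class SyntheticActivationSpec:
    """Elliptical activation-map specification (optical-mapping geometry)."""

    n_x: int = 90
    n_y: int = 60
    extent_x_mm: float = 16.5
    extent_y_mm: float = 12.0
    v_l: float = 60.0     # cm/s along x
    v_t: float = 30.0     # cm/s along y
    origin: tuple | None = None   # (row, col); default: grid center
    noise_sigma_ms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.v_l <= 0 or self.v_t <= 0:
            raise ConfigurationError("speeds must be > 0")
        if self.n_x < 2 or self.n_y < 2:
            raise ConfigurationError("grid must be at least 2x2")
        if self.noise_sigma_ms < 0:
            raise ConfigurationError("noise_sigma_ms must be >= 0")


def make_activation_map(spec: SyntheticActivationSpec):
    """Analytic elliptical map t = 100*sqrt((x/v_L)^2 + (y/v_T)^2) ms.

    Returns (ActivationMap, true CVResult).  x, y in mm from the pacing
    origin; the factor 100 converts mm/(cm/s) to ms.
    """
    dx = spec.extent_x_mm / (spec.n_x - 1)
    dy = spec.extent_y_mm / (spec.n_y - 1)
    origin = spec.origin if spec.origin is not None \
        else (spec.n_y // 2, spec.n_x // 2)
    orow, ocol = origin
    if not (0 <= orow < spec.n_y and 0 <= ocol < spec.n_x):
        raise ConfigurationError("origin outside the grid")
    x = (np.arange(spec.n_x) - ocol) * dx
    y = (np.arange(spec.n_y) - orow) * dy
    xx, yy = np.meshgrid(x, y)
    t = 100.0 * np.hypot(xx / spec.v_l, yy / spec.v_t)
    if spec.noise_sigma_ms > 0:
        rng = np.random.default_rng(spec.seed)
        t = t + rng.normal(0.0, spec.noise_sigma_ms, size=t.shape)
    return (ActivationMap(t, dx, dy, (orow, ocol)),
            CVResult(spec.v_l, spec.v_t))


def make_upstroke_trace(t_act: float, *, amplitude: float = 100.0,
                        tau: float = 0.5, dt: float = 0.05,
                        duration: float | None = None, v_rest: float = -85.0,
                        noise_sigma: float = 0.0, seed: int = 0):
    """Sigmoidal upstroke V(t) = V_rest + A/(1+exp(-(t-t_act)/tau)).

    Returns (times, trace, t_act).  ``noise_sigma`` is in mV.  The
    inflection (max dV/dt) lies at ``t_act``.
    """
    if duration is None:
        duration = 2.0 * t_act
    if not (0.0 < t_act < duration):
        raise ConfigurationError("t_act must lie inside the trace window")
    if tau <= 0 or dt <= 0:
        raise ConfigurationError("tau and dt must be > 0")
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    v = v_rest + amplitude / (1.0 + np.exp(-(times - t_act) / tau))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sigma, size=v.shape)
    return times, v, t_act
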