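"""Two-channel cluster identification and Nav1.5-Cx43 association analysis.

Pipeline: each channel is thresholded by Otsu's method, connected
components (8-connected by default) become clusters, and every Nav1.5
cluster is classified relative to the Cx43 clusters as

``overlapping``
    shares at least one pixel with a Cx43 cluster;
``perinexal``
    no shared pixel, but its minimum edge-to-edge distance to some Cx43
    cluster is within the perinexal width (default 200 nm);
``distal``
    otherwise.

Edge-to-edge distance between two clusters is defined on pixel centres as
``(min Euclidean distance - 1 px) * pixel_size``, so clusters whose
boundary pixels are adjacent have a gap of 0 nm.  Distances are computed
with a Euclidean distance transform on a padded bounding box per Cx43
cluster, which also yields per-Cx43 partner counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ConfigurationError

OVERLAPPING = "overlapping"
PERINEXAL = "perinexal"
DISTAL = "distal"
CLASSES = (OVERLAPPING, PERINEXAL, DISTAL)


class DegenerateImageError(ValueError):
    """Raised when an image cannot be thresholded (constant intensity)."""


@dataclass
class CalibratedImage:
    """A 2-D intensity image with physical pixel size (nm/pixel)."""

    data: np.ndarray
    pixel_size_nm: float
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ConfigurationError("image must be 2-D")
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be > 0")
        if np.any(self.data < 0):
            raise ConfigurationError("intensities must be non-negative")


@dataclass
class Cluster:
    """One connected component of a thresholded channel."""

    pixels: np.ndarray            # (n, 2) integer (row, col)
    pixel_size_nm: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, int).reshape(-1, 2)
        if self.pixels.shape[0] == 0:
            raise ConfigurationError("cluster must be non-empty")

    @property
    def area_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def area_nm2(self) -> float:
        return self.area_px * self.pixel_size_nm ** 2

    @property
    def centroid(self) -> tuple[float, float]:
        """Unweighted mean pixel coordinate (row, col)."""
        return tuple(self.pixels.mean(axis=0))

    @property
    def equivalent_diameter_nm(self) -> float:
        """Diameter of the circle with the same calibrated area."""
        return 2.0 * np.sqrt(self.area_nm2 / np.pi)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        return int(rmin), int(rmax), int(cmin), int(cmax)


def otsu_threshold(image) -> float:
    """Otsu's threshold: maximizes between-class variance of the histogram.

    For integer images the histogram is exact over the value range (one
    bin per integer); for float images a 256-bin histogram over
    [min, max] is used.  The returned threshold is a bin-edge value;
    foreground is ``data > threshold``.  Ties are broken toward the
    lowest threshold.
    """
    data = image.data if isinstance(image, CalibratedImage) else np.asarray(image)
    flat = data.ravel()
    lo, hi = flat.min(), flat.max()
    if lo == hi:
        raise DegenerateImageError("constant image has no Otsu threshold")
    if np.issubdtype(data.dtype, np.integer):
        values = np.arange(int(lo), int(hi) + 1, dtype=float)
        counts = np.bincount((flat - int(lo)).astype(np.int64),
                             minlength=values.size).astype(float)
    else:
        counts, edges = np.histogram(flat, bins=256, range=(float(lo), float(hi)))
        counts = counts.astype(float)
        values = 0.5 * (edges[:-1] + edges[1:])
    # candidate thresholds: after bin k, classes are [..k] and [k+1..]
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    m0 = np.cumsum(counts * values)[:-1] / np.where(w0 > 0, w0, 1.0)
    m1 = ((counts * values).sum() - np.cumsum(counts * values)[:-1]) \
        / np.where(w1 > 0, w1, 1.0)
    valid = (w0 > 0) & (w1 > 0)
    between = np.where(valid, w0 * w1 * (m0 - m1) ** 2, -np.inf)
    k = int(np.argmax(between))
    return float(values[k])


def find_clusters(mask: np.ndarray, pixel_size_nm: float,
                  connectivity: int = 8) -> list[Cluster]:
    """Maximal connected components of a boolean mask as clusters."""
    mask = np.asarray(mask, bool)
    if mask.ndim != 2:
        raise ConfigurationError("mask must be 2-D")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ConfigurationError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    out = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        rr, cc = np.nonzero(labels[sl] == lab)
        pixels = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        out.append(Cluster(pixels, pixel_size_nm))
    return out


def threshold_and_find_clusters(image: CalibratedImage,
                                connectivity: int = 8) -> list[Cluster]:
    """Otsu-threshold a channel and return its clusters."""
    return find_clusters(image.data > otsu_threshold(image),
                         image.pixel_size_nm, connectivity)


@dataclass(frozen=True)
class AssociationParams:
    """Association geometry: perinexal region width beyond the Cx43 edge."""

    perinexal_width_nm: float = 200.0

    def __post_init__(self):
        if self.perinexal_width_nm <= 0:
            raise ConfigurationError("perinexal_width_nm must be > 0")


def _partner_hist(counts: np.ndarray) -> dict:
    return {"0": int(np.sum(counts == 0)), "1": int(np.sum(counts == 1)),
            ">=2": int(np.sum(counts >= 2))}


@dataclass
class AssociationReport:
    """Association statistics between Nav1.5 and Cx43 cluster populations."""

    nav_classes: list            # per-Nav1.5 class, CLASSES members
    overlap_partner_counts: np.ndarray    # per-Cx43: # overlapping Nav1.5
    perinexal_partner_counts: np.ndarray  # per-Cx43: # perinexal Nav1.5
    cx43_equivalent_diameters_nm: np.ndarray
    perinexal_width_nm: float

    def __post_init__(self):
        self.overlap_partner_counts = np.asarray(self.overlap_partner_counts, int)
        self.perinexal_partner_counts = np.asarray(self.perinexal_partner_counts, int)
        self.cx43_equivalent_diameters_nm = np.asarray(
            self.cx43_equivalent_diameters_nm, float)
        for c in self.nav_classes:
            if c not in CLASSES:
                raise ConfigurationError(f"unknown class {c!r}")
        n = self.n_cx43
        if (self.perinexal_partner_counts.size != n
                or self.cx43_equivalent_diameters_nm.size != n):
            raise ConfigurationError("per-Cx43 arrays must share one length")

    @property
    def n_nav(self) -> int:
        return len(self.nav_classes)

    @property
    def n_cx43(self) -> int:
        return self.overlap_partner_counts.size

    @property
    def nav_fractions(self) -> dict:
        """Fraction of Nav1.5 clusters per class (NaN when no clusters)."""
        if self.n_nav == 0:
            return {c: float("nan") for c in CLASSES}
        return {c: self.nav_classes.count(c) / self.n_nav for c in CLASSES}

    @property
    def cx43_fraction_with_overlap(self) -> float:
        if self.n_cx43 == 0:
            return float("nan")
        return float(np.mean(self.overlap_partner_counts >= 1))

    @property
    def cx43_fraction_with_perinexal(self) -> float:
        if self.n_cx43 == 0:
            return float("nan")
        return float(np.mean(self.perinexal_partner_counts >= 1))

    @property
    def overlap_partner_histogram(self) -> dict:
        """Cx43 clusters binned by overlapping-partner count (0, 1, >=2)."""
        return _partner_hist(self.overlap_partner_counts)

    @property
    def perinexal_partner_histogram(self) -> dict:
        return _partner_hist(self.perinexal_partner_counts)

    @property
    def median_cx43_equivalent_diameter_nm(self) -> float:
        if self.n_cx43 == 0:
            return float("nan")
        return float(np.median(self.cx43_equivalent_diameters_nm))

    def to_dict(self) -> dict:
        return {
            "perinexal_width_nm": self.perinexal_width_nm,
            "n_nav": self.n_nav,
            "n_cx43": self.n_cx43,
            "nav_classes": list(self.nav_classes),
            "nav_fractions": self.nav_fractions,
            "cx43_fraction_with_overlap": self.cx43_fraction_with_overlap,
            "cx43_fraction_with_perinexal": self.cx43_fraction_with_perinexal,
            "overlap_partner_counts": self.overlap_partner_counts.tolist(),
            "perinexal_partner_counts": self.perinexal_partner_counts.tolist(),
            "overlap_partner_histogram": self.overlap_partner_histogram,
            "perinexal_partner_histogram": self.perinexal_partner_histogram,
            "median_overlap_partner_count":
                float(np.median(self.overlap_partner_counts))
                if self.n_cx43 else float("nan"),
            "std_overlap_partner_count":
                float(np.std(self.overlap_partner_counts))
                if self.n_cx43 else float("nan"),
            "median_perinexal_partner_count":
                float(np.median(self.perinexal_partner_counts))
                if self.n_cx43 else float("nan"),
            "std_perinexal_partner_count":
                float(np.std(self.perinexal_partner_counts))
                if self.n_cx43 else float("nan"),
            "cx43_equivalent_diameters_nm":
                self.cx43_equivalent_diameters_nm.tolist(),
            "median_cx43_equivalent_diameter_nm":
                self.median_cx43_equivalent_diameter_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationReport":
        return cls(nav_classes=list(d["nav_classes"]),
                   overlap_partner_counts=d["overlap_partner_counts"],
                   perinexal_partner_counts=d["perinexal_partner_counts"],
                   cx43_equivalent_diameters_nm=d["cx43_equivalent_diameters_nm"],
                   perinexal_width_nm=d["perinexal_width_nm"])


def edge_distance_nm(mask_a: np.ndarray, mask_b: np.ndarray,
                     pixel_size_nm: float) -> float:
    """Edge-to-edge distance between two masks, (min EDT - 1 px) * size.

    0 when boundary pixels are adjacent, negative values are clipped to 0,
    and overlap also yields 0.
    """
    if not (mask_a.any() and mask_b.any()):
        raise ConfigurationError("both masks must be non-empty")
    edt = ndimage.distance_transform_edt(~np.asarray(mask_a, bool))
    d = edt[np.asarray(mask_b, bool)].min()
    return max(0.0, (float(d) - 1.0) * pixel_size_nm)


def associate(cx43: list[Cluster], nav: list[Cluster],
              params: AssociationParams = AssociationParams()) -> AssociationReport:
    """Classify every Nav1.5 cluster against the Cx43 population.

    Both cluster lists must come from images of identical pixel size.
    A Nav1.5 cluster's class is its best relation over all Cx43 clusters
    (overlap > perinexal > distal); partner counts are tallied
    independently per Cx43 cluster.
    """
    sizes = {c.pixel_size_nm for c in cx43} | {c.pixel_size_nm for c in nav}
    if len(sizes) > 1:
        raise ConfigurationError(
            f"calibration mismatch between cluster lists: {sorted(sizes)}")
    pixel_size = sizes.pop() if sizes else 1.0

    report_empty = AssociationReport(
        nav_classes=[DISTAL] * len(nav) if not cx43 else [],
        overlap_partner_counts=np.zeros(len(cx43), int),
        perinexal_partner_counts=np.zeros(len(cx43), int),
        cx43_equivalent_diameters_nm=[c.equivalent_diameter_nm for c in cx43],
        perinexal_width_nm=params.perinexal_width_nm)
    if not cx43 or not nav:
        return report_empty

    pad = int(np.ceil(params.perinexal_width_nm / pixel_size)) + 2
    # index Nav pixels once for bounding-box lookups
    nav_pix = [c.pixels for c in nav]
    nav_bbox = np.array([c.bbox for c in nav])  # (n, 4)

    best = np.full(len(nav), 2, int)  # 0 overlap, 1 perinexal, 2 distal
    overlap_counts = np.zeros(len(cx43), int)
    perinexal_counts = np.zeros(len(cx43), int)

    for i, cx in enumerate(cx43):
        rmin, rmax, cmin, cmax = cx.bbox
        r0, c0 = rmin - pad, cmin - pad
        box = np.zeros((rmax - rmin + 1 + 2 * pad,
                        cmax - cmin + 1 + 2 * pad), bool)
        box[cx.pixels[:, 0] - r0, cx.pixels[:, 1] - c0] = True
        edt = ndimage.distance_transform_edt(~box)
        # Nav clusters whose bbox intersects the padded box can be partners
        near = ~((nav_bbox[:, 1] < r0) | (nav_bbox[:, 0] > rmax + pad)
                 | (nav_bbox[:, 3] < c0) | (nav_bbox[:, 2] > cmax + pad))
        for j in np.flatnonzero(near):
            p = nav_pix[j]
            inside = ((p[:, 0] >= r0) & (p[:, 0] < r0 + box.shape[0])
                      & (p[:, 1] >= c0) & (p[:, 1] < c0 + box.shape[1]))
            if not inside.any():
                continue
            d = edt[p[inside, 0] - r0, p[inside, 1] - c0].min()
            if d == 0.0:
                overlap_counts[i] += 1
                best[j] = min(best[j], 0)
            elif (d - 1.0) * pixel_size <= params.perinexal_width_nm:
                perinexal_counts[i] += 1
                best[j] = min(best[j], 1)
    return AssociationReport(
        nav_classes=[CLASSES[b] for b in best],
        overlap_partner_counts=overlap_counts,
        perinexal_partner_counts=perinexal_counts,
        cx43_equivalent_diameters_nm=[c.equivalent_diameter_nm for c in cx43],
        perinexal_width_nm=params.perinexal_width_nm)


def analyze_images(cx43_image: CalibratedImage, nav_image: CalibratedImage,
                   params: AssociationParams = AssociationParams(),
                   connectivity: int = 8) -> AssociationReport:
    """Full pipeline: Otsu threshold both channels, cluster, associate."""
    if cx43_image.pixel_size_nm != nav_image.pixel_size_nm:
        raise ConfigurationError("channel calibrations differ")
    return associate(threshold_and_find_clusters(cx43_image, connectivity),
                     threshold_and_find_clusters(nav_image, connectivity),
                     params)


def summarize(report: AssociationReport) -> pd.DataFrame:
    """Tidy one-row-per-statistic table of the report."""
    d = report.to_dict()
    rows = [("n_nav_clusters", d["n_nav"]),
            ("n_cx43_clusters", d["n_cx43"])]
    rows += [(f"nav_fraction_{c}", d["nav_fractions"][c]) for c in CLASSES]
    rows += [("cx43_fraction_with_overlap", d["cx43_fraction_with_overlap"]),
             ("cx43_fraction_with_perinexal", d["cx43_fraction_with_perinexal"])]
    for rel in ("overlap", "perinexal"):
        hist = d[f"{rel}_partner_histogram"]
        rows += [(f"cx43_{rel}_partners_{b}", hist[b]) for b in ("0", "1", ">=2")]
        rows += [(f"median_{rel}_partner_count", d[f"median_{rel}_partner_count"]),
                 (f"std_{rel}_partner_count", d[f"std_{rel}_partner_count"])]
    rows.append(("median_cx43_equivalent_diameter_nm",
                 d["median_cx43_equivalent_diameter_nm"]))
    return pd.DataFrame(rows, columns=["statistic", "value"])
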