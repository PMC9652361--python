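"""Organism-level morphometry for zebrafish embryo phenotyping.

Covers the measurements scored on embryo images and annotations:

* notochord bend angles from an ordered trace, their severity classes
  (180°: normal; 179°–110°: mild; ≤109°: severe) and circular statistics
  (mean vector µ, resultant length R, circular SD = sqrt(−2 ln R));
* axis measurements — anterior–posterior length, convergence–extension index
  (AP / mediolateral), head area, the angle between the A–P ends, atrioventricular
  canal widths and spindle dimensions — from landmark coordinates;
* spot counting (acridine-orange-positive dying cells) by local-maximum
  detection with non-maximum suppression;
* mitotic-phase scoring (early / metaphase / late) from the shape of the
  phospho-histone-H3 mask of a single cell;
* the morpholino worsening index: percent severely affected embryos with the
  morpholino divided by the same percent without it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.measure import regionprops, label as sk_label
from shapely.geometry import LineString

from .errors import GeometryError, ParameterError

__all__ = [
    "BendClass",
    "MitoticPhase",
    "CircularStats",
    "WorseningIndex",
    "notochord_angles",
    "classify_bend",
    "circular_stats",
    "ce_index",
    "worsening_index",
    "polygon_area",
    "measure_polyline",
    "angle_between_ends",
    "spindle_dimensions",
    "count_ao_spots",
    "classify_mitotic_phase",
]


class BendClass(str, Enum):
    NORMAL = "normal"
    MILD = "mild"
    SEVERE = "severe"


class MitoticPhase(str, Enum):
    EARLY = "early"
    METAPHASE = "metaphase"
    LATE = "late"


def _interior_angle(p_prev, p, p_next) -> float:
    u = np.asarray(p_prev, dtype=float) - np.asarray(p, dtype=float)
    v = np.asarray(p_next, dtype=float) - np.asarray(p, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("duplicated consecutive vertices")
    # atan2 form: well conditioned near 0° and 180°, unlike acos
    cross = abs(u[0] * v[1] - u[1] * v[0])
    dot = float(np.dot(u, v))
    ang = math.degrees(math.atan2(cross, dot))
    return 180.0 if ang == 0 else ang  # a 0° fold cannot arise from distinct pts


def notochord_angles(trace: np.ndarray) -> list[float]:
    """Interior angle (degrees, in (0, 180]) at every non-terminal vertex."""
    pts = np.asarray(trace, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("a trace needs at least 3 (x, y) vertices")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise GeometryError("duplicated consecutive vertices in trace")
    return [_interior_angle(pts[i - 1], pts[i], pts[i + 1]) for i in range(1, len(pts) - 1)]


def classify_bend(angle: float) -> BendClass:
    """Severity class of one bend angle.

    Printed boundaries: 180° normal, 179°–110° mild, ≤109° severe.  The
    fractional gaps the integer boundaries leave — (179°, 180°) and
    (109°, 110°) — close upward (toward the less severe class), so
    measurement noise near a boundary never inflates severity.
    """
    if not 0 < angle <= 180:
        raise GeometryError(f"bend angle must lie in (0, 180], got {angle}")
    if angle > 179:
        return BendClass.NORMAL
    if angle > 109:
        return BendClass.MILD
    return BendClass.SEVERE


@dataclass
class CircularStats:
    """Mean direction µ (deg, [0, 360)), resultant length R and circular SD (deg)."""

    mu: float
    r: float
    circ_sd: float
    n: int


def circular_stats(angles_deg, axial: bool = False,
                   sd_formula: str = "ln") -> CircularStats:
    """Circular mean vector and dispersion of a collection of angles.

    R is the length of the mean unit vector, µ its direction, and the
    circular SD is sqrt(−2 ln R) in radians (reported in degrees); the
    angular-deviation alternative sqrt(2 (1 − R)) is available via
    ``sd_formula="angular"``.  With ``axial=True`` angles are doubled before
    averaging and µ halved afterwards, the usual treatment for axial data.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ParameterError("circular_stats needs at least one angle")
    mult = 2.0 if axial else 1.0
    rad = np.deg2rad(a * mult)
    c, s = float(np.mean(np.cos(rad))), float(np.mean(np.sin(rad)))
    r = min(math.hypot(c, s), 1.0)
    mu = math.degrees(math.atan2(s, c)) % 360.0
    if axial:
        mu = (mu / 2.0) % 360.0
    if sd_formula == "ln":
        sd_rad = math.sqrt(-2.0 * math.log(r)) if r > 0 else float("inf")
    elif sd_formula == "angular":
        sd_rad = math.sqrt(2.0 * (1.0 - r))
    else:
        raise ParameterError(f"unknown sd_formula {sd_formula!r}")
    return CircularStats(mu=mu, r=r, circ_sd=math.degrees(sd_rad), n=int(a.size))


def ce_index(ap_length: float, ml_length: float) -> float:
    """Convergence–extension index: anterior–posterior / mediolateral extent."""
    if ml_length <= 0:
        raise GeometryError(f"ml_length must be > 0, got {ml_length}")
    if ap_length <= 0:
        raise GeometryError(f"ap_length must be > 0, got {ap_length}")
    return float(ap_length) / float(ml_length)


@dataclass
class WorseningIndex:
    """Fold-change in percent severely affected embryos, +MO over −MO.

    ``ratio`` is the published quantity; ``ratio_minus_1`` and ``log2_ratio``
    are companion transforms that place "no change" at 0 (emitted alongside,
    never replacing the ratio).  NaN marks the undefined zero-denominator case.
    """

    ratio: float
    ratio_minus_1: float
    log2_ratio: float


def worsening_index(pct_severe_plus_mo: float, pct_severe_minus_mo: float) -> WorseningIndex:
    for v in (pct_severe_plus_mo, pct_severe_minus_mo):
        if v < 0 or v > 100:
            raise ParameterError(f"percentages must lie in [0, 100], got {v}")
    if pct_severe_minus_mo == 0:
        nan = float("nan")
        return WorseningIndex(ratio=nan, ratio_minus_1=nan, log2_ratio=nan)
    ratio = pct_severe_plus_mo / pct_severe_minus_mo
    log2 = math.log2(ratio) if ratio > 0 else float("-inf")
    return WorseningIndex(ratio=ratio, ratio_minus_1=ratio - 1.0, log2_ratio=log2)


def polygon_area(points) -> float:
    """Shoelace area of a closed polygon (absolute value).

    Self-intersecting outlines trigger a warning; the absolute shoelace
    value is still returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("a polygon needs at least 3 (x, y) points")
    ring = np.vstack([pts, pts[:1]])
    if not LineString(ring).is_simple:
        warnings.warn("self-intersecting polygon; returning absolute shoelace area",
                      stacklevel=2)
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def measure_polyline(points) -> float:
    """Total Euclidean length of an ordered polyline."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise GeometryError("a polyline needs at least 2 (x, y) points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def angle_between_ends(head_pt, pivot_pt, tail_pt) -> float:
    """Angle amplitude (degrees) between the A–P ends as seen from a pivot."""
    return _interior_angle(head_pt, pivot_pt, tail_pt)


def spindle_dimensions(axis_endpoints, width_endpoints) -> tuple[float, float, float]:
    """(length, width, aspect = length/width) of a mitotic spindle."""
    length = measure_polyline(axis_endpoints)
    width = measure_polyline(width_endpoints)
    if width <= 0 or length <= 0:
        raise GeometryError("spindle length and width must be > 0")
    return length, width, length / width


def count_ao_spots(image: np.ndarray, min_separation: float = 10.0,
                   threshold_policy: tuple = ("rel", 0.5),
                   smooth_sigma: float = 1.0) -> int:
    """Count bright spots as local maxima with non-maximum suppression.

    The image is optionally Gaussian-smoothed (``smooth_sigma``) before peak
    detection; ``threshold_policy`` is ``("rel", f)`` for a threshold at
    fraction f of the smoothed maximum, or ``("abs", v)`` for an absolute
    threshold in smoothed-intensity units.  Maxima closer than
    ``min_separation`` are suppressed down to the strongest.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("count_ao_spots expects a 2D image")
    if smooth_sigma > 0:
        img = gaussian_filter(img, smooth_sigma)
    if img.max() <= 0:
        return 0
    kind, val = threshold_policy
    if kind == "rel":
        thr = float(val) * float(img.max())
    elif kind == "abs":
        thr = float(val)
    else:
        raise ParameterError(f"unknown threshold policy {kind!r}")
    peaks = peak_local_max(img, min_distance=max(1, int(round(min_separation))),
                           threshold_abs=thr, exclude_border=False)
    return int(len(peaks))


def classify_mitotic_phase(mask: np.ndarray, size_ratio_min: float = 0.5,
                           anisotropy_min: float = 2.5) -> MitoticPhase:
    """Mitotic phase from the shape of a single cell's pH3-positive mask.

    Two separated components of comparable size (smaller/larger area ratio
    ≥ ``size_ratio_min``) read as late mitosis (ana/telophase); a single
    strongly anisotropic component (major/minor axis ratio ≥
    ``anisotropy_min``) as a metaphase plate; anything else as early
    (prophase/prometaphase).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty pH3 mask: no positive pixels")
    labels = sk_label(mask)
    props = sorted(regionprops(labels), key=lambda p: p.area, reverse=True)
    if len(props) >= 2 and props[1].area / props[0].area >= size_ratio_min:
        return MitoticPhase.LATE
    big = props[0]
    minor = big.axis_minor_length
    anisotropy = big.axis_major_length / minor if minor > 0 else float("inf")
    if anisotropy >= anisotropy_min:
        return MitoticPhase.METAPHASE
    return MitoticPhase.EARLY
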