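"""Thresholded Manders colocalization coefficients within a ROI.

M1 is the fraction of channel-A above-threshold integrated signal that lies
on channel-B above-threshold pixels; M2 swaps the roles:

    M1 = sum(A over {A > tA and B > tB} ∩ ROI) / sum(A over {A > tA} ∩ ROI)

Positivity is strict (> threshold); a pixel exactly at threshold is
negative.  Thresholds default to Otsu computed from pixels inside the ROI,
applied identically to every condition; fixed thresholds are accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ThresholdError

__all__ = ["ColocResult", "auto_threshold", "manders", "manders_auto"]


@dataclass
class ColocResult:
    """M1/M2 with the thresholds that produced them; NaN marks an undefined
    coefficient (no positive pixels of that channel in the ROI)."""

    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    roi_id: str = ""

    @property
    def m1_defined(self) -> bool:
        return not math.isnan(self.m1)

    @property
    def m2_defined(self) -> bool:
        return not math.isnan(self.m2)


def auto_threshold(channel: np.ndarray, roi: np.ndarray | None = None,
                   method: str = "otsu", value: float | None = None) -> float:
    """Scalar threshold for one channel from pixels inside the ROI only."""
    channel = np.asarray(channel, dtype=float)
    if roi is None:
        roi = np.ones(channel.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ThresholdError("ROI is empty")
    if method == "fixed":
        if value is None:
            raise ThresholdError("fixed method requires a threshold value")
        return float(value)
    if method != "otsu":
        raise ThresholdError(f"unknown thresholding method {method!r}")
    vals = channel[roi]
    if np.ptp(vals) == 0:
        raise ThresholdError("cannot threshold a constant channel (no separable classes)")
    return float(threshold_otsu(vals))


def manders(ch_a: np.ndarray, ch_b: np.ndarray, t_a: float, t_b: float,
            roi: np.ndarray | None = None, roi_id: str = "") -> ColocResult:
    """Thresholded Manders coefficients of two equal-shape channels in a ROI."""
    ch_a = np.asarray(ch_a, dtype=float)
    ch_b = np.asarray(ch_b, dtype=float)
    if ch_a.shape != ch_b.shape:
        raise ValueError(f"channel shapes differ: {ch_a.shape} vs {ch_b.shape}")
    if roi is None:
        roi = np.ones(ch_a.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != ch_a.shape:
        raise ValueError("ROI shape must match the channels")
    pos_a = (ch_a > t_a) & roi
    pos_b = (ch_b > t_b) & roi
    both = pos_a & pos_b
    sum_a = float(ch_a[pos_a].sum())
    sum_b = float(ch_b[pos_b].sum())
    m1 = float(ch_a[both].sum() / sum_a) if sum_a > 0 else float("nan")
    m2 = float(ch_b[both].sum() / sum_b) if sum_b > 0 else float("nan")
    return ColocResult(m1=m1, m2=m2, threshold_a=float(t_a),
                       threshold_b=float(t_b), roi_id=roi_id)


def manders_auto(ch_a: np.ndarray, ch_b: np.ndarray,
                 roi: np.ndarray | None = None, method: str = "otsu",
                 roi_id: str = "") -> ColocResult:
    """Manders coefficients with per-channel automatic thresholds in the ROI."""
    t_a = auto_threshold(ch_a, roi, method=method)
    t_b = auto_threshold(ch_b, roi, method=method)
    return manders(ch_a, ch_b, t_a, t_b, roi, roi_id=roi_id)
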