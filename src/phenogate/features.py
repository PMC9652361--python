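"""Per-cell segmentation and the features the classification gates consume.

Segmentation is intentionally simple and fully automatic: the cell is the
largest connected above-threshold component of the transfection-marker
channel, the nucleus the largest above-threshold component of the nucleus
channel inside the cell, and each organelle mask the above-threshold pixels
of its channel inside the cell.  Thresholds default to Otsu computed within
the relevant region; fixed per-channel thresholds can be supplied instead.

Features
--------
GolgiFeatures
    A — Golgi-positive area as percent of the whole-cell area,
    ``100 * |golgi mask| / |cell mask|``.
    MI — mean intensity of the Golgi-positive pixels, normalized per config.
    The default ``reference`` mode divides by a fixed arbitrary-units scale
    (``reference_intensity``), appropriate when acquisition settings are held
    constant across conditions so intensities are comparable; ``cell`` mode
    divides by the mean of the Golgi channel over the whole cell and ``raw``
    applies no normalization.  Note that in ``cell`` mode MI cannot fall
    below 1 when the Golgi-positive pixels are the bright class, so gates
    below 1 require ``reference`` (or ``raw``) normalization.
CopiFeatures
    COP-I area / nucleus area ratio, the connected-object count, and a
    perinuclear-clustering flag (largest object's centroid within a small
    dilation of the nucleus).
TfnFeatures
    Fraction of Tfn-positive integrated signal inside a perinuclear ROI,
    plus cluster statistics of the Tfn-positive mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import binary_dilation, disk

from .errors import SegmentationError, ThresholdError
from .stack import ImageStack

__all__ = [
    "DEFAULT_REFERENCE_INTENSITY",
    "SegmentationConfig",
    "CellSegmentation",
    "GolgiFeatures",
    "CopiFeatures",
    "TfnFeatures",
    "segment_cell",
    "golgi_features",
    "copi_features",
    "tfn_features",
    "perinuclear_roi",
]

# Arbitrary-units intensity scale: 100 counts == MI 1.0.  The synthetic
# generator renders Golgi amplitudes on this scale, so generated and measured
# MI agree; for real data the scale is a per-experiment calibration choice.
DEFAULT_REFERENCE_INTENSITY = 100.0


@dataclass
class SegmentationConfig:
    marker_channel: str = "marker"
    nucleus_channel: str = "nucleus"
    organelle_channels: dict[str, str] = field(default_factory=lambda: {"golgi": "golgi"})
    threshold_method: str = "otsu"  # or "fixed"
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    mi_normalization: str = "reference"  # reference | cell | raw
    reference_intensity: float = DEFAULT_REFERENCE_INTENSITY
    pn_dilation_px: int = 5
    pn_roi_width_px: int = 15

    def threshold(self, channel_name: str, values: np.ndarray) -> float:
        if self.threshold_method == "fixed" or channel_name in self.fixed_thresholds:
            try:
                return float(self.fixed_thresholds[channel_name])
            except KeyError:
                raise ThresholdError(
                    f"no fixed threshold configured for channel {channel_name!r}"
                ) from None
        if values.size == 0 or np.ptp(values) == 0:
            raise ThresholdError(
                f"cannot threshold channel {channel_name!r}: constant intensities"
            )
        return float(threshold_otsu(values))


@dataclass
class CellSegmentation:
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    organelle_masks: dict[str, np.ndarray]
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cell_mask.any():
            raise SegmentationError("cell mask is empty")
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise SegmentationError("nucleus mask escapes the cell mask")
        for name, mask in self.organelle_masks.items():
            if (mask & ~self.cell_mask).any():
                raise SegmentationError(f"organelle mask {name!r} escapes the cell mask")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_cell(stack: ImageStack, config: SegmentationConfig | None = None) -> CellSegmentation:
    """Segment cell, nucleus and organelle masks from a multichannel stack."""
    config = config or SegmentationConfig()
    marker = stack[config.marker_channel]
    if not np.any(marker > 0):
        raise SegmentationError(
            f"marker channel {config.marker_channel!r} has no positive signal"
        )
    thresholds: dict[str, float] = {}
    t_marker = config.threshold(config.marker_channel, marker.ravel())
    thresholds[config.marker_channel] = t_marker
    cell = _largest_component(marker > t_marker)
    if not cell.any():
        raise SegmentationError(
            f"empty cell mask from channel {config.marker_channel!r}"
        )

    nuc_ch = stack[config.nucleus_channel]
    t_nuc = config.threshold(config.nucleus_channel, nuc_ch.ravel())
    thresholds[config.nucleus_channel] = t_nuc
    nucleus = _largest_component(nuc_ch > t_nuc) & cell
    if not nucleus.any():
        raise SegmentationError(
            f"nucleus (channel {config.nucleus_channel!r}) not found inside the cell"
        )

    organelles = {}
    for name, ch_name in config.organelle_channels.items():
        ch = stack[ch_name]
        try:
            t = config.threshold(ch_name, ch[cell])
        except ThresholdError:
            if np.ptp(ch[cell]) == 0:  # uniformly blank channel -> empty mask
                organelles[name] = np.zeros_like(cell)
                thresholds[ch_name] = float("inf")
                continue
            raise
        thresholds[ch_name] = t
        organelles[name] = (ch > t) & cell
    return CellSegmentation(cell_mask=cell, nucleus_mask=nucleus,
                            organelle_masks=organelles, thresholds=thresholds)


@dataclass
class GolgiFeatures:
    """The gated (A, MI) pair; MI is NaN when the Golgi mask is empty."""

    a: float
    mi: float

    @property
    def mi_defined(self) -> bool:
        return not np.isnan(self.mi)


def golgi_features(seg: CellSegmentation, golgi_channel: np.ndarray,
                   config: SegmentationConfig | None = None,
                   mask_name: str = "golgi") -> GolgiFeatures:
    """Compute (A, MI) for one cell from its segmentation and Golgi channel."""
    config = config or SegmentationConfig()
    cell = seg.cell_mask
    golgi = seg.organelle_masks[mask_name]
    a = 100.0 * golgi.sum() / cell.sum()
    if not golgi.any():
        return GolgiFeatures(a=float(a), mi=float("nan"))
    mean_in = float(golgi_channel[golgi].mean())
    mode = config.mi_normalization
    if mode == "reference":
        mi = mean_in / config.reference_intensity
    elif mode == "cell":
        mi = mean_in / float(golgi_channel[cell].mean())
    elif mode == "raw":
        mi = mean_in
    else:
        raise ValueError(f"unknown mi_normalization {mode!r}")
    return GolgiFeatures(a=float(a), mi=float(mi))


@dataclass
class CopiFeatures:
    area_ratio: float
    n_components: int
    pn_clustered: bool


def copi_features(seg: CellSegmentation, copi_channel: np.ndarray | None = None,
                  config: SegmentationConfig | None = None,
                  mask_name: str = "copi") -> CopiFeatures:
    """COP-I area ratio, object count and perinuclear-clustering flag."""
    config = config or SegmentationConfig()
    if not seg.nucleus_mask.any():
        raise SegmentationError("COP-I area ratio undefined: empty nucleus mask")
    copi = seg.organelle_masks[mask_name]
    ratio = float(copi.sum() / seg.nucleus_mask.sum())
    labels, n = ndimage.label(copi)
    if n == 0:
        return CopiFeatures(area_ratio=0.0, n_components=0, pn_clustered=False)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    biggest = 1 + int(np.argmax(sizes))
    centroid = ndimage.center_of_mass(labels == biggest)
    near_nucleus = binary_dilation(seg.nucleus_mask, disk(config.pn_dilation_px))
    r, c = (int(round(centroid[0])), int(round(centroid[1])))
    r = min(max(r, 0), copi.shape[0] - 1)
    c = min(max(c, 0), copi.shape[1] - 1)
    return CopiFeatures(area_ratio=ratio, n_components=int(n),
                        pn_clustered=bool(near_nucleus[r, c]))


@dataclass
class TfnFeatures:
    pn_fraction: float
    n_clusters: int
    largest_cluster_fraction: float
    empty: bool = False


def perinuclear_roi(seg: CellSegmentation, width: int | None = None,
                    config: SegmentationConfig | None = None) -> np.ndarray:
    """Default PN ROI: an annulus of the given width around the nucleus, in-cell."""
    config = config or SegmentationConfig()
    width = config.pn_roi_width_px if width is None else width
    ring = binary_dilation(seg.nucleus_mask, disk(width)) & ~seg.nucleus_mask
    return ring & seg.cell_mask


def tfn_features(seg: CellSegmentation, tfn_channel: np.ndarray,
                 pn_roi: np.ndarray | None = None,
                 config: SegmentationConfig | None = None,
                 mask_name: str = "tfn") -> TfnFeatures:
    """Perinuclear fraction of Tfn-positive signal plus cluster statistics."""
    config = config or SegmentationConfig()
    if pn_roi is None:
        pn_roi = perinuclear_roi(seg, config=config)
    if (pn_roi & ~seg.cell_mask).any():
        raise SegmentationError("PN ROI must lie inside the cell mask")
    tfn = seg.organelle_masks[mask_name]
    if not tfn.any():
        return TfnFeatures(pn_fraction=0.0, n_clusters=0,
                           largest_cluster_fraction=0.0, empty=True)
    total = float(tfn_channel[tfn].sum())
    inside = float(tfn_channel[tfn & pn_roi].sum())
    labels, n = ndimage.label(tfn)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return TfnFeatures(
        pn_fraction=inside / total,
        n_clusters=int(n),
        largest_cluster_fraction=float(sizes.max() / tfn.sum()),
    )
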