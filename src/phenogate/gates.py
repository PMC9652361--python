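"""Classification gates for organelle morphotypes and their tabulation.

The central classifier places each cell in (A, MI) feature space, where
A is the Golgi-positive area as a percentage of the whole-cell area and MI
is the normalized Golgi mean intensity, and assigns one of four morphotypes
by rectangular gates:

* compact:              A < 2.6  and MI > 1.5
* expanded:             2.7 < A < 12 and MI > 0.8
* partially dispersed:  2.7 < A < 12 and MI < 0.8
* totally dispersed:    A > 12   and MI < 0.8

The strict inequalities are applied exactly as written, which leaves gaps
(e.g. A in [2.6, 2.7], MI exactly 0.8, low-A/low-MI cells).  The default
boundary policy labels such cells ``unclassified`` rather than silently
reassigning them; a nearest-gate policy is available for robustness studies.

Companion classifiers cover the COP-I compartment (compact/expanded/diffused
by the COP-I area / nucleus area ratio with a 0.25 cut), transferrin
distribution (clustered/semi-clustered/dispersed) and the in-vivo GalT signal
(ribbon vs puncta).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "GateConfig",
    "Morphotype",
    "CopiClass",
    "TfnClass",
    "GaltClass",
    "classify_golgi_morphotype",
    "classify_copi",
    "classify_tfn",
    "classify_galt_invivo",
    "tabulate_classes",
    "ClassCountTable",
]


class Morphotype(str, Enum):
    COMPACT = "compact"
    EXPANDED = "expanded"
    PARTIALLY_DISPERSED = "partially_dispersed"
    TOTALLY_DISPERSED = "totally_dispersed"
    UNCLASSIFIED = "unclassified"


class CopiClass(str, Enum):
    COMPACT = "compact"
    EXPANDED = "expanded"
    DIFFUSED = "diffused"


class TfnClass(str, Enum):
    CLUSTERED = "clustered"
    SEMI_CLUSTERED = "semi_clustered"
    DISPERSED = "dispersed"


class GaltClass(str, Enum):
    RIBBON = "ribbon"
    PUNCTA = "puncta"


@dataclass(frozen=True)
class GateConfig:
    """Every classification threshold of the pipeline, as configuration.

    The Golgi (A, MI) gate values and the COP-I ratio cut are the published
    ones; the transferrin cuts and the ribbon dominance cut operationalize
    scoring that was originally done by eye and are therefore package
    defaults, echoed into every output.
    """

    a_compact_max: float = 2.6
    a_mid_lo: float = 2.7
    a_mid_hi: float = 12.0
    mi_compact_min: float = 1.5
    mi_mid: float = 0.8
    copi_ratio_cut: float = 0.25
    tfn_clustered_min: float = 0.5
    tfn_dispersed_max_cluster: float = 0.05
    ribbon_dominance_min: float = 0.5
    ribbon_elongation_min: float = 2.0
    boundary_policy: str = "unclassified"  # or "nearest"

    def __post_init__(self) -> None:
        if not (self.a_compact_max <= self.a_mid_lo < self.a_mid_hi):
            raise ParameterError("require a_compact_max <= a_mid_lo < a_mid_hi")
        if not (0 < self.mi_mid < self.mi_compact_min):
            raise ParameterError("require 0 < mi_mid < mi_compact_min")
        for name in ("copi_ratio_cut", "tfn_clustered_min",
                     "tfn_dispersed_max_cluster", "ribbon_dominance_min"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.boundary_policy not in ("unclassified", "nearest"):
            raise ParameterError("boundary_policy must be 'unclassified' or 'nearest'")

    def to_dict(self) -> dict:
        return asdict(self)

    # (A lo, A hi, MI lo, MI hi) open rectangles; None = unbounded side.
    def gate_rectangles(self) -> dict[Morphotype, tuple]:
        g = self
        return {
            Morphotype.COMPACT: (None, g.a_compact_max, g.mi_compact_min, None),
            Morphotype.EXPANDED: (g.a_mid_lo, g.a_mid_hi, g.mi_mid, None),
            Morphotype.PARTIALLY_DISPERSED: (g.a_mid_lo, g.a_mid_hi, None, g.mi_mid),
            Morphotype.TOTALLY_DISPERSED: (g.a_mid_hi, None, None, g.mi_mid),
        }


def _in_gate(a: float, mi: float, rect: tuple) -> bool:
    lo, hi, mlo, mhi = rect
    return ((lo is None or a > lo) and (hi is None or a < hi)
            and (mlo is None or mi > mlo) and (mhi is None or mi < mhi))


def _rect_distance(a: float, mi: float, rect: tuple, a_scale: float, mi_scale: float) -> float:
    """Scaled Euclidean distance from (a, mi) to the closure of an open gate."""
    lo, hi, mlo, mhi = rect
    da = 0.0
    if lo is not None and a < lo:
        da = (lo - a) / a_scale
    elif hi is not None and a > hi:
        da = (a - hi) / a_scale
    dm = 0.0
    if mlo is not None and mi < mlo:
        dm = (mlo - mi) / mi_scale
    elif mhi is not None and mi > mhi:
        dm = (mi - mhi) / mi_scale
    return math.hypot(da, dm)


def classify_golgi_morphotype(a: float, mi: float, config: GateConfig | None = None) -> Morphotype:
    """Assign the Golgi morphotype for one cell from its (A, MI) pair.

    ``mi`` may be NaN (the undefined-MI sentinel from an empty Golgi mask),
    in which case the cell is unclassified under either boundary policy.
    """
    config = config or GateConfig()
    a = float(a)
    mi = float(mi)
    if not math.isfinite(a):
        raise ParameterError(f"A must be finite, got {a}")
    if math.isnan(mi):
        return Morphotype.UNCLASSIFIED
    rects = config.gate_rectangles()
    hits = [label for label, rect in rects.items() if _in_gate(a, mi, rect)]
    if len(hits) > 1:  # impossible with a valid config; guard anyway
        raise ParameterError(f"gates overlap at (A={a}, MI={mi}): {hits}")
    if hits:
        return hits[0]
    if config.boundary_policy == "nearest":
        # Scale each axis by its outermost finite gate value so the two
        # dimensionally different axes contribute comparably.
        a_scale, mi_scale = config.a_mid_hi, config.mi_compact_min
        return min(rects, key=lambda lb: _rect_distance(a, mi, rects[lb], a_scale, mi_scale))
    return Morphotype.UNCLASSIFIED


def classify_copi(area_ratio: float, pn_clustered: bool,
                  config: GateConfig | None = None) -> CopiClass:
    """COP-I compartment class from the area ratio and perinuclear clustering.

    Diffused when no clustered signal sits at the perinuclear region;
    otherwise compact when COP-I area / nucleus area <= 0.25 and expanded
    when the ratio exceeds 0.25.
    """
    config = config or GateConfig()
    if not math.isfinite(area_ratio) or area_ratio < 0:
        raise ParameterError(f"area_ratio must be finite and >= 0, got {area_ratio}")
    if not pn_clustered:
        return CopiClass.DIFFUSED
    return CopiClass.COMPACT if area_ratio <= config.copi_ratio_cut else CopiClass.EXPANDED


def classify_tfn(pn_fraction: float, largest_cluster_fraction: float,
                 config: GateConfig | None = None, *, empty: bool = False) -> TfnClass:
    """Transferrin distribution class.

    Clustered when the perinuclear fraction of Tfn-positive signal reaches
    ``tfn_clustered_min``; dispersed when no single cluster holds at least
    ``tfn_dispersed_max_cluster`` of the Tfn-positive area; else
    semi-clustered.  A cell with no Tfn-positive signal is dispersed.
    """
    config = config or GateConfig()
    if empty:
        return TfnClass.DISPERSED
    for v in (pn_fraction, largest_cluster_fraction):
        if not math.isfinite(v) or not 0 <= v <= 1:
            raise ParameterError(f"fractions must lie in [0,1], got {v}")
    if pn_fraction >= config.tfn_clustered_min:
        return TfnClass.CLUSTERED
    if largest_cluster_fraction < config.tfn_dispersed_max_cluster:
        return TfnClass.DISPERSED
    return TfnClass.SEMI_CLUSTERED


def classify_galt_invivo(n_components: int, largest_fraction: float,
                         largest_elongation: float,
                         largest_adjacent_to_nucleus: bool,
                         config: GateConfig | None = None) -> GaltClass:
    """Ribbon vs puncta call for the in-vivo GalT-positive Golgi signal.

    Ribbon requires a dominant largest object (fraction >= the dominance cut,
    default 0.5, boundary inclusive) that looks ribbon-like: elongated
    (major/minor axis ratio >= 2) or lying against the nucleus.  Everything
    else, including the zero-object case, is puncta.
    """
    config = config or GateConfig()
    if n_components <= 0:
        return GaltClass.PUNCTA
    ribbonish = (largest_elongation >= config.ribbon_elongation_min
                 or largest_adjacent_to_nucleus)
    if largest_fraction >= config.ribbon_dominance_min and ribbonish:
        return GaltClass.RIBBON
    return GaltClass.PUNCTA


@dataclass
class ClassCountTable:
    """Condition x class counts with derived row percentages."""

    counts: pd.DataFrame
    gate_config: GateConfig

    def percentages(self, include_unclassified: bool = True) -> pd.DataFrame:
        counts = self.counts
        if not include_unclassified and Morphotype.UNCLASSIFIED.value in counts.columns:
            counts = counts.drop(columns=[Morphotype.UNCLASSIFIED.value])
        totals = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = counts.div(totals, axis=0) * 100.0
        return pct.fillna(0.0)


def tabulate_classes(labels_by_condition: dict[str, list],
                     config: GateConfig | None = None,
                     class_order: list[str] | None = None) -> ClassCountTable:
    """Tabulate class labels into a condition x class count table.

    ``labels_by_condition`` maps a condition name to the per-cell (or
    per-embryo) labels; enum labels are accepted and stored by value.  An
    empty condition yields an all-zero row.
    """
    config = config or GateConfig()
    norm = {
        cond: [lab.value if isinstance(lab, Enum) else str(lab) for lab in labels]
        for cond, labels in labels_by_condition.items()
    }
    if class_order is None:
        seen: list[str] = []
        for labels in norm.values():
            for lab in labels:
                if lab not in seen:
                    seen.append(lab)
        class_order = seen
    rows = {}
    for cond, labels in norm.items():
        rows[cond] = {c: labels.count(c) for c in class_order}
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=class_order).fillna(0).astype(int)
    return ClassCountTable(counts=counts, gate_config=config)
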