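"""Seeded, ground-truthed synthetic micrographs and traces.

Every generator here is a pure function of a spec (which includes the seed):
identical spec twice gives bit-identical output.  The generators emulate the
structures the analysis stages assume —

* single transfected cells with a compact, expanded, partially dispersed or
  totally dispersed Golgi signal, built to hit a target (A, MI) feature pair
  exactly on the ground-truth masks before blur and noise are applied;
* channel pairs with a prescribed thresholded-Manders overlap (M1, M2);
* notochord polylines with prescribed interior bend angles;
* spot fields with a known number of well-separated Gaussian spots.

Shapes are deliberately simple: ribbons are crescents grown against the
nucleus, puncta are disks.  Noise is additive Gaussian on a zero background,
clipped at zero; the point-spread function is an isotropic Gaussian blur.
Realistic optics (Poisson shot noise, spectral bleed-through, 3D) are out of
scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .features import DEFAULT_REFERENCE_INTENSITY
from .gates import GateConfig, Morphotype
from .stack import ImageStack

__all__ = [
    "SyntheticCellSpec",
    "CellGroundTruth",
    "ColocSpec",
    "ColocGroundTruth",
    "NotochordSpec",
    "SpotFieldSpec",
    "generate_cell_image",
    "generate_population",
    "generate_coloc_pair",
    "generate_notochord_trace",
    "generate_spot_image",
    "write_ground_truth_sidecar",
]

MARKER_INTENSITY = 200.0
NUCLEUS_INTENSITY = 180.0

# Finite (A, MI) rectangles inside each printed gate used when sampling
# population targets.  The unbounded gate sides are capped at values a real
# acquisition would show (A <= ~26 % of the cell, MI <= 2.8 reference units).
TARGET_BOXES = {
    Morphotype.COMPACT: ((0.5, 2.6), (1.5, 2.8)),
    Morphotype.EXPANDED: ((2.7, 12.0), (0.8, 2.8)),
    Morphotype.PARTIALLY_DISPERSED: ((2.7, 12.0), (0.1, 0.8)),
    Morphotype.TOTALLY_DISPERSED: ((12.0, 26.0), (0.1, 0.8)),
}

# Number of Golgi objects per morphotype when the spec leaves it unset:
# one perinuclear body for compact/expanded, a handful of mid-size puncta
# for partial dispersal, many small puncta for total dispersal.
DEFAULT_N_OBJECTS = {
    Morphotype.COMPACT: 1,
    Morphotype.EXPANDED: 1,
    Morphotype.PARTIALLY_DISPERSED: 8,
    Morphotype.TOTALLY_DISPERSED: 40,
}


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Recipe for one synthetic transfected cell."""

    morphotype: Morphotype
    target_a: float
    target_mi: float
    image_shape: tuple[int, int] = (256, 256)
    cell_radius: float = 100.0
    nucleus_radius: float = 30.0
    n_golgi_objects: int | None = None
    psf_sigma: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "morphotype", Morphotype(self.morphotype))
        if self.morphotype is Morphotype.UNCLASSIFIED:
            raise ParameterError("cannot generate an 'unclassified' cell")
        if not 0 < self.target_a < 100:
            raise ParameterError(f"target_a must lie in (0, 100), got {self.target_a}")
        if self.target_mi <= 0:
            raise ParameterError(f"target_mi must be > 0, got {self.target_mi}")
        if self.nucleus_radius >= self.cell_radius:
            raise ParameterError("nucleus_radius must be < cell_radius")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ParameterError("noise_sd and psf_sigma must be >= 0")
        r = self.cell_radius
        if 2 * r + 4 > min(self.image_shape):
            raise ParameterError("cell does not fit in image_shape")

    @property
    def n_objects(self) -> int:
        if self.n_golgi_objects is not None:
            return self.n_golgi_objects
        return DEFAULT_N_OBJECTS[self.morphotype]


@dataclass
class CellGroundTruth:
    """What the generator actually drew, before blur and noise."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    golgi_mask: np.ndarray
    true_label: Morphotype
    realized_a: float
    realized_mi: float
    seed: int

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {"cell": self.cell_mask, "nucleus": self.nucleus_mask,
                "golgi": self.golgi_mask}


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _grow_nearest(available: np.ndarray, anchor, n: int) -> np.ndarray:
    """Mask of the n available pixels nearest (Euclidean) to the anchor."""
    idx = np.argwhere(available)
    if len(idx) < n:
        raise ParameterError(
            f"cannot place {n} pixels: only {len(idx)} available"
        )
    d2 = ((idx - np.asarray(anchor, dtype=float)) ** 2).sum(axis=1)
    take = idx[np.argsort(d2, kind="stable")[:n]]
    out = np.zeros(available.shape, dtype=bool)
    out[take[:, 0], take[:, 1]] = True
    return out


def _place_golgi(spec: SyntheticCellSpec, cell, nucleus, nuc_center, rng) -> np.ndarray:
    n_cell = int(cell.sum())
    n_px = int(round(spec.target_a / 100.0 * n_cell))
    if n_px < 1:
        raise ParameterError(
            f"target_a={spec.target_a} yields an empty Golgi mask at this cell size"
        )
    available = cell & ~nucleus
    if int(available.sum()) < n_px:
        raise ParameterError(
            f"target_a={spec.target_a} exceeds the cytoplasmic area of the cell"
        )
    n_obj = max(1, spec.n_objects)
    if spec.morphotype in (Morphotype.COMPACT, Morphotype.EXPANDED) or n_obj == 1:
        # One body grown against the nucleus boundary: crescent/semicircular
        # when small, a larger perinuclear blob as the pixel budget grows.
        theta = rng.uniform(0, 2 * np.pi)
        anchor = (nuc_center[0] + (spec.nucleus_radius + 1) * np.sin(theta),
                  nuc_center[1] + (spec.nucleus_radius + 1) * np.cos(theta))
        return _grow_nearest(available, anchor, n_px)
    # Puncta: near-equal pixel budgets at well-separated random centers.
    budgets = np.full(n_obj, n_px // n_obj)
    budgets[: n_px % n_obj] += 1
    budgets = budgets[budgets > 0]
    radius_est = np.sqrt(budgets.max() / np.pi)
    min_sep = 2 * radius_est + 3
    centers: list[np.ndarray] = []
    coords = np.argwhere(available)
    for _ in range(2000 * len(budgets)):
        if len(centers) == len(budgets):
            break
        cand = coords[rng.integers(len(coords))]
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < len(budgets):
        raise ParameterError(
            f"could not place {len(budgets)} Golgi objects with separation {min_sep:.1f}"
        )
    golgi = np.zeros(cell.shape, dtype=bool)
    for center, budget in zip(centers, budgets):
        blob = _grow_nearest(available & ~golgi, center, int(budget))
        golgi |= blob
    return golgi


def generate_cell_image(spec: SyntheticCellSpec) -> tuple[ImageStack, CellGroundTruth]:
    """Render one synthetic cell as a 3-channel stack plus its ground truth.

    Channels: ``marker`` (transfection marker filling the cell), ``nucleus``
    and ``golgi``.  Ground-truth (A, MI) are realized exactly on the binary
    masks: A from the pixel count, MI from the constant in-mask amplitude
    ``target_mi * DEFAULT_REFERENCE_INTENSITY``, so the sidecar values are
    exact regardless of the blur and noise applied to the rendered image.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    center = (shape[0] / 2.0, shape[1] / 2.0)
    cell = _disk_mask(shape, center, spec.cell_radius)

    max_off = spec.cell_radius - spec.nucleus_radius - 2
    if max_off < 0:
        raise ParameterError("nucleus cannot fit inside the cell")
    off = min(0.35 * spec.cell_radius, max_off)
    theta = rng.uniform(0, 2 * np.pi)
    nuc_center = (center[0] + off * np.sin(theta), center[1] + off * np.cos(theta))
    nucleus = _disk_mask(shape, nuc_center, spec.nucleus_radius)
    if not (nucleus & cell).sum() == nucleus.sum():
        raise ParameterError("nucleus mask escapes the cell mask")

    golgi = _place_golgi(spec, cell, nucleus, nuc_center, rng)

    amplitude = spec.target_mi * DEFAULT_REFERENCE_INTENSITY
    channels = {
        "marker": MARKER_INTENSITY * cell.astype(float),
        "nucleus": NUCLEUS_INTENSITY * nucleus.astype(float),
        "golgi": amplitude * golgi.astype(float),
    }
    if spec.psf_sigma > 0:
        channels = {k: gaussian_filter(v, spec.psf_sigma) for k, v in channels.items()}
    if spec.noise_sd > 0:
        channels = {
            k: np.clip(v + rng.normal(0.0, spec.noise_sd, shape), 0.0, None)
            for k, v in channels.items()
        }

    realized_a = 100.0 * golgi.sum() / cell.sum()
    realized_mi = amplitude / DEFAULT_REFERENCE_INTENSITY
    truth = CellGroundTruth(
        cell_mask=cell, nucleus_mask=nucleus, golgi_mask=golgi,
        true_label=spec.morphotype, realized_a=float(realized_a),
        realized_mi=float(realized_mi), seed=spec.seed,
    )
    stack = ImageStack(channels, meta={"morphotype": spec.morphotype.value,
                                       "seed": spec.seed})
    return stack, truth


def sample_targets(label: Morphotype, n: int, rng, margin: float = 0.2,
                   config: GateConfig | None = None) -> np.ndarray:
    """Draw n (A, MI) targets uniformly inside the label's gate box.

    ``margin`` shrinks the finite sampling box by that fraction of its width
    on every side, keeping targets away from the printed gate boundaries.
    """
    if not 0 <= margin < 0.5:
        raise ParameterError("margin must lie in [0, 0.5)")
    (a_lo, a_hi), (mi_lo, mi_hi) = TARGET_BOXES[Morphotype(label)]
    da, dmi = a_hi - a_lo, mi_hi - mi_lo
    a = rng.uniform(a_lo + margin * da, a_hi - margin * da, size=n)
    mi = rng.uniform(mi_lo + margin * dmi, mi_hi - margin * dmi, size=n)
    return np.column_stack([a, mi])


def generate_population(n_per_class: dict, seed: int, margin: float = 0.2,
                        noise_sd: float = 0.0, noise_frac: float | None = None,
                        psf_sigma: float = 1.0,
                        image_shape: tuple[int, int] = (256, 256),
                        cell_radius: float = 100.0, nucleus_radius: float = 30.0,
                        ) -> list[tuple[ImageStack, CellGroundTruth]]:
    """Generate a deterministic population of cells, per-class counts as given.

    Per-cell (A, MI) targets are drawn uniformly inside each class gate with
    the requested boundary margin; per-cell seeds derive from ``seed``.
    ``noise_frac``, when given, overrides ``noise_sd`` with a per-cell noise
    level expressed as a fraction of that cell's Golgi amplitude
    (``target_mi * DEFAULT_REFERENCE_INTENSITY``).
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    order = [Morphotype(k) for k in n_per_class]
    records = []
    for label in order:
        n = int(n_per_class[label.value if isinstance(label, Morphotype) else label])
        if n < 0:
            raise ParameterError("per-class counts must be >= 0")
        if n == 0:
            continue
        targets = sample_targets(label, n, rng, margin=margin)
        child_seeds = ss.spawn(n)
        for (a, mi), child in zip(targets, child_seeds):
            cell_noise = (noise_frac * float(mi) * DEFAULT_REFERENCE_INTENSITY
                          if noise_frac is not None else noise_sd)
            spec = SyntheticCellSpec(
                morphotype=label, target_a=float(a), target_mi=float(mi),
                image_shape=image_shape, cell_radius=cell_radius,
                nucleus_radius=nucleus_radius, psf_sigma=psf_sigma,
                noise_sd=cell_noise,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            records.append(generate_cell_image(spec))
    return records


# ---------------------------------------------------------------------------
# Colocalization pairs


@dataclass(frozen=True)
class ColocSpec:
    """Recipe for a two-channel pair with prescribed Manders overlap."""

    true_m1: float
    true_m2: float
    n_objects: int = 8
    roi_shape: tuple[int, int] = (128, 128)
    object_radius: float = 5.0
    amplitude: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.true_m1, self.true_m2):
            if not 0 <= v <= 1:
                raise ParameterError(f"Manders targets must lie in [0,1], got {v}")
        if (self.true_m1 == 0) != (self.true_m2 == 0):
            # M1 = 0 means the A+∧B+ overlap carries no signal, which forces
            # M2 = 0 too (and vice versa); mixed zero targets are unreachable.
            raise ParameterError("true_m1 and true_m2 must be zero together")
        if self.n_objects < 0:
            raise ParameterError("n_objects must be >= 0")
        if self.n_objects == 0 and self.true_m1 > 0:
            raise ParameterError("true_m1 > 0 is unreachable with n_objects = 0")


@dataclass
class ColocGroundTruth:
    mask_a: np.ndarray
    mask_b: np.ndarray
    realized_m1: float
    realized_m2: float
    spec: ColocSpec


def _place_disks(shape, n, radius, rng, forbidden=None, max_tries=20000):
    mask = np.zeros(shape, dtype=bool)
    order: list[np.ndarray] = []  # per-object masks, placement order
    margin = int(np.ceil(radius)) + 1
    placed = 0
    for _ in range(max_tries):
        if placed == n:
            break
        c = (rng.integers(margin, shape[0] - margin),
             rng.integers(margin, shape[1] - margin))
        disk = _disk_mask(shape, c, radius)
        clash = mask & disk
        if forbidden is not None:
            clash = clash | (forbidden & disk)
        if not clash.any():
            mask |= disk
            order.append(disk)
            placed += 1
    if placed < n:
        raise ParameterError(f"could not place {n} disks of radius {radius}")
    return mask, order


def generate_coloc_pair(spec: ColocSpec) -> tuple[ImageStack, ColocGroundTruth]:
    """Two channels whose thresholded Manders coefficients hit the targets.

    Both channels are unions of equal-amplitude disks, so M1 reduces to the
    fraction of channel-A pixels that are also B-positive; the overlap pixel
    count is chosen to match ``true_m1`` (and the B-only pixel count to match
    ``true_m2``) up to one pixel.  Exact for identical (M1=M2=1) and fully
    disjoint (M1=M2=0) pairs.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.roi_shape
    if spec.n_objects == 0:
        a = np.zeros(shape, dtype=bool)
        objects = []
    else:
        a, objects = _place_disks(shape, spec.n_objects, spec.object_radius, rng)
    n_a = int(a.sum())

    if spec.n_objects == 0:
        b = np.zeros(shape, dtype=bool)
    elif spec.true_m1 == 1.0 and spec.true_m2 == 1.0:
        b = a.copy()
    elif spec.true_m1 == 0.0:
        b, _ = _place_disks(shape, spec.n_objects, spec.object_radius, rng, forbidden=a)
    else:
        overlap_n = int(round(spec.true_m1 * n_a))
        overlap_n = max(1, min(overlap_n, n_a))
        b = np.zeros(shape, dtype=bool)
        remaining = overlap_n
        for disk in objects:  # whole objects first, then part of the next one
            n_d = int(disk.sum())
            if remaining >= n_d:
                b |= disk
                remaining -= n_d
            elif remaining > 0:
                idx = np.argwhere(disk)
                ctr = idx.mean(axis=0)
                d2 = ((idx - ctr) ** 2).sum(axis=1)
                take = idx[np.argsort(d2, kind="stable")[:remaining]]
                b[take[:, 0], take[:, 1]] = True
                remaining = 0
        n_b_target = int(round(overlap_n / spec.true_m2)) if spec.true_m2 > 0 else overlap_n
        n_b_target = max(n_b_target, overlap_n)
        extra = n_b_target - overlap_n
        if extra > 0:
            free = ~a & ~b
            # carve B-only pixels as disks grown in free space
            placed = 0
            for _ in range(20000):
                if placed >= extra:
                    break
                margin = int(np.ceil(spec.object_radius)) + 1
                c = (rng.integers(margin, shape[0] - margin),
                     rng.integers(margin, shape[1] - margin))
                disk = _disk_mask(shape, c, spec.object_radius) & free
                n_take = min(int(disk.sum()), extra - placed)
                if n_take <= 0:
                    continue
                idx = np.argwhere(disk)
                take = idx[:n_take]
                b[take[:, 0], take[:, 1]] = True
                free[take[:, 0], take[:, 1]] = False
                placed += n_take
            if placed < extra:
                raise ParameterError("could not reach the true_m2 target: ROI too full")

    overlap = a & b
    n_b = int(b.sum())
    realized_m1 = float(overlap.sum() / n_a) if n_a else float("nan")
    realized_m2 = float(overlap.sum() / n_b) if n_b else float("nan")

    ch_a = spec.amplitude * a.astype(float)
    ch_b = spec.amplitude * b.astype(float)
    if spec.noise_sd > 0:
        ch_a = np.clip(ch_a + rng.normal(0, spec.noise_sd, shape), 0, None)
        ch_b = np.clip(ch_b + rng.normal(0, spec.noise_sd, shape), 0, None)
    stack = ImageStack({"ch_a": ch_a, "ch_b": ch_b}, meta={"seed": spec.seed})
    truth = ColocGroundTruth(mask_a=a, mask_b=b, realized_m1=realized_m1,
                             realized_m2=realized_m2, spec=spec)
    return stack, truth


# ---------------------------------------------------------------------------
# Notochord traces


@dataclass(frozen=True)
class NotochordSpec:
    """Polyline recipe: one interior bend angle per non-terminal vertex."""

    vertex_angles: tuple = ()
    segment_length: float = 50.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertex_angles", tuple(float(a) for a in self.vertex_angles))
        for a in self.vertex_angles:
            if not 0 < a <= 180:
                raise ParameterError(f"vertex angles must lie in (0, 180], got {a}")
        if self.segment_length <= 0:
            raise ParameterError("segment_length must be > 0")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")


def generate_notochord_trace(spec: NotochordSpec) -> np.ndarray:
    """Ordered (n, 2) vertex coordinates realizing the requested bend angles.

    The trace starts at the origin heading along +x; at each interior vertex
    the heading turns by 180° − angle, with alternating turn sign so the
    trace wiggles rather than curls.  Jitter (if any) is i.i.d. Gaussian on
    every coordinate and is the only consumer of the seed, so jitter_sd = 0
    traces are seed-independent.
    """
    angles = spec.vertex_angles if spec.vertex_angles else (180.0,)
    pts = [np.zeros(2)]
    heading = 0.0
    step = spec.segment_length
    pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
    for i, ang in enumerate(angles):
        turn = (180.0 - ang) * (1 if i % 2 == 0 else -1)
        heading += np.deg2rad(turn)
        pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
    trace = np.asarray(pts)
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        trace = trace + rng.normal(0.0, spec.jitter_sd, trace.shape)
    return trace


# ---------------------------------------------------------------------------
# Spot fields


@dataclass(frozen=True)
class SpotFieldSpec:
    """Recipe for a field of well-separated Gaussian spots."""

    n_spots: int
    min_separation: float = 10.0
    amplitude: float = 100.0
    spot_sigma: float = 2.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ParameterError("n_spots must be >= 0")
        if self.min_separation <= 0 or self.amplitude <= 0 or self.spot_sigma <= 0:
            raise ParameterError("min_separation, amplitude, spot_sigma must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def generate_spot_image(spec: SpotFieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render Gaussian spots at integer pixel centers; returns (image, (n,2) coords)."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    margin = int(np.ceil(3 * spec.spot_sigma)) + 2
    if 2 * margin >= min(shape):
        raise ParameterError("image_shape too small for the spot size")
    centers: list[tuple[int, int]] = []
    for _ in range(5000 * max(1, spec.n_spots)):
        if len(centers) == spec.n_spots:
            break
        c = (int(rng.integers(margin, shape[0] - margin)),
             int(rng.integers(margin, shape[1] - margin)))
        if all(np.hypot(c[0] - r, c[1] - q) >= spec.min_separation for r, q in centers):
            centers.append(c)
    if len(centers) < spec.n_spots:
        raise ParameterError(
            f"could not place {spec.n_spots} spots with separation "
            f"{spec.min_separation} in {shape}"
        )
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    image = np.zeros(shape, dtype=float)
    for r, q in centers:
        image += spec.amplitude * np.exp(
            -((rr - r) ** 2 + (cc - q) ** 2) / (2 * spec.spot_sigma**2)
        )
    if spec.noise_sd > 0:
        image = np.clip(image + rng.normal(0, spec.noise_sd, shape), 0, None)
    coords = np.asarray(centers, dtype=float).reshape(-1, 2)
    return image, coords


def write_ground_truth_sidecar(path, truth: CellGroundTruth) -> None:
    """JSON sidecar for a generated cell: label, realized (A, MI), seed."""
    payload = {
        "label": truth.true_label.value,
        "realized_A": truth.realized_a,
        "realized_MI": truth.realized_mi,
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
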