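# Methods

This note documents the models, conventions and design choices behind
phenogate: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Golgi morphotype gating

Each cell contributes one point in (A, MI) space. `A` is purely geometric:
the Golgi-positive pixel count over the whole-cell pixel count, × 100. `MI`
is the mean intensity of the Golgi-positive pixels under a configurable
normalization (`SegmentationConfig.mi_normalization`):

- **reference** (default): divide by a fixed arbitrary-units scale
  (`reference_intensity`, default 100 counts ≡ MI 1.0). This reflects the
  acquisition practice the gates presume — laser power, detector gain and
  offsets held constant within an experiment — so per-pixel intensity is
  comparable across cells and a dispersed Golgi, spreading a finite amount
  of labelled protein over more area, genuinely reads out MI < 1.
- **cell**: divide by the mean of the Golgi channel over the whole cell
  mask. This is scale-free (invariant to multiplying the channel by any
  positive constant), but it is bounded below by 1 whenever the
  Golgi-positive pixels are the above-threshold (bright) class — the mean of
  the brightest pixels cannot fall below the mean of all pixels — so gates
  below 1 are unreachable in this mode. It is kept for relative
  comparisons and for its invariance property, not for gating.
- **raw**: no normalization; the user's instrument units.

The published gate thresholds (2.6 / 2.7 / 12 on A; 1.5 / 0.8 on MI) are
applied with strict inequalities exactly as printed. The four open
rectangles are mutually exclusive but not exhaustive: the band
A ∈ [2.6, 2.7], the boundary lines, the region A < 2.6 with MI ≤ 1.5, and
A > 12 with MI ≥ 0.8 belong to no gate. The default boundary policy labels
such cells `unclassified` explicitly — silent reassignment would bias class
percentages — and a `nearest` policy (scaled Euclidean distance to the gate
closures; A scaled by 12, MI by 1.5; ties broken in gate order
compact → expanded → partially → totally dispersed) is available for
robustness studies. The same gap-closure logic, made explicit, applies to
the bend-angle classes below.

## Segmentation

Cell = largest connected component of the transfection-marker channel above
threshold; nucleus = largest above-threshold component of the nucleus
channel, intersected with the cell; each organelle mask = above-threshold
pixels of its channel within the cell. Thresholds default to Otsu (marker
and nucleus over the whole image, organelles within the cell mask); fixed
per-channel thresholds can be configured. Otsu behaves well on these
near-bimodal single-cell images across the full foreground-fraction range
the gates cover (~0.5–26 % of the cell); this is exercised directly by the
recovery tests. Masks are 0-based row/column pixel sets; no physical-unit
conversion happens inside feature code (pixel size is metadata).

Perinuclear operationalizations (the original scoring was by eye):
COP-I is "clustered at the PN" when the largest COP-I object's centroid
falls within a 5-px dilation of the nucleus; the default PN ROI for
transferrin is a 15-px annulus around the nucleus clipped to the cell, and
a user ROI mask overrides it. The transferrin class cuts
(`tfn_clustered_min` = 0.5 of Tfn-positive signal in the PN ROI;
`tfn_dispersed_max_cluster` = 0.05 largest-cluster area fraction) and the
ribbon call (largest object ≥ 0.5 of the signal, boundary inclusive, and
elongation ≥ 2 or nucleus-adjacent) are package defaults, exposed in
configuration and echoed into every output's provenance.

## Colocalization

Thresholded Manders coefficients with strict positivity (a pixel exactly at
threshold is negative — a fixed, documented convention). Default
thresholding is Otsu within the ROI, applied identically to both channels
and all conditions; the exact algorithm behind the commercial tool this
replaces is unknowable, so numerical identity with it is not claimed, only
the same definition of M1/M2.

## Embryo morphometry

Interior angles are computed with the atan2 form
(`atan2(|u×v|, u·v)`), which is well conditioned near 0° and 180° where the
acos form loses ~6 digits. Bend severity uses the printed integer
boundaries (180 normal; 179–110 mild; ≤109 severe); the fractional gaps
(179°, 180°) and (109°, 110°) close upward, i.e. toward the less severe
class, so measurement noise near a boundary cannot inflate severity; the
monotonicity of severity in decreasing angle is property-tested. Per-embryo
severity uses the mean of all bend angles; the minimum angle is reported
alongside. Circular statistics follow the standard convention of circular-
statistics software: R is the mean resultant length, µ its direction, and
circular SD = √(−2 ln R) (radians, reported in degrees); the angular
deviation √(2(1−R)) is available via `sd_formula="angular"`, and axial
treatment (angle doubling) via `axial=True`. Angles are treated as plain
directions by default even though bend angles live in (0, 180].

The worsening index is the plain ratio of percent-severe with morpholino to
percent-severe without, as published; because a ratio cannot be negative,
the companion transforms ratio−1 and log₂ ratio (which place "no change" at
0, matching how an alleviation window below 0 is usually drawn) are emitted
alongside but never replace the ratio. A zero denominator yields NaN, an
explicit undefined sentinel.

Spot counting smooths with a σ = 1 px Gaussian, thresholds at half the
smoothed maximum by default, and suppresses non-maxima within
`min_separation`. Mitotic-phase scoring operationalizes a manual protocol:
two components of comparable size (ratio ≥ 0.5) → late; a single component
with major/minor axis ratio ≥ 2.5 → metaphase; otherwise early. All three
thresholds are configuration.

## Statistics

χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with df = 1; no Yates correction by
default (only the plain test is named by the protocols this mirrors), the
corrected variant behind a flag; expected counts below 5 warn but do not
block. One-sample t against a fixed H₀ mean with two-sided p. Both are
written from the formulas and verified against scipy's independent
implementations in the tests; p-values come from scipy's chi-square and t
distributions. Raw p-values are reported; Bonferroni/Holm adjustment is
offered on a caller-assembled family, since the class tables themselves do
not define one.

## Synthetic data generator

Every generator is a pure function of its spec (seed included); identical
spec ⇒ bit-identical output, which the determinism tests assert at byte
level through the full pipeline.

**Cells.** A disk cell (radius 100 px in a 256×256 frame) with an offset
disk nucleus (radius 30 px, offset 35 % of the cell radius in a seeded
random direction). The Golgi mask is grown to an exact pixel budget
`round(target_A/100 · |cell|)`: compact and expanded morphotypes grow one
body against the nucleus boundary (crescent-like when small, a larger
perinuclear blob as the budget grows), partial dispersal distributes the
budget over 8 mid-size puncta, total dispersal over 40 small puncta
cell-wide, placed with separation and grown as nearest-pixel disks. The
Golgi amplitude is `target_MI × reference_intensity`, so the ground-truth
MI equals the target exactly and ground-truth A is exact up to one pixel
(half a pixel of a ~31,000-px cell is ~0.002 in A — the generator cannot
hit an arbitrary real-valued A closer than the grid allows). Dispersal
lowering the per-pixel intensity is encoded by the gate targets themselves
(compact boxes pair small A with high MI, dispersed boxes large A with low
MI); no separate constant-integrated-intensity constraint is imposed, since
MI is targeted directly. Rendering applies an isotropic Gaussian PSF
(σ = 1 px default) and additive Gaussian noise clipped at zero. Population
sampling draws (A, MI) targets uniformly inside finite per-class gate boxes
(unbounded gate sides capped at A = 26, MI = 2.8) shrunk by a boundary
margin (default 0.2 of the box width per side); `noise_frac` scales noise
to each cell's own Golgi amplitude.

**Colocalization pairs.** Both channels are unions of equal-amplitude
disks, so M1 reduces to a pixel-count fraction; the overlap pixel count is
chosen to hit `true_m1` (whole objects first, then part of one object) and
B-only pixels to hit `true_m2`, each exact to one pixel (well within the
stated 0.02 tolerance at the default ~600-pixel channel support). The
extremes are exact: M1 = M2 = 1 is built as identical channels, M1 = M2 = 0
as disjoint supports. Because M1 = 0 means the A⁺∧B⁺ overlap carries no
signal, it forces M2 = 0 (and vice versa); specs with exactly one zero
target are rejected as unreachable.

**Notochord traces** realize requested interior angles by turning
180° − angle at each vertex with alternating sign (a wiggle, not a curl);
coordinate jitter is the only consumer of the seed, so jitter-free traces
are seed-independent. **Spot fields** place Gaussian spots (σ = 2 px,
amplitude 100) at integer centers with enforced minimum separation and
bounded rejection sampling.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: Poisson shot noise, spectral bleed-through,
uneven illumination, cell-to-cell shape variability, touching cells, 3D
structure, and out-of-focus light beyond a single Gaussian PSF. Passing
recovery tests demonstrate that the pipeline's measurement and gating logic
is correct and robust to additive noise at the stated level, not that the
published thresholds transfer to any particular microscope: the MI scale of
real data depends on acquisition settings the user must calibrate via
`reference_intensity` (how the original MI axis was scaled across
experiments is not recoverable from the protocol, which is why the
normalization is configuration rather than a guess).

## Validation problem sizes

The acceptance checks run 200 cells (50 per morphotype, margin 0.2) for
recovery at zero noise and at noise = 10 % of each cell's Golgi amplitude;
a 3001×301 grid (step 0.01 over A ∈ [0,30], MI ∈ [0,3]) for gate-partition
integrity; 100 random colocalization pairs against a pixel-summation
oracle (1e-9); 1000 random angle sets against a trigonometric oracle
(1e-9); 100 trace round-trips (1e-9); 100 spot fields at SNR 5; and the
demo pipeline twice for byte-identical outputs. These sizes make the suite
a few tens of seconds on one CPU while keeping every rate estimate at or
above 100 trials.

## Known limitations

- Single-cell images only: no instance segmentation of confluent fields.
- The largest-component cell rule assumes one dominant transfected cell
  per frame.
- Otsu thresholding assumes a foreground/background intensity separation;
  very low SNR or strong gradients call for fixed thresholds via config.
- Gate-boundary cells are sensitive to the boundary policy by construction;
  report the policy (it is embedded in every output's provenance).
- The in-vivo ribbon/puncta and mitotic-phase rules are deterministic
  stand-ins for protocols originally scored by eye; their thresholds are
  honest configuration, not fitted constants.
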