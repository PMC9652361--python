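# phenogate

Quantitative phenotyping for cell-biology and zebrafish imaging studies of
Golgi/secretory-pathway perturbations. The package turns fluorescence
micrographs and morphometric annotations into discrete, gate-defined
phenotype classes and the statistics applied to them — the kind of scoring
used to characterize GTPase variants that fragment the Golgi in cells and
bend the body axis in embryos — and ships a seeded synthetic-data generator
so that every stage can be validated against known ground truth without any
proprietary imaging data.

## What it computes

**Golgi morphotype gating.** For each transfected cell, two features are
measured from the segmented masks:

- `A` — Golgi-positive area as a percentage of the whole-cell area,
  `A = 100 · |Golgi⁺| / |cell|`;
- `MI` — normalized mean intensity of the Golgi-positive pixels
  (arbitrary units; see `docs/methods.md` for the normalization modes).

Cells are classified by rectangular gates in (A, MI) space:

| morphotype           | gate                     |
|----------------------|--------------------------|
| compact              | A < 2.6 and MI > 1.5     |
| expanded             | 2.7 < A < 12 and MI > 0.8|
| partially dispersed  | 2.7 < A < 12 and MI < 0.8|
| totally dispersed    | A > 12 and MI < 0.8      |

Points falling in none of the gates (the strict inequalities leave gaps) are
reported `unclassified` by default; a nearest-gate policy is available.
Companion classifiers score the COP-I compartment (compact/expanded at a
COP-I-area/nucleus-area cut of 0.25, else diffused), transferrin
distribution (clustered / semi-clustered / dispersed) and the in-vivo GalT
signal (ribbon vs puncta).

**Colocalization.** Thresholded Manders coefficients inside a ROI:
`M1 = Σ A over {A>tA ∧ B>tB} / Σ A over {A>tA}` and symmetrically `M2`,
with per-channel Otsu thresholds computed in the ROI.

**Embryo morphometry.** Notochord bend angles from ordered traces; severity
classes (180° normal, 179°–110° mild, ≤109° severe); circular statistics
(mean vector µ, resultant length R, circular SD = √(−2 ln R)); the
convergence–extension index AP/ML; head area, polyline lengths, A–P end
angles and spindle dimensions; spot counting for acridine-orange-positive
cells; mitotic-phase scoring from pH3 mask shape; and the morpholino
worsening index (percent severe with MO ÷ percent severe without).

**Statistics.** Two-sided chi-square on 2×2 tables,
χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), and the one-sample t test against a
control-defined H₀ mean — both implemented from the formulas and
cross-checked against scipy in the test suite.

## Worked example

Classify one synthetic compact cell end to end:

```python
from phenogate.synth import SyntheticCellSpec, generate_cell_image
from phenogate.features import segment_cell, golgi_features
from phenogate.gates import classify_golgi_morphotype

spec = SyntheticCellSpec("compact", target_a=1.5, target_mi=2.0, seed=1)
stack, truth = generate_cell_image(spec)
seg = segment_cell(stack)
f = golgi_features(seg, stack["golgi"])
print(f"A = {f.a:.3f} %   MI = {f.mi:.3f}   ->",
      classify_golgi_morphotype(f.a, f.mi).value)
```

prints

```
A = 1.499 %   MI = 1.852   -> compact
```

The cell was built to occupy 1.5 % of the cell area at twice the reference
intensity; segmentation recovers the area almost exactly, the Gaussian
point-spread blur shaves the measured MI from 2.0 to 1.85, and the (A, MI)
pair falls in the compact gate.

The full demo pipeline — simulate 20 cells (5 per morphotype), segment,
gate, tabulate, score colocalization pairs and notochord trace groups:

```bash
phenogate run --seed 1 --out demo
```

```
{"n_cells": 20, "n_failures": 0, "label_recovery": 1.0}
```

`demo/class_percentages.csv` shows 25 % per morphotype with nothing
unclassified, i.e. every generated cell was recovered as its true class;
`demo/fish_circular.csv` summarizes the two simulated embryo groups

```
condition,n_angles,mu_deg,R,circ_sd_deg
control,18,178.468,0.99990,0.798
mutant,18,85.403,0.97466,12.982
```

(straight controls cluster tightly at ~180°, the bent group at ~85° with a
wider circular spread), and `demo/stats.csv` carries the severe-vs-not
chi-square between the groups (χ² = 12.0, p ≈ 5.3·10⁻⁴). A quick 2×2 test
from the shell:

```bash
phenogate stats 20 5 5 20
# {"chi2": 18.0, "df": 1, "p_value": 2.209e-05}
```

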