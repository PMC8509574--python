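# Methods

This note records the models, conventions and numerical choices behind
`pleurovol`, and what the synthetic experiments do and do not establish.

## Imaging model and phantom generator

A phantom is a voxel grid in Hounsfield units with a fixed canonical
frame: axes `(z, y, x)`, `z = 0` the most superior slice, `x` increasing
toward the patient's left. It contains:

* a torso of soft tissue (default 40 HU) standing in exterior air
  (−1000 HU). The torso cross-section is the union of the widest lung
  cross-sections and the trachea, dilated by the chest-wall thickness
  (default 15 mm) with an exact Euclidean dilation, so the wall has
  uniform thickness even obliquely;
* two ellipsoidal aerated lungs (default −850 HU, semi-axes 95/75/55 mm
  craniocaudal/AP/lateral, ≈ 1.6 L each — the scale of the study
  cohort's aerated lungs);
* a trachea (radius 9 mm) opening at the superior face, with two main
  bronchi running laterally into the lungs. The lumen is air and carries
  a one-voxel soft-tissue bronchial wall, open at its distal end, so a
  HU threshold connects the lungs to the airway only through the tree;
* on the affected side, a pleural rind of soft-tissue HU with controlled
  per-level thickness `rind_mm = (upper, middle, lower)`.

The rind is carved per axial slice as an exact inward Euclidean-distance
offset of the lung cross-section, so its thickness perpendicular to the
cavity wall equals the nominal value everywhere in the plane. An inward
offset by `t` is only a uniform shell while `t` stays below the pole
radius of curvature `B²/A` of the cross-section (beyond that the offset
curve develops cusps and the in-plane gap at the poles exceeds `t`); on
slices near the apex/base where that bound bites, the carved rind is
capped at `B²/A − 2` voxels. The cap keeps the maximum in-plane
perpendicular thickness per level equal to the nominal rind, and keeps
the aerated volume monotone in `rind_mm`. If a level has no slice that
can host the full nominal thickness, generation fails loudly rather than
silently under-delivering ground truth.

Ground truth (per-side aerated volume, airway volume, burden slots under
the default substitution rules) is defined on the noise-free generating
masks as voxel count × voxel volume; optional Gaussian HU noise (σ up to
50 HU is exercised) is added afterwards, so recovery tolerances are
interpretable. Default grid: 75 × 128 × 192 voxels at 3 × 1.5 × 1.5 mm
(3 mm slices, as in the study acquisitions).

What the phantoms do **not** emulate: ribs and mediastinal organs,
contrast phases, reconstruction kernels, partial-volume effects at
tissue boundaries (geometry is binary before noise), pleural effusion or
hydropneumothorax (the study excluded such patients), and respiratory
or cardiac motion. Passing recovery tests therefore demonstrates the
correctness of the measurement chain on idealised anatomy, not clinical
segmentation performance.

## Segmentation

1. **Threshold**: voxels with −1020 ≤ HU ≤ −250 (endpoints inclusive;
   the window bounds are parameters).
2. **Exterior removal**: 26-connected components touching a lateral
   (x/y) face of the grid are exterior air. Components smaller than
   1 cm³ are dropped as speckle. Nothing left → "no lung found".
3. **Airway cropping**: region growing over lumen-density voxels
   (HU ≤ −925, the midpoint of aerated lung and air) from the most
   superior such voxel — the tracheal lumen, which by convention opens
   at the superior face. The grown tree is dilated by one voxel and the
   dilation is intersected with lumen-density voxels before subtraction,
   so the margin absorbs noisy lumen-boundary voxels but cannot eat
   aerated lung. No seed → warning and no cropping.
4. **Left/right split**: components are assigned by centroid relative to
   the body midline (centroid of the hole-filled torso mask — filling
   the pleural cavities first keeps the midline invariant to one-sided
   disease). A single component straddling the midline is split by the
   midsagittal plane with a warning.
5. **Volumetry**: volume = voxel count × voxel volume;
   `diff_cm3 = contralateral − ipsilateral`;
   `diff_pct = 100 · diff_cm3 / contralateral`.

The percent difference is taken relative to the **contralateral** lung.
This convention is validated by the bundled R2 cohort: reconstructing
`contralateral = ipsilateral / (1 − diff_pct/100)` reproduces the
published cm³-difference summary (median 1371, IQR 667.4–2164) exactly.

On noise-free phantoms the segmentation masks equal the generating masks
voxel for voxel, so volume recovery is exact; with 50 HU noise the
volumes stay within a fraction of a percent (the 600 HU margin between
aerated lung and the upper threshold is 12 σ).

## Pleural thickness and disease burden

Thickness needs a reference for where the chest wall would be if the
pleural space were disease-free; a radiologist reads this off the bony
thorax, which the package does not model. Instead, the expected cavity
boundary on each axial slice is estimated as the convex hull of the
**contralateral** aerated lung mirrored across the body midline.
Measurement at a cavity-boundary point `p`:

* `d(p)` = in-plane Euclidean distance from `p` to the nearest aerated
  voxel of the affected lung (for a uniform rind of thickness `t` this
  distance equals `t` and is realised along the boundary normal —
  "perpendicular to the chest wall" by construction);
* thickness `t̂(p) = d(p) + depth(p) − s`, where `depth(p)` is `p`'s
  distance to the cavity exterior and `s` one in-plane voxel: the two
  terms cancel the half-voxel offsets between voxel centres and the two
  tissue surfaces (exact for grid-aligned boundaries);
* a candidate is discarded if the straight path from `p` to its nearest
  aerated voxel crosses non-soft-tissue that is not lung (e.g. the air
  column of a main bronchus), and boundary points the hull bridged in
  (bronchus mouth, discretisation concavities) never seed measurements;
* raw distances below 0.75 voxel are treated as boundary discretisation,
  not lesion.

Per level, the slice maxima are collected and the two largest values
from distinct axial slices become the level's two slots (distinct slices
prevent double-counting a single focal mass). Substitution rules: a slot
below the measurability floor (3 mm, one slice thickness) but present
takes the 5 mm default; an absent lesion takes 0 mm. The burden is the
sum of the six slots. Both chest-wall and mediastinal surfaces are
eligible for either slot.

On phantoms the per-level maxima agree with the generating rind within
one in-plane voxel and the six-slot burden within two voxels per slot.
The mirrored-contralateral cavity estimate assumes roughly symmetric
hemithoraces; phantoms are generated with symmetric lung geometry, and
on real anatomy (where the two cavities differ) the reference would be
correspondingly biased — a deliberate limitation, since anatomical
landmark detection is out of scope. Levels are always delimited by
user-supplied landmark slice indices, never auto-detected.

## Cohort statistics

* **Quartiles**: R-6 convention (positions `p·(n+1)`; SPSS HAVERAGE,
  numpy `method="weibull"`). Pinned because it reproduces the published
  R2 summaries digit for digit (TLC 75 (71–80), burden 133 (70–181),
  volume 1545 (1322–1782), diff% 47.01 (28.39–59.01)).
* **Mann–Whitney**: two-sided; exact for small tie-free samples,
  tie-corrected normal approximation otherwise (scipy).
* **Fisher**: two-sided hypergeometric-sum p; conditional-MLE odds
  ratio; a zero margin returns p = 1 with the OR flagged undefined.
* **Spearman**: average ranks for ties; exact permutation p for n ≤ 8
  without ties, t-approximation otherwise; constant input is flagged.
* **ROC / cut-offs**: AUC by the rank (Mann–Whitney) formulation, so
  `AUC ≡ U/(n₁n₀)` holds as a cross-operation identity. Cut-off
  candidates are midpoints between consecutive sorted unique values
  (hence half-unit clinical cut-offs); the winner maximises
  sensitivity + specificity, ties broken toward higher specificity and
  then the smaller value. Classification rules use strict inequalities.
* **Logistic regression**: maximum likelihood (statsmodels), Wald CIs
  and p-values, ORs per unit of the predictor's native scale.
  Univariable screening at α = 0.05 determines the multivariable entry
  set; the screened set is configurable because the source analysis did
  not publish it exactly. Perfect or quasi-separation (non-convergence,
  |coef| > 50, or exploding standard errors) is flagged, never silently
  reported.
* Missing optional covariates are handled complete-case per comparison.
  No multiple-testing correction is applied (none was used in the
  source analysis). All tests are two-sided.

## Synthetic cohorts

Individual data exist only for the 15 unresectable patients (bundled,
checksummed, never mutated — derived columns are always recomputed).
Two-group analyses therefore run on synthetic cohorts: per group,
lognormal marginals (normal for the percent difference) matched to the
published group medians and IQRs, default sizes 43 MCR vs 15 R2, with no
within-patient correlation beyond the group effect. These cohorts
exercise the machinery and reproduce the direction and rough magnitude
of the published discrimination (AUCs in the 0.65–0.90 range across
seeds); they cannot reproduce the exact published AUCs, specificities or
multivariable ORs, which depend on the unpublished individual data.
Logistic parameter recovery uses cohorts drawn from a known logistic
model (n = 500 per replicate): estimated coefficients fall within two
standard errors of truth and null CIs cover 1 at the nominal rate.

## Problem sizes and determinism

Default phantoms are 75 × 128 × 192 voxels (≈ 1.8 M); a full
generate–segment–measure pass takes a few seconds on one CPU. Test
simulations use 100–2000 replicates per check; the acceptance script
uses 50 logistic replicates. All randomness flows through
`numpy.random.default_rng` seeds; pipeline reports serialise with sorted
keys so identical configurations give byte-identical JSON.
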