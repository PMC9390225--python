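# Methods

`pleuraquant` quantifies and classifies pleural effusions from chest-CT
volumes paired with lung/pleura label masks. The segmentation itself is an
input (any segmenter that emits background/lung/pleura — optionally airway —
labels can feed the pipeline); everything downstream of the masks is
implemented here: detection and volumetry, interpretable complexity
features, shape and NGTDM radiomics, ROC-based threshold selection, a
five-model random-forest classification protocol, and the agreement
statistics used to evaluate each stage.

## Complexity features

For each pleural side (left/right split by connected components of
lung∪pleura against the sagittal midline, majority vote for straddling
components) the pipeline measures, in physical millilitres via the voxel
spacing:

* **Detection and volumetry.** An effusion is called present when the
  pleura label reaches 2 mL — the same minimal-volume prerequisite used
  for all features, chosen because smaller collections are
  indistinguishable from segmentation noise.
* **Hyperdensity.** Voxels above 30 HU within the pleura label are grouped
  into 26-connected components; components under 2 mL are discarded as
  spurious. `f_hyper` is the surviving volume, `f_hyper_rate` its
  percentage of the collection volume.
* **Rim/cavity partition.** The cavity is the erosion of the pleura label
  by a physical ball of radius `rim_mm` (default 4 mm), computed from the
  Euclidean distance transform; the rim is the remainder. Because the
  distance transform measures to background voxel *centres* — up to half a
  voxel beyond the material boundary, less for oblique interfaces — a
  quarter of the smallest voxel edge is subtracted, which keeps the
  digital erosion of a 20 mm test ball within 5% of the continuous one.
  The ≥2 mL filter is applied on the whole pleura label *before* the
  partition intersection, so the rim/cavity split cannot fragment a single
  collection below threshold. `f_pleura_rate` and `f_cavity_rate` are the
  hyperdense percentages of rim and cavity; their ratio `f_inout_ratio`
  and the indexed ratio `f_inout_ratio_index = f_inout_ratio ×
  f_hyper_rate` summarize whether hyperdensity concentrates at the margin
  (thickening) or in the interior (hemorrhagic/purulent fluid). A zero
  rim rate leaves the ratio *missing* (`NaN`), never 0 or ∞: a clean rim
  and a cavity-dominant pattern must not be conflated. The classifier
  imputes missing values with 0 plus an indicator column.
* **Gas.** `f_gas` is the ≥2 mL component volume below −850 HU inside the
  pleura label. `f_pneumothorax` collects sub-threshold components that
  are outside lung∪pleura∪airway, inside the body (tissue above −500 HU,
  holes filled), face-adjacent (6-neighbourhood) to lung or pleura, and
  not connected through sub-threshold voxels to the airway label; without
  an airway label the bronchial-exclusion rule is skipped with a warning.
  Component grouping is deliberately permissive (26-connected) while the
  anatomical-contact test is strict (face adjacency).

Rates are reported on the 0–100 scale; reported proportions are rounded
half-up to two decimals (0.625 → 0.63), matching how such tables are
conventionally printed.

## Radiomics

Only the families that carry signal for this problem are implemented:
3D shape and NGTDM texture, following the IBSI reference conventions.
Shape: eigenvalue features from the covariance of physical voxel-centre
coordinates (axis lengths 4√λ, elongation √(λ₂/λ₁), flatness √(λ₃/λ₁));
mesh volume (divergence theorem) and surface area from a marching-cubes
isosurface at level 0.5; sphericity (36πV²)^⅓/A; maximum 3D diameter and
per-plane maximum 2D diameters from boundary-voxel hulls. The binary mask
is Gaussian-smoothed by 0.8 voxel before meshing: a hard binary isosurface
is a staircase that materially overstates surface area, and the
smoothing restores the spherical limit while biasing compact-structure
volumes by well under 1% (both checked against the analytic ball in the
tests). Mesh volumes of plate-like regions only a few voxels thick are
biased low — mesh features are classifier inputs, not volumetry, which
always uses voxel counts.

NGTDM uses fixed-bin-width discretization (25 HU, anchored at the region
minimum — the conventional CT choice when no protocol is stated) and the
Amadasun–King formulas with the neighbourhood mean over the 26-
neighbourhood restricted to the region. Degenerate conventions are fixed
and tested: a single occupied grey level gives busyness = strength =
contrast = complexity = 0 and coarseness capped at 10⁶. An externally
computed radiomics table can be ingested as CSV instead of (or alongside)
the built-in features.

## Threshold selection

Candidate hyperdensity cutoffs (8.5, 15.6, 30 HU) and rim widths (4, 5,
8 mm) are compared by the AUC (Mann–Whitney rank formulation, ties ½) of
the recomputed feature — absolute hyperdense volume for the HU sweep, rim
hyperdensity rate for the mm sweep, per case the maximum over sides —
against the binary case labels. The winner is the argmax AUC; ties break
toward the least permissive candidate (highest HU, smallest width), which
reproduces the conventional operating point (30 HU, 4 mm) whenever
candidates tie on clean data. Defaults throughout the package use that
operating point.

## Classification protocol

Five independent binary random-forest tasks: simple-vs-complex plus one
model per complexity feature (hyperdense fluid, pleural thickening, gas,
loculation), over the combined complexity + radiomic feature table,
aggregated per case by the maximum over sides. Per task:

1. the training table is randomly downsampled to an exact 1:1 class ratio
   (majority subsampled without replacement, seed-controlled);
2. a preliminary 100-tree forest ranks features by mean impurity decrease;
   features at or above the median importance are kept, ties included —
   note that when more than half the importances are zero the median is
   zero and everything survives, which is the literal consequence of the
   ≥-percentile rule;
3. hyperparameters are tuned by leave-one-out cross-validated accuracy
   over a deliberately small grid: `max_depth ∈ {None, 8}` ×
   `min_samples_leaf ∈ {1, 5}` at a fixed 100 trees. Tree count is not a
   bias–variance axis at these sample sizes (a few hundred cases,
   ~10²-strong feature sets); depth and leaf size are. Ties break toward
   the most regularized candidate;
4. the final forest is fitted on the balanced table; test positivity
   requires probability **strictly** greater than 0.5, so an exact 0.5
   is a negative call.

One global seed fans out to named streams (downsampling, selection,
fitting), so every stage is independently reproducible; a saved bundle
(JSON metadata + serialized forests) replays predictions to 1e-12.

## Synthetic phantom generator

No clinical CTs ship with the package, so the study conditions are
emulated by a parametric thoracic phantom: an ellipsoidal soft-tissue body
(40 HU) with two ellipsoidal lungs (−800 HU), an optional cylindrical
trachea (label 3, −1000 HU), and per-side pleural collections:

* **dependent effusions** — posterior crescents between the lung surface
  and a posteriorly shifted outer ellipsoid: concave, draping shapes;
* **loculated effusions** — ball-minus-lung lenses abutting the lung
  posterolaterally; overlapping a convex lung surface yields the obtuse
  contact angle by construction, and the collection is convex;
* **hyperdense inclusions** (default 60 HU, fresh-blood range) as
  depth-core layers `{EDT > s}` of the collection, so an inclusion no
  larger than the cavity partition lies entirely inside it and
  ground-truth labels are recoverable by measurement;
* **rim thickening** painted on `{EDT ≤ width}` (default 4 mm, 60 HU);
* **gas** as −1000 HU bubbles placed at the deepest available point of
  the collection, and **pneumothorax** as an anterior-lateral −1000 HU
  pocket between lung and chest wall (label 0 — it is outside the
  pleural segmentation), face-adjacent to the lung and disjoint from the
  airway;
* additive Gaussian noise (default σ = 10 HU, a typical soft-kernel CT
  noise level) on the CT only, never on the mask.

Effusion and pocket volumes are matched by bisection on one geometric
parameter (realized volumes within ~0.5%); inclusions and bubbles are
exact-count voxel selections (within one voxel). Ground truth records the
realized voxelized volumes and the binary labels they imply: an inclusion
≥2 mL above 30 HU ⇒ hyperdense fluid; a painted rim ≥2 mL above 30 HU ⇒
thickening; any single bubble or pocket ≥2 mL ⇒ gas; lens geometry ⇒
loculation; `complex` is the OR.

Cohorts draw the four labels independently per case with the clinical
prevalences (5.1% hyperdense, 28.4% thickening, 29.9% gas, 38.2%
loculation); real complexity features co-occur, so independence slightly
overstates the complex fraction (~0.66 vs 0.56) — acceptable for a
protocol testbed. Volume ranges (12–28 mL lenses, 15–80 mL crescents,
pockets 10–20 mL, bubbles ≥2.6 mL, inclusions ~3–6 mL) are sized to the
default grid so every requested structure is geometrically feasible *and*
its label is recoverable with margin: hyperdense crescents are drawn at
≥56 mL so the cavity partition exceeds the inclusion's 2 mL rule, and gas
bubbles stay clear of that rule's boundary so σ = 10 HU noise cannot flip
a label. Fluid densities are uniform on 0–12 HU (serous range, and ≥1.8σ
below the 30 HU cutoff so noise-driven false hyperdensities stay below
the 2 mL filter). Each cohort case carries one unilateral effusion;
bilateral disease is supported by the generator but not drawn, since
classification is per case with max-over-sides aggregation.

**Label-derivation rules** (measurement side): hyperdense fluid ⇔
cavity-restricted surviving hyperdensity ≥ 2 mL; thickening ⇔ rim
hyperdensity rate ≥ 50% (painted rims measure ≈100%, localized cavity
inclusions ≤ ~25%); gas ⇔ `f_gas` or `f_pneumothorax` ≥ 2 mL; loculation
⇔ solidity (voxel volume / convex-hull volume) ≥ 0.62, a threshold that
sits in the gap between the concave crescents and the convex lenses
across the default volume ranges; the exact-label-recovery tests exercise
this margin on every random cohort case.

### What the phantom does and does not show

The phantom reproduces the *decision structure* of the problem — HU
contrasts, physical thresholds, morphology, component filtering, label
semantics — with analytically known truth, which is what makes exact
recovery testable. It does not contain ribs, vessels, atelectasis,
partial-volume blur, beam hardening, contrast phases, nodular (vs smooth)
thickening, or inter-patient anatomical variability. Passing tests
therefore demonstrate that the measurement and classification machinery
is correct and self-consistent, not that clinical accuracy on real CTs
would match; clinical figures require clinical data.

## Problem sizes

Default grids are 96×88×72 at 1.5 mm (cohorts) and 144×132×108 at
1.0 mm (single-case validation at the reference resolution). The validation suite uses 100 random 1 mm phantoms for
ground-truth recovery, 200 random ≤32³ grids for brute-force oracle
equivalence, and a 200-train/100-test cohort for the classification
protocol; these sizes keep the full suite comfortably reproducible on a
single CPU while leaving the statistical margins (label recovery, AUC)
wide.

## Evaluation statistics

Dice (two empty masks = 1.0: perfect agreement on absence; one empty =
0); sensitivity/specificity/PPV/NPV from confusion counts with Wilson 95%
CIs (a zero denominator blanks that statistic only); ICC(2,1) — two-way
random effects, absolute agreement, single measurement — the appropriate
form for comparing an automated against a manual volumetry, with
F-distribution CI bounds and zero-variance data defined as ICC 1.0;
Bland–Altman bias ± 1.96·SD (sample SD); Pearson correlation of paired
volumes. The ICC implementation is cross-checked against an independent
ANOVA-table oracle (1e-10) and against `pingouin`.

## Known limitations

* The phantom's smooth ellipsoidal geometry makes shape-based loculation
  detection easier than in patients; the solidity rule is a phantom
  ground-truth device, not a clinical classifier.
* Only smooth rim thickening is generated; "nodular" thickening has no
  quantitative definition here.
* NGTDM features are computed on the noisy CT inside the pleura label;
  with σ = 10 HU they mostly reflect gas/hyperdensity contrast, which is
  the intended signal for the gas task.
* Per-case aggregation is max-over-sides; per-side classification is
  supported by the tables but not the default.
* DICOM series reading, resampling/registration and segmentation itself
  are out of scope; NIfTI volumes with consistent grids are required.
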