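# Methods

This note documents the models and procedures implemented in
`atlasmorph`, the parameter choices that matter, what the synthetic
phantom does and does not emulate, and the numerical conventions that
make results platform-independent and reproducible.

## Pipeline model

The package assumes segmentation *propagation* has already happened: for
each target image, N atlases (MR images with reference segmentations)
have been registered to the target and their label maps resampled onto
the target grid. Everything downstream of that registration is
implemented here.

**Vote-rule fusion.** The fused label at a voxel is the most frequent
code among the N candidates. Background (code 0) participates as a
first-class vote by default, because fused whole-head label maps contain
background and a voxel most candidates call background should be
background. A `foreground` mode restricts votes to nonzero codes for
users who prefer atlas-consensus foreground. Plurality ties resolve to
the smallest code (background smallest of all): deterministic,
order-independent, and biased toward the conservative choice. Binary
masks fuse by strict majority — a voxel is set only if more than half
the candidates agree, so an exact split on an even count is false.

**Intracranial mask.** Input is a semi-automatic WM+GM brain mask and a
CSF mask. The brain mask is blurred with a Gaussian kernel, thresholded,
hole-filled, then united with the CSF mask and the original mask and
hole-filled again. Parameters:

| parameter | default | units | notes |
|---|---|---|---|
| kernel width | 6 | mm | interpreted as σ; a FWHM reading (σ ≈ 2.55 mm) is selectable because kernel conventions differ between toolkits |
| threshold | 0.27 | fraction of full intensity | applied to the blurred [0, 1] mask, before hole-filling (blur → threshold → fill order) |
| hole-filling | — | — | 3D flood fill from the grid border, 6-connected background; any cavity not reaching the border is filled |

The blur divides the kernel width by the per-axis voxel spacing, so
anisotropic grids blur isotropically in physical space, and uses zero
padding at the grid border. The union with the original mask guarantees
the containment contract (brain mask ⊆ intracranial mask) even for thin
structures that a wide kernel would otherwise dilute below threshold.

**Tissue discretization.** Voxels are assigned to the arg-max class
among CSF, GM, WM and an implicit background class whose probability is
max(0, 1 − ΣP). Ties among tissue classes break in the fixed order
CSF < GM < WM; tissue classes win ties against background. The fixed
order makes discretization platform-independent; which class wins a
three-way tie is immaterial in practice (ties have measure zero in real
probability maps) but must be pinned for bit-reproducibility.

**Tissue-class masking.** Each region's `mask_class` (GM, CSF or none)
lives in the region table. Cortical regions keep only GM voxels —
relevant because cortical neuronal loss is a GM phenomenon — and the
lateral ventricles keep only CSF voxels, which corrects their tendency
to be oversegmented into hypointense white matter. Ventricles (other
than lateral), central structures, cerebellum and brainstem pass through
unmasked. Masking is idempotent and can only shrink regions.

**Volumetry and normalization.** Raw volume is voxel count × voxel
volume (from header spacing; no isotropy assumed). Normalized volume is
raw/ICV × 10⁴. ICV normalization removes head-size and global-scaling
effects, which also makes results immune to linear scanner-scaling
differences; the arbitrary 10⁴ factor puts typical regions in a
readable 1–200 range.

**Asymmetry.** A_r = 2|V_R − V_L|/(V_R + V_L) is bounded in [0, 2] and
symmetric under hemisphere swap; the unbalanced ratio V_L/V_R
complements it with a signed direction. Pairs with zero total volume
(or zero right volume, for the ratio) are reported as missing rather
than zero — a zero would masquerade as perfect symmetry.

**WMD index.** A = (M_W ∩ F_G) ⊖ E captures white matter that the
intensity-based tissue classifier labeled gray (the T1 signature of
white-matter disease); B = (M_V ∩ S_B) ⊖ E captures ventricle labels
that overreach into brain tissue. E is the full 26-connected 3×3×3 cube
in voxel units; the erosion removes thin boundary sheets that arise from
ordinary misregistration rather than disease, so only confluent
hypointensity survives. Voxels whose neighborhood extends outside the
grid are eroded away (background padding) — a conservative choice that
can only lower the index. WMHI = |W|/ICV × scale with scale defaulting
to the same 10⁴ used for volumes. Validation helpers rank images by
index and sample 42:21:7 from the tertiles for visual review
(oversampling the tail where disease concentrates) and correlate the
index with a 0–3 visual rating via Kendall's tau-b, treating ±0.3 rater
tendencies as continuous values; tau-b's tie correction is essential
with a 4-level rating.

A known blind spot is reproduced as a test rather than patched:
hypointense tissue absorbed into an adjacent label (classically the
caudate nucleus) appears in neither A nor B, so a caudate can be
oversegmented by disease while the index reads 0.

**Outlier QC.** Normalized volumes are z-scored within
(diagnosis, gender, field-strength) strata, per region, using the
sample SD (ddof = 1); |z| > 4 (strict) flags a region for review.
Strata with n < 3 or zero variance yield no flags and are reported on a
warnings channel. Field strength is a stratum key in its own right;
images of one subject at two field strengths are treated as separate
observations.

**Group statistics.** Region-wise comparisons between diagnosis groups
use Welch's unequal-variance t-test — the paper-trail default when
group variances differ, as they do with neurodegeneration — and report
raw two-tailed p-values. No multiplicity correction is applied by
design: the p-values rank regions against each other rather than test
hypotheses (Bonferroni/FDR can be applied downstream if needed).
Equivalence of group means (used for ICV stability across diagnoses)
uses TOST with margin ε = 0.05 × pooled mean; the pooled (rather than
reference-group) mean was chosen because the comparison is symmetric,
and the referent is configurable. The TOST p is the larger of the two
one-sided Welch p-values; `statsmodels.ttost_ind` provides the
computation and the test suite checks it against an independently coded
closed form.

**Agreement metrics.** Per-region Jaccard J = |A∩B|/|A∪B| and Dice
D = 2|A∩B|/(|A|+|B|), related by D = 2J/(1+J). JC_m averages J over
regions present in either segmentation; a region empty in both is an
undefined 0/0 and is excluded, empty in exactly one scores 0. The
across-subject dispersion JC_σ is reported per region as the SD of J as
a percentage of its mean. Precision of a fused segmentation is
estimated by randomly bisecting the atlas set into two equal halves,
fusing each, and computing JC_m between the halves; the split is
deterministic given the seed and the halves are disjoint and
exhaustive.

## The phantom

The generator emulates the *statistical* structure of a dementia-cohort
segmentation study, not anatomy:

* ~25 regions as ellipsoidal blobs on a hemispheric head template:
  bilateral pairs with consecutive codes (odd = right, even = left) and
  midline singletons, including hippocampus, amygdala, parahippocampal,
  temporal and fusiform cortex, lateral ventricles with temporal horns,
  caudate, cerebellum, brainstem and generic cortical fillers.
* Healthy region volumes set to the printed healthy-cohort means
  (fraction of ICV × 10⁴, e.g. hippocampus 14.4 right / 13.3 left,
  lateral ventricle body 125.2/138.1), which also builds a
  right-larger-than-left hippocampal asymmetry of ~0.08 into the
  healthy template.
* Diagnosis effects: per-(region, diagnosis) fractional volume changes;
  the defaults are the printed effect sizes (about −20% hippocampus and
  +40% lateral ventricle in AD vs healthy, graded through stable and
  progressive MCI). Volumes are realized by thresholding each region's
  ellipsoidal distance field at the exact target voxel count — uniform
  boundary peeling/growth that is deterministic and yields nested
  shapes, so effect recovery is limited only by voxelization.
* Inter-subject variability: multiplicative lognormal noise on region
  volumes with CV 0.06. Rationale: ICV normalization removes most
  head-size-driven variance, and the residual within-group CV of
  normalized subcortical volumes in well-segmented adult cohorts is of
  order 5–10%; 6% represents a clean, well-normalized cohort. Disease
  heterogeneity is modeled separately through the effect table, not
  through this noise term.
* Head size: per-subject ICV drawn from N(1.41, 0.143²) litres
  truncated to [1.0, 1.9] l (the printed cohort distribution), realized
  by isotropic voxel-size scaling so that region volumes scale with ICV
  before group effects apply — which is exactly the confound ICV
  normalization is meant to remove.
* WMD lesions: the requested lesion volume is taken as the
  nearest-to-seed ball of white-matter voxels abutting the right
  lateral ventricle; lesion voxels get GM probability > WM probability,
  mimicking the classifier failure the WMD index detects. Nested lesion
  sets plus the monotonicity of erosion make the index provably
  monotone in lesion load for fixed geometry.
* Atlas candidates: boundary jitter. Each simulated propagated atlas
  flips boundary-shell voxels with probability `jitter` (< 0.5) to a
  uniformly chosen differing 6-neighbor's code; interior voxels never
  change. This keeps majority-vote behavior analytically tractable: the
  expected per-boundary-voxel disagreement equals the jitter rate, and
  fusion of 30 candidates at jitter 0.2 recovers the truth almost
  everywhere.

Not emulated: cortical folding, MR intensity and noise models, scanner
artifacts, nonrigid registration error fields (jitter is spatially
independent, unlike real registration error, which is correlated),
partial-volume effects, and longitudinal change. Consequently, passing
phantom tests demonstrates the correctness of the computational stages
and their statistical behavior under controlled effects — not
segmentation accuracy on real images.

Determinism: one root seed; per-subject streams derive from a stable
hash of the subject id, so cohorts regenerate bit-identically and any
subject can be regenerated in isolation. All derived seeds stay below
2³¹.

## Problem sizes

Default phantom grid 48×56×48 voxels at 3 mm (head ≈ 43 000 voxels),
30 simulated atlases. The effect-recovery analysis uses 40 + 40
subjects over 20 seeds; the WMD validation sample uses 70 images; the
bisection analysis uses one 30-candidate stack. These sizes keep the
full test suite and the acceptance script in the tens of seconds on a
single CPU while leaving every region at least ~20 voxels.

## Known limitations

* The phantom's boundary jitter under-represents spatially correlated
  registration failure, so fusion and bisection numbers on phantoms are
  optimistic relative to real multi-atlas pipelines.
* The WMHI scale factor is a convention (10⁴); absolute index values
  are comparable only within a fixed scale and erosion element.
* The default region table covers the regions with printed codes plus
  fillers; a full atlas table (e.g. 83 regions) must be supplied as CSV
  for real data, including the superregion and mask-class columns.
* TOST power depends on n: tiny cohorts (the 8-subject smoke default)
  will rarely declare equivalence even for identical generative ICV
  distributions.
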