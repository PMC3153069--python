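# atlasmorph

Regional brain morphometry on multi-atlas segmentations of T1-weighted
MR images, for researchers who work with label maps rather than raw
images. The package implements the post-registration stages of a
multi-atlas pipeline for dementia cohorts: propagated atlas label maps
go in; vote-fused segmentations, intracranial-volume-normalized regional
volumes, asymmetry indices, a white-matter disease index and cohort QC
statistics come out. A synthetic phantom generator stands in for image
data, so the whole pipeline is testable and reproducible on any machine.

## What it computes

* **Vote-rule decision fusion.** Given N candidate segmentations of a
  target (one per registered atlas; 30 in the standard setup), the fused
  label at each voxel is the plurality vote, with ties broken toward the
  smallest region code. Binary masks fuse by strict majority.
* **Intracranial mask.** The WM+GM brain mask is blurred with a 6 mm
  Gaussian kernel, thresholded at 27%, hole-filled and extended by the
  CSF mask. The input mask is always contained in the result. Regional
  volumes are expressed as fraction of intracranial volume (ICV),
  scaled by 10⁴.
* **Tissue-class masking.** Cortical labels are restricted to the
  gray-matter class, lateral ventricles to CSF; central structures,
  cerebellum and brainstem are exempt. The mapping lives in a region
  table (CSV), not in code.
* **White-matter hypointensities index (WMHI).** With M_W the fused
  atlas white-matter mask, F_G the target's discrete GM mask, M_V the
  fused lateral ventricles, S_B the WM+GM mask and E a 3×3×3 cube:

      A = (M_W ∩ F_G) ⊖ E,  B = (M_V ∩ S_B) ⊖ E,  W = A ∪ B
      WMHI = |W| / ICV × 10⁴

  The index flags T1-hypointense white matter that tissue classifiers
  mislabel as gray matter and that can distort segmentations.
* **Asymmetry.** For paired volumes V_R, V_L the balanced index
  A_r = 2|V_R − V_L| / (V_R + V_L) ∈ [0, 2] and the ratio V_L / V_R.
* **QC statistics.** Per-region Jaccard/Dice agreement between
  segmentations (D = 2J/(1+J)), atlas-bisection precision (JC_m between
  fusions of two random atlas half-sets), z-score outlier flagging
  (|z| > 4 within diagnosis × gender × field-strength strata), Welch
  t-test matrices between diagnosis groups, and TOST equivalence
  (α = 0.05, ε = 0.05 μ).

## Worked example

```python
import numpy as np
from atlasmorph import (
    PhantomSpec, SubjectRecord, generate_subject, perturb_atlas_labels,
    vote_fuse, discretize_tissue, build_icv_mask, mask_labels,
    measure_volumes, asymmetry_indices, compute_wmd_mask, wmhi_index,
    pairwise_agreement, jc_to_dsc, BinaryMask,
)

spec = PhantomSpec(seed=1, wmd_lesion_volume=8000.0)
sub = generate_subject(spec, SubjectRecord("AD-000", "AD", "M", 1.5, ("I0",)))

candidates = perturb_atlas_labels(sub.labels, n_atlases=30, jitter=0.2, seed=1)
fused = vote_fuse(candidates)
print(f"fusion vs truth JC_m: {pairwise_agreement(fused, sub.labels).jc_m:.3f}")

csf, gm, wm = discretize_tissue(sub.tissue)
icv = build_icv_mask(sub.wm_gm_mask, csf)          # 6 mm blur, 27% threshold
masked = mask_labels(fused, gm, csf, spec.region_table())
vols = measure_volumes(masked, icv, spec.region_table(), "AD-000", "I0")
hippo = vols.set_index("region_code").loc[[1, 2], "normalized"]
print(f"ICV: {icv.volume_mm3()/1e6:.2f} l")
print(f"hippocampus R/L normalized: {hippo[1]:.1f} / {hippo[2]:.1f}")

asym = asymmetry_indices(vols, spec.region_table())
row = asym[asym["right_code"] == 1].iloc[0]
print(f"hippocampal A_r: {row['a_r']:.3f}, L/R: {row['l_over_r']:.3f}")

m_v = BinaryMask(np.isin(fused.grid, [45, 46, 47, 48]), fused.voxel_size)
res = wmhi_index(compute_wmd_mask(sub.atlas_wm_mask, gm, m_v, sub.wm_gm_mask), icv)
print(f"WMHI: {res.wmhi:.2f}")
print(f"DSC at the cohort JC_m 0.802: {jc_to_dsc(0.802):.3f}")
```

Output:

```
fusion vs truth JC_m: 1.000
ICV: 1.41 l
hippocampus R/L normalized: 12.6 / 10.9
hippocampal A_r: 0.139, L/R: 0.870
WMHI: 6.98
DSC at the cohort JC_m 0.802: 0.890
```

Reading the numbers: fusing 30 jittered candidates recovers the ground
truth exactly (JC_m 1.0). The subject's intracranial volume is 1.41 l;
hippocampal volumes are in fraction-of-ICV × 10⁴ units and sit below the
healthy means (14.4 right, 13.3 left) because this is a simulated AD
subject with −18% atrophy plus inter-subject noise. The asymmetry index
0.139 is elevated relative to the healthy median (~0.08). The WMHI of
6.98 reflects the injected 8 cm³ hypointense lesion after erosion and
ICV normalization; a lesion-free subject scores 0.

The same stages are scriptable from a shell via the `amk` command
(`amk phantom`, `amk icv`, `amk fuse`, `amk wmhi`, `amk volumes`,
`amk agree`, `amk outliers`, `amk tost`, `amk run`); `amk run --out DIR`
executes the whole chain on a synthetic cohort and writes five CSV
reports plus provenance JSON, byte-identical under a fixed seed.

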