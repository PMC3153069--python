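"""White-matter hypointensities index (WMHI).

White-matter disease (WMD) appears on T1-weighted images as diffusely
hypointense white matter. Intensity-based tissue classifiers mislabel
such voxels as gray matter, which in turn distorts atlas-based
segmentations (lateral ventricles, caudate and insula tend to be
overestimated). The WMHI estimates the affected volume purely by set
operations on four binary masks:

* ``M_W`` — atlas-consensus white matter (majority vote over propagated
  atlas WM masks; atlases are young healthy adults, so M_W marks where
  WM ought to be),
* ``F_G`` — the target's discrete gray-matter mask,
* ``M_V`` — fused lateral-ventricle labels,
* ``S_B`` — the target's WM+GM brain mask.

Two intermediate images are built with a full 3x3x3 cubic structuring
element E::

    A = (M_W intersect F_G) eroded by E     (WM that classified as GM)
    B = (M_V intersect S_B) eroded by E     (ventricle label overreaching
                                             into brain tissue)
    W = A union B

and the index is the volume of W as a fraction of intracranial volume,
scaled by 1e4 by default. The index is zero when no hypointense voxels
survive erosion; a known blind spot is hypointense tissue absorbed into
an adjacent label (classically the caudate nucleus), which appears in
neither A nor B and leaves the index at zero.

Validation support: ranking images by WMHI and sampling 42:21:7 from the
tertiles for visual review, and Kendall tau-b correlation against a
semiquantitative 0-3 visual rating (with optional +-0.3 tendencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sp_stats

from .containers import BinaryMask, check_same_geometry

__all__ = [
    "DEFAULT_WMHI_SCALE",
    "STRUCTURING_ELEMENT_SHAPE",
    "WMHIResult",
    "WahlundScore",
    "compute_wmd_mask",
    "wmhi_index",
    "stratified_review_sample",
    "score_correlation",
]

#: WMHI = |W| / ICV * scale; same arbitrary 1e4 factor used for
#: normalized region volumes
DEFAULT_WMHI_SCALE = 1.0e4

#: erosion structuring element: full (26-connected) cube, voxel units
STRUCTURING_ELEMENT_SHAPE = (3, 3, 3)


@dataclass
class WMHIResult:
    """WMD mask decomposition and (once normalized) the scalar index."""

    W: BinaryMask
    A: BinaryMask
    B: BinaryMask
    wmhi: float | None = None
    icv_mm3: float | None = None
    scale: float = DEFAULT_WMHI_SCALE


@dataclass(frozen=True)
class WahlundScore:
    """Semiquantitative 0-3 hypointensity rating, T1-adapted.

    0: no hypointensities clearly identifiable as lesions; 1: focal
    lesions; 2: beginning confluence; 3: diffuse involvement. The rater
    may record a tendency of +-0.3 points.
    """

    value: int
    tendency: float = 0.0
    rater_blinded: bool = True

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2, 3):
            raise ValueError(f"base score must be in {{0,1,2,3}}, got {self.value}")
        if not np.isclose(abs(self.tendency), 0.3) and self.tendency != 0.0:
            raise ValueError(f"tendency must be -0.3, 0 or +0.3, got {self.tendency}")

    @property
    def numeric(self) -> float:
        return self.value + self.tendency


def compute_wmd_mask(
    m_w: BinaryMask,
    f_g: BinaryMask,
    m_v: BinaryMask,
    s_b: BinaryMask,
) -> WMHIResult:
    """Build the WMD mask W = A union B from the four input masks.

    Erosion uses the full 3x3x3 cube with background padding at the grid
    border (border voxels whose neighborhood leaves the grid are eroded
    away — conservative estimate).
    """
    check_same_geometry(m_w, f_g, m_v, s_b)
    se = np.ones(STRUCTURING_ELEMENT_SHAPE, dtype=bool)
    a = ndimage.binary_erosion(m_w.grid & f_g.grid, structure=se, border_value=0)
    b = ndimage.binary_erosion(m_v.grid & s_b.grid, structure=se, border_value=0)
    vs = m_w.voxel_size
    return WMHIResult(W=BinaryMask(a | b, vs), A=BinaryMask(a, vs), B=BinaryMask(b, vs))


def wmhi_index(
    result: WMHIResult,
    icv_mask: BinaryMask,
    scale: float = DEFAULT_WMHI_SCALE,
) -> WMHIResult:
    """Normalize |W| by intracranial volume into the scalar index.

    ``wmhi = |W| / |ICV| * scale``; volume ratios make the index
    invariant under isotropic rescaling of the whole head.
    """
    check_same_geometry(result.W, icv_mask)
    icv = icv_mask.volume_mm3()
    if icv <= 0:
        raise ValueError("ICV mask is empty; WMHI undefined")
    result.wmhi = result.W.volume_mm3() / icv * scale
    result.icv_mm3 = icv
    result.scale = float(scale)
    return result


def stratified_review_sample(
    wmhi_values: pd.Series,
    proportions: tuple[int, int, int] = (42, 21, 7),
    seed: int = 0,
) -> list:
    """Sample image ids for visual review, stratified by WMHI tertile.

    Images are ranked by index descending and split into three equal
    parts (remainders going to the earlier, higher-index parts); from
    each part the requested count is drawn without replacement. The
    default 42:21:7 proportions oversample the high-index tail, whose
    images are the ones most likely to show disease.
    """
    s = pd.Series(wmhi_values)
    if len(proportions) != 3:
        raise ValueError("proportions must have exactly 3 entries")
    if any(p < 0 for p in proportions):
        raise ValueError("proportions must be non-negative")
    if len(s) < sum(proportions):
        raise ValueError(f"cannot sample {sum(proportions)} from {len(s)} images")
    ranked = s.sort_values(ascending=False, kind="stable")
    n = len(ranked)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    rng = np.random.default_rng(seed)
    chosen = []
    start = 0
    for size, want in zip(sizes, proportions):
        part = ranked.index[start : start + size]
        start += size
        if want > size:
            raise ValueError(f"requested {want} images from a tertile of {size}")
        if want:
            pick = rng.choice(len(part), size=want, replace=False)
            chosen.extend(part[np.sort(pick)])
    return list(chosen)


def score_correlation(wmhi_values, scores) -> float:
    """Kendall tau-b between WMHI and the numeric visual score.

    ``scores`` may be :class:`WahlundScore` objects or plain numbers;
    tendencies make the scores continuous and tau-b handles the heavy
    ties. Returns NaN when either side is constant (undefined).
    """
    x = np.asarray(wmhi_values, dtype=float)
    y = np.asarray([s.numeric if isinstance(s, WahlundScore) else float(s) for s in scores])
    if len(x) != len(y):
        raise ValueError("wmhi_values and scores must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    tau = sp_stats.kendalltau(x, y, variant="b").statistic
    return float(tau)
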