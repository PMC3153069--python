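"""Intracranial mask construction and tissue-class masking of labels.

The intracranial (ICV) mask is grown from a semi-automatic white-matter +
gray-matter brain mask: the mask is blurred with a 6 mm Gaussian kernel,
thresholded at 27% of full intensity, hole-filled, and extended by the
CSF mask so that internal and peri-cerebral CSF is included while
meninges, sinuses and extracranial tissue stay out. The input WM+GM mask
is always fully contained in the result, which keeps the ICV measurement
insensitive to operator variability in the original mask.

Tissue probability maps are discretized by per-voxel arg-max (with an
implicit background class), and region labels are then restricted to the
tissue class appropriate for each region: cortical labels to GM, lateral
ventricles to CSF, central structures / cerebellum / brainstem kept
whole. The exemption list lives in the region table's ``mask_class``
column, not in code.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import BinaryMask, LabelVolume, TissueMaps, check_same_geometry
from .morphometry import RegionTable

__all__ = [
    "DEFAULT_SIGMA_MM",
    "DEFAULT_THRESHOLD",
    "build_icv_mask",
    "discretize_tissue",
    "mask_labels",
]

#: Gaussian kernel width for ICV mask construction, in mm. Interpreted as
#: sigma by default; pass ``kernel_is_fwhm=True`` to read it as FWHM.
DEFAULT_SIGMA_MM = 6.0

#: threshold applied to the blurred [0, 1] mask
DEFAULT_THRESHOLD = 0.27

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _fill_holes(grid: np.ndarray) -> np.ndarray:
    # background components not connected to the grid border are filled;
    # 6-connectivity for the background flood-fill
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_fill_holes(grid, structure=structure)


def build_icv_mask(
    wm_gm_mask: BinaryMask,
    csf_mask: BinaryMask,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    threshold: float = DEFAULT_THRESHOLD,
    kernel_is_fwhm: bool = False,
) -> BinaryMask:
    """Intracranial mask from a WM+GM brain mask and a CSF mask.

    Pipeline: Gaussian blur (``sigma_mm``) -> threshold at ``threshold``
    of full intensity -> hole-fill, then union with the CSF mask and the
    original WM+GM mask (containment guarantee), then a final hole-fill.

    The blur uses zero (background) padding at the grid border, and the
    kernel width is divided by the voxel spacing per axis, so anisotropic
    grids blur isotropically in physical space.
    """
    check_same_geometry(wm_gm_mask, csf_mask)
    if wm_gm_mask.count() == 0:
        raise ValueError("WM+GM mask is empty; nothing to expand into an intracranial mask")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    sigma = float(sigma_mm)
    if kernel_is_fwhm:
        sigma /= _FWHM_PER_SIGMA
    sigma_vox = [sigma / vs for vs in wm_gm_mask.voxel_size]
    blurred = ndimage.gaussian_filter(
        wm_gm_mask.grid.astype(float), sigma=sigma_vox, mode="constant", cval=0.0
    )
    envelope = _fill_holes(blurred >= threshold)
    combined = envelope | csf_mask.grid | wm_gm_mask.grid
    return BinaryMask(_fill_holes(combined), wm_gm_mask.voxel_size)


def discretize_tissue(maps: TissueMaps) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Per-voxel arg-max tissue classification.

    Each voxel is assigned to the most probable class among CSF, GM, WM
    and implicit background (probability ``1 - (csf+gm+wm)``, floored at
    0). Ties among tissue classes break in the fixed order
    CSF < GM < WM; tissue classes win ties against background. The three
    returned masks are mutually disjoint. All-zero maps give pure
    background.
    """
    stack = np.stack([maps.csf, maps.gm, maps.wm])
    background = np.clip(1.0 - stack.sum(axis=0), 0.0, None)
    winner = stack.argmax(axis=0)  # first max wins: CSF < GM < WM
    best = np.take_along_axis(stack, winner[None], axis=0)[0]
    is_bg = best < background
    csf = (winner == 0) & ~is_bg
    gm = (winner == 1) & ~is_bg
    wm = (winner == 2) & ~is_bg
    vs = maps.voxel_size
    return BinaryMask(csf, vs), BinaryMask(gm, vs), BinaryMask(wm, vs)


def mask_labels(
    labels: LabelVolume,
    gm: BinaryMask,
    csf: BinaryMask,
    regions: RegionTable,
) -> LabelVolume:
    """Restrict each region label to its tissue class.

    Regions with ``mask_class`` GM keep only GM voxels, CSF regions
    (lateral ventricles) keep only CSF voxels, and ``none`` regions are
    passed through unchanged. Idempotent; per-region output volume never
    exceeds the input volume.
    """
    check_same_geometry(labels, gm, csf)
    classes = regions.mask_class_map()
    present = labels.codes()
    unknown = [int(c) for c in present if int(c) not in classes]
    if unknown:
        raise KeyError(f"label codes {unknown} not in region table")
    out = labels.grid.copy()
    for code in present:
        cls = classes[int(code)]
        if cls == "none":
            continue
        keep = gm.grid if cls == "GM" else csf.grid
        out[(labels.grid == code) & ~keep] = 0
    return LabelVolume(out, labels.voxel_size, labels.code_table_ref)
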