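"""Regional volumetry: raw and ICV-normalized volumes, superregion
aggregates, and left/right asymmetry indices.

The region code table drives everything downstream of segmentation: which
codes exist, how left/right partners pair up (by convention consecutive
codes, odd = right, even = left), which superregion each code aggregates
into, and which tissue class masks it (GM for cortical labels, CSF for
the lateral ventricles, none for central structures, cerebellum and
brainstem).

Region sizes are expressed both raw (mm^3) and as a fraction of the
intracranial volume scaled by 1e4, the standard head-size normalization
that removes global scaling effects from group comparisons.

The volume table produced by :func:`measure_volumes` is a plain pandas
DataFrame with columns ``subject_id, image_id, region_code, raw_mm3,
normalized, icv_mm3`` — one row per (image, region).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinaryMask, LabelVolume, check_same_geometry

__all__ = [
    "RegionTable",
    "NORMALIZATION_SCALE",
    "VOLUME_COLUMNS",
    "measure_volumes",
    "aggregate_superregions",
    "asymmetry_indices",
]

#: region volumes are reported as fraction of ICV times this factor
NORMALIZATION_SCALE = 1.0e4

VOLUME_COLUMNS = ["subject_id", "image_id", "region_code", "raw_mm3", "normalized", "icv_mm3"]

HEMISPHERES = {"L", "R", "midline"}
MASK_CLASSES = {"GM", "CSF", "none"}
SUPERREGIONS = {"TL", "FL", "PL", "OL", "IC", "PF", "CS", "VS"}

# Default table: the regions with printed codes in the source atlas
# (temporal-lobe structures and lateral ventricles), plus cerebellum,
# brainstem and caudate, plus generic cortical filler pairs used by the
# synthetic phantom. A full custom table can be loaded from CSV.
_DEFAULT_ROWS = [
    # code, name, hemisphere, pair_code, superregion, mask_class
    (1, "Hippocampus R", "R", 2, "TL", "GM"),
    (2, "Hippocampus L", "L", 1, "TL", "GM"),
    (3, "Amygdala R", "R", 4, "TL", "GM"),
    (4, "Amygdala L", "L", 3, "TL", "GM"),
    (9, "G parahippocamp/amb R", "R", 10, "TL", "GM"),
    (10, "G parahippocamp/amb L", "L", 9, "TL", "GM"),
    (13, "Middle and inf temp gg R", "R", 14, "TL", "GM"),
    (14, "Middle and inf temp gg L", "L", 13, "TL", "GM"),
    (15, "Fusiform g R", "R", 16, "TL", "GM"),
    (16, "Fusiform g L", "L", 15, "TL", "GM"),
    (17, "Cerebellum R", "R", 18, "PF", "none"),
    (18, "Cerebellum L", "L", 17, "PF", "none"),
    (19, "Brainstem", "midline", None, "PF", "none"),
    (33, "Caudate nucleus R", "R", 34, "CS", "none"),
    (34, "Caudate nucleus L", "L", 33, "CS", "none"),
    (45, "Lat ventricle main R", "R", 46, "VS", "CSF"),
    (46, "Lat ventricle main L", "L", 45, "VS", "CSF"),
    (47, "Lat ventricle temp horn R", "R", 48, "VS", "CSF"),
    (48, "Lat ventricle temp horn L", "L", 47, "VS", "CSF"),
    (51, "Frontal filler R", "R", 52, "FL", "GM"),
    (52, "Frontal filler L", "L", 51, "FL", "GM"),
    (53, "Precentral filler R", "R", 54, "FL", "GM"),
    (54, "Precentral filler L", "L", 53, "FL", "GM"),
    (55, "Parietal filler R", "R", 56, "PL", "GM"),
    (56, "Parietal filler L", "L", 55, "PL", "GM"),
    (57, "Occipital filler R", "R", 58, "OL", "GM"),
    (58, "Occipital filler L", "L", 57, "OL", "GM"),
]

#: number of non-filler rows in the default table
N_CORE_REGIONS = 19


class RegionTableError(ValueError):
    """The region table violates one of its structural invariants."""


@dataclass
class RegionTable:
    """Code -> (name, hemisphere, pair, superregion, masking class) table.

    Backed by a DataFrame with columns ``code, name, hemisphere,
    pair_code, superregion, mask_class``; ``pair_code`` is NaN for
    unpaired (midline) regions.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        required = ["code", "name", "hemisphere", "pair_code", "superregion", "mask_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise RegionTableError(f"region table missing columns {missing}")
        df["code"] = df["code"].astype(int)
        self.frame = df.reset_index(drop=True)
        self.validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def default(cls, n_regions: int = 25) -> "RegionTable":
        """The built-in table truncated/extended to ``n_regions`` labels.

        ``n_regions`` counts total labels: the 19 core regions plus
        bilateral filler pairs, so valid values are 19, 21, 23, 25, 27.
        """
        extra = n_regions - N_CORE_REGIONS
        if extra < 0 or extra % 2 or n_regions > len(_DEFAULT_ROWS):
            raise RegionTableError(
                f"n_regions must be one of {list(range(N_CORE_REGIONS, len(_DEFAULT_ROWS) + 1, 2))}, "
                f"got {n_regions}"
            )
        rows = _DEFAULT_ROWS[:n_regions]
        df = pd.DataFrame(rows, columns=["code", "name", "hemisphere", "pair_code", "superregion", "mask_class"])
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        if df["code"].duplicated().any():
            dupes = sorted(df.loc[df["code"].duplicated(), "code"])
            raise RegionTableError(f"duplicate region codes {dupes}")
        if (df["code"] <= 0).any():
            raise RegionTableError("region codes must be positive")
        bad = set(df["hemisphere"]) - HEMISPHERES
        if bad:
            raise RegionTableError(f"unknown hemisphere values {sorted(bad)}")
        bad = set(df["mask_class"]) - MASK_CLASSES
        if bad:
            raise RegionTableError(f"unknown mask_class values {sorted(bad)}")
        bad = set(df["superregion"]) - SUPERREGIONS
        if bad:
            raise RegionTableError(f"unknown superregion values {sorted(bad)}")
        by_code = df.set_index("code")
        for code, row in by_code.iterrows():
            pc = row["pair_code"]
            if pd.isna(pc):
                continue
            pc = int(pc)
            if pc not in by_code.index:
                raise RegionTableError(f"region {code} pairs with unknown code {pc}")
            back = by_code.loc[pc, "pair_code"]
            if pd.isna(back) or int(back) != code:
                raise RegionTableError(f"pairing not symmetric for codes {code} <-> {pc}")
            if by_code.loc[pc, "superregion"] != row["superregion"]:
                raise RegionTableError(f"paired codes {code}/{pc} in different superregions")
            # odd = right / even = left convention, checked where hemispheres are declared
            if row["hemisphere"] == "R" and code % 2 == 0 and pc == code - 1:
                raise RegionTableError(f"code {code}: even code declared right of pair ({code}, {pc})")

    # -- accessors ------------------------------------------------------
    @property
    def codes(self) -> np.ndarray:
        return self.frame["code"].to_numpy()

    def __contains__(self, code: int) -> bool:
        return int(code) in set(self.frame["code"])

    def name_of(self, code: int) -> str:
        return str(self.frame.set_index("code").loc[int(code), "name"])

    def mask_class_map(self) -> dict[int, str]:
        return dict(zip(self.frame["code"], self.frame["mask_class"]))

    def superregion_map(self) -> dict[int, str]:
        return dict(zip(self.frame["code"], self.frame["superregion"]))

    def pairs(self) -> list[tuple[int, int]]:
        """(right_code, left_code) for every declared bilateral pair."""
        out = []
        for _, row in self.frame.iterrows():
            if pd.isna(row["pair_code"]):
                continue
            code, pc = int(row["code"]), int(row["pair_code"])
            if row["hemisphere"] == "R":
                out.append((code, pc))
            elif row["hemisphere"] == "L":
                continue  # listed from the right-hand row
            elif code < pc:  # hemisphere-agnostic fallback
                out.append((code, pc))
        return out


# ---------------------------------------------------------------------------
# volumetry
# ---------------------------------------------------------------------------

def measure_volumes(
    labels: LabelVolume,
    icv_mask: BinaryMask,
    regions: RegionTable,
    subject_id: str = "",
    image_id: str = "",
) -> pd.DataFrame:
    """Per-region raw (mm^3) and ICV-normalized volumes for one image.

    Every code in ``regions`` gets a row; codes absent from the image get
    raw volume 0. ``normalized = raw / ICV * 1e4``.
    """
    check_same_geometry(labels, icv_mask)
    icv_mm3 = icv_mask.volume_mm3()
    if icv_mm3 <= 0:
        raise ValueError("ICV mask is empty; cannot normalize volumes")
    present = labels.codes()
    known = set(int(c) for c in regions.codes)
    unknown = [int(c) for c in present if int(c) not in known]
    if unknown:
        raise KeyError(f"label codes {unknown} not in region table")
    counts = np.bincount(labels.grid.ravel(), minlength=int(regions.codes.max()) + 1)
    rows = []
    for code in regions.codes:
        raw = float(counts[code]) * labels.voxel_volume if code < len(counts) else 0.0
        rows.append(
            {
                "subject_id": subject_id,
                "image_id": image_id,
                "region_code": int(code),
                "raw_mm3": raw,
                "normalized": raw / icv_mm3 * NORMALIZATION_SCALE,
                "icv_mm3": icv_mm3,
            }
        )
    return pd.DataFrame(rows, columns=VOLUME_COLUMNS)


def aggregate_superregions(vols: pd.DataFrame, regions: RegionTable) -> pd.DataFrame:
    """Sum normalized volumes per superregion for each image.

    Returns a DataFrame indexed by ``image_id`` with one column per
    superregion present. The grand total over superregions equals the
    total over regions by construction.
    """
    if vols.empty:
        return pd.DataFrame()
    sr_map = regions.superregion_map()
    unmapped = sorted(set(vols["region_code"].astype(int)) - set(sr_map))
    if unmapped:
        raise KeyError(f"region codes {unmapped} have no superregion mapping")
    df = vols.copy()
    df["superregion"] = df["region_code"].astype(int).map(sr_map)
    return df.pivot_table(
        index="image_id", columns="superregion", values="normalized", aggfunc="sum", fill_value=0.0
    )


def asymmetry_indices(vols: pd.DataFrame, regions: RegionTable) -> pd.DataFrame:
    """Balanced and unbalanced left/right asymmetry per image and pair.

    The balanced index ``a_r = 2|V_R - V_L| / (V_R + V_L)`` lies in
    [0, 2] and is invariant under swapping hemispheres; the unbalanced
    index is ``V_L / V_R``. Pairs with ``V_R + V_L = 0`` (balanced) or
    ``V_R = 0`` (ratio) are reported as NaN, not zero.
    """
    pairs = regions.pairs()
    out = []
    for image_id, img in vols.groupby("image_id", sort=False):
        by_code = img.set_index("region_code")["normalized"]
        subject = img["subject_id"].iloc[0]
        for right, left in pairs:
            v_r = float(by_code.get(right, np.nan))
            v_l = float(by_code.get(left, np.nan))
            total = v_r + v_l
            a_r = 2.0 * abs(v_r - v_l) / total if total > 0 else np.nan
            ratio = v_l / v_r if v_r > 0 else np.nan
            out.append(
                {
                    "subject_id": subject,
                    "image_id": image_id,
                    "right_code": right,
                    "left_code": left,
                    "v_r": v_r,
                    "v_l": v_l,
                    "a_r": a_r,
                    "l_over_r": ratio,
                }
            )
    return pd.DataFrame(
        out,
        columns=["subject_id", "image_id", "right_code", "left_code", "v_r", "v_l", "a_r", "l_over_r"],
    )
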