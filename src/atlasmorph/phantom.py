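"""Synthetic brain phantoms for exercising the pipeline end to end.

Real inputs to this pipeline are T1-derived label volumes, tissue
probability maps and brain masks from an elderly dementia cohort. The
phantom module fabricates structurally equivalent data so that every
downstream stage (fusion, masking, WMD indexing, volumetry, QC) is
testable without any image downloads. Anatomical realism is explicitly
not a goal; what is emulated is the statistical structure:

* bilateral paired regions with consecutive codes (odd = right,
  even = left) and midline singletons, placed as ellipsoidal blobs on a
  hemispheric head template;
* diagnosis-dependent atrophy / ventricular expansion: each region's
  voxel count is the healthy template count scaled by a per-(region,
  diagnosis) fractional effect (defaults follow the printed
  dementia-cohort effect sizes: about -20% hippocampus and +40% lateral
  ventricle in AD vs healthy) times multiplicative inter-subject noise;
* head-size variation: per-subject intracranial volume drawn from the
  cohort's printed distribution (mean 1.41 l, SD 0.143 l, range
  1.02-1.86 l) and realized by isotropic voxel-size scaling;
* white-matter hypointensity lesions: a compact blob of white-matter
  voxels adjacent to the right lateral ventricle whose GM probability is
  raised above the WM probability, with controllable total volume;
* per-atlas boundary jitter standing in for the 30 independently
  registered atlas segmentations that vote fusion consumes.

Region sizes are realized by ranking each region's voxels along its
ellipsoidal distance field and keeping exactly the target count — a
level-set formulation of uniform boundary erosion/dilation that is
deterministic and gives nested shapes across effect sizes.

Determinism: one root seed; per-subject streams are derived by stable
hashing of the subject id, so a cohort regenerates bit-identically and
any single subject can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryMask, LabelVolume, TissueMaps
from .morphometry import RegionTable

__all__ = [
    "PhantomSpec",
    "SubjectRecord",
    "SubjectData",
    "PhantomTemplate",
    "PhantomSizingError",
    "DIAGNOSES",
    "DEFAULT_EFFECT_TABLE",
    "ICV_MEAN_MM3",
    "ICV_SD_MM3",
    "ICV_RANGE_MM3",
    "build_template",
    "generate_subject",
    "generate_cohort",
    "perturb_atlas_labels",
    "perturb_binary_mask",
    "subject_seed",
]

DIAGNOSES = ("HS", "s-MCI", "p-MCI", "AD", "O")
GENDERS = ("F", "M")
FIELD_STRENGTHS = (1.5, 3.0)

#: cohort ICV distribution (mm^3): mean / SD / truncation range
ICV_MEAN_MM3 = 1.41e6
ICV_SD_MM3 = 0.143e6
ICV_RANGE_MM3 = (1.0e6, 1.9e6)

# Fractional volume change vs healthy subjects per diagnosis, for the
# regions with printed effect sizes; every other region is unaffected.
# Keys: diagnosis -> {region code: fraction}.
_PRINTED_EFFECTS = {
    # code: (s-MCI, p-MCI, AD)
    47: (0.10, 0.32, 0.43),
    45: (0.17, 0.27, 0.40),
    46: (0.21, 0.31, 0.39),
    48: (0.06, 0.21, 0.34),
    2: (-0.09, -0.15, -0.20),
    3: (-0.08, -0.15, -0.19),
    10: (-0.09, -0.15, -0.19),
    1: (-0.09, -0.14, -0.18),
    4: (-0.08, -0.14, -0.18),
    9: (-0.07, -0.13, -0.18),
    14: (-0.05, -0.14, -0.17),
    15: (-0.05, -0.11, -0.16),
    16: (-0.06, -0.12, -0.16),
    13: (-0.03, -0.10, -0.14),
}

DEFAULT_EFFECT_TABLE: dict[str, dict[int, float]] = {
    "HS": {},
    "O": {},
    "s-MCI": {c: v[0] for c, v in _PRINTED_EFFECTS.items()},
    "p-MCI": {c: v[1] for c, v in _PRINTED_EFFECTS.items()},
    "AD": {c: v[2] for c, v in _PRINTED_EFFECTS.items()},
}

# Healthy-template region volumes as fraction of ICV * 1e4 (the printed
# healthy means where available, plausible values for the filler and
# central regions) and blob placement: center in normalized ellipsoid
# coordinates for the RIGHT-hemisphere member (x mirrored for left,
# x = 0 for midline) plus per-axis shape ratios of the ellipsoidal field.
_LAYOUT = {
    # code: (hs_vol_1e4, (ux, uy, uz), (rx, ry, rz))
    1: (14.4, (0.55, -0.30, -0.40), (1.0, 1.8, 1.0)),
    2: (13.3, (0.55, -0.30, -0.40), (1.0, 1.8, 1.0)),
    3: (9.5, (0.52, 0.02, -0.50), (1.0, 1.0, 1.0)),
    4: (9.9, (0.52, 0.02, -0.50), (1.0, 1.0, 1.0)),
    9: (23.4, (0.38, -0.55, -0.42), (1.0, 1.6, 1.0)),
    10: (24.3, (0.38, -0.55, -0.42), (1.0, 1.6, 1.0)),
    13: (62.3, (0.72, -0.12, -0.12), (1.0, 1.8, 1.2)),
    14: (59.9, (0.72, -0.12, -0.12), (1.0, 1.8, 1.2)),
    15: (20.4, (0.30, -0.70, -0.30), (1.0, 1.6, 1.0)),
    16: (21.4, (0.30, -0.70, -0.30), (1.0, 1.6, 1.0)),
    17: (150.0, (0.25, -0.48, -0.70), (1.2, 1.0, 1.0)),
    18: (150.0, (0.25, -0.48, -0.70), (1.2, 1.0, 1.0)),
    19: (60.0, (0.0, -0.18, -0.72), (1.0, 1.0, 1.8)),
    33: (20.0, (0.45, 0.28, 0.12), (1.0, 1.4, 1.0)),
    34: (20.0, (0.45, 0.28, 0.12), (1.0, 1.4, 1.0)),
    45: (125.2, (0.25, 0.02, 0.10), (1.0, 2.4, 1.0)),
    46: (138.1, (0.25, 0.02, 0.10), (1.0, 2.4, 1.0)),
    47: (5.3, (0.40, -0.42, -0.12), (1.0, 1.8, 1.0)),
    48: (4.8, (0.40, -0.42, -0.12), (1.0, 1.8, 1.0)),
    51: (80.0, (0.45, 0.58, 0.28), (1.0, 1.4, 1.0)),
    52: (80.0, (0.45, 0.58, 0.28), (1.0, 1.4, 1.0)),
    53: (70.0, (0.28, 0.38, 0.62), (1.0, 1.2, 1.0)),
    54: (70.0, (0.28, 0.38, 0.62), (1.0, 1.2, 1.0)),
    55: (60.0, (0.45, -0.28, 0.58), (1.0, 1.2, 1.0)),
    56: (60.0, (0.45, -0.28, 0.58), (1.0, 1.2, 1.0)),
    57: (50.0, (0.25, -0.68, 0.32), (1.0, 1.2, 1.0)),
    58: (50.0, (0.25, -0.68, 0.32), (1.0, 1.2, 1.0)),
}

#: ellipsoid-norm radii of the nested head compartments
_WM_NORM = 0.88        # white matter fills the interior up to here
_REGION_NORM = 0.92    # region blobs must stay inside this
# the (_WM_NORM, 1] band not claimed by a region is sulcal/shell CSF


class PhantomSizingError(ValueError):
    """The grid is too small to host the requested regions."""


@dataclass(frozen=True)
class SubjectRecord:
    """Cohort metadata for one synthetic subject."""

    subject_id: str
    diagnosis: str
    gender: str
    field_strength: float
    image_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if float(self.field_strength) not in FIELD_STRENGTHS:
            raise ValueError(f"field_strength must be in {FIELD_STRENGTHS}, got {self.field_strength}")


@dataclass(frozen=True)
class PhantomSpec:
    """Generator configuration; identical (spec, seed) -> identical data."""

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: float = 3.0
    n_regions: int = 25
    effect_table: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_TABLE.items()}
    )
    wmd_lesion_volume: float = 0.0
    icv_target: float = ICV_MEAN_MM3
    seed: int = 0
    #: inter-subject multiplicative CV of region volumes (lognormal)
    volume_noise_cv: float = 0.06

    def __post_init__(self) -> None:
        if any(int(s) < 16 for s in self.grid_shape):
            raise PhantomSizingError(f"grid_shape {self.grid_shape} too small (min 16 per axis)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.wmd_lesion_volume < 0:
            raise ValueError("wmd_lesion_volume must be >= 0")
        if self.icv_target <= 0:
            raise ValueError("icv_target must be positive")
        for dx, effects in self.effect_table.items():
            if dx not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis {dx!r} in effect_table")
            for code, f in effects.items():
                if f <= -1.0:
                    raise ValueError(f"effect for region {code} in {dx} must be > -1, got {f}")

    def region_table(self) -> RegionTable:
        return RegionTable.default(self.n_regions)


def subject_seed(root_seed: int, subject_id: str) -> int:
    """Stable per-subject seed below 2^31 derived from the root seed."""
    h = hashlib.blake2b(subject_id.encode("utf-8"), digest_size=4).digest()
    return (int(root_seed) ^ int.from_bytes(h, "big")) % (2**31)


# ---------------------------------------------------------------------------
# template construction (subject-independent geometry)
# ---------------------------------------------------------------------------

@dataclass
class PhantomTemplate:
    """Fixed geometry shared by all subjects generated under one spec."""

    spec_key: str
    grid_shape: tuple[int, int, int]
    head_mask: np.ndarray                 # bool, ellipsoid norm <= 1
    head_voxels: int
    territories: dict[int, np.ndarray]    # code -> flat indices (field-ordered)
    template_counts: dict[int, int]       # code -> healthy voxel count
    wm_flat: np.ndarray                   # flat indices of template white matter
    healthy_wm_mask: np.ndarray           # bool: WM incl. expansion reserve of ventricles
    shell_csf_flat: np.ndarray            # flat indices of sulcal/shell CSF
    lesion_order: np.ndarray              # WM flat indices by distance to the lesion seed
    region_table: RegionTable


_TEMPLATE_CACHE: dict[str, PhantomTemplate] = {}


def _template_key(spec: PhantomSpec) -> str:
    payload = {
        "grid_shape": list(spec.grid_shape),
        "n_regions": spec.n_regions,
        "effects": {dx: sorted(eff.items()) for dx, eff in sorted(spec.effect_table.items())},
        "noise_cv": spec.volume_noise_cv,
    }
    return hashlib.blake2b(json.dumps(payload, sort_keys=True).encode(), digest_size=8).hexdigest()


def build_template(spec: PhantomSpec) -> PhantomTemplate:
    """Lay out head, regions and compartments for ``spec`` (cached)."""
    key = _template_key(spec)
    cached = _TEMPLATE_CACHE.get(key)
    if cached is not None:
        return cached

    regions = spec.region_table()
    shape = tuple(int(s) for s in spec.grid_shape)
    nx, ny, nz = shape
    semi = np.array([0.42 * nx, 0.45 * ny, 0.42 * nz])
    if semi.min() < 6:
        raise PhantomSizingError(f"grid {shape} leaves head semi-axes {semi} < 6 voxels")
    center = (np.array(shape) - 1) / 2.0

    ix, iy, iz = np.indices(shape)
    u = np.stack(
        [(ix - center[0]) / semi[0], (iy - center[1]) / semi[1], (iz - center[2]) / semi[2]]
    )
    norm = np.sqrt((u**2).sum(axis=0))
    head_mask = norm <= 1.0
    head_voxels = int(head_mask.sum())

    # candidate pool for region blobs: strictly interior voxels
    pool = np.flatnonzero((norm <= _REGION_NORM).ravel())
    pool_u = u.reshape(3, -1)[:, pool]

    # healthy counts and per-region claim budgets
    hemis = dict(zip(regions.frame["code"], regions.frame["hemisphere"]))
    counts, budgets = {}, {}
    for code in regions.codes:
        code = int(code)
        if code not in _LAYOUT:
            raise PhantomSizingError(f"no phantom layout for region code {code}")
        hs_vol, _, _ = _LAYOUT[code]
        n_hs = max(2, round(hs_vol / 1e4 * head_voxels))
        max_eff = max([0.0] + [eff.get(code, 0.0) for eff in spec.effect_table.values()])
        # reserve headroom for expansion effects plus ~5 sigma of noise
        budget = int(np.ceil(n_hs * (1.0 + max_eff) * (1.0 + 6.0 * spec.volume_noise_cv))) + 2
        counts[code] = n_hs
        budgets[code] = budget
    if sum(budgets.values()) > 0.6 * len(pool):
        raise PhantomSizingError(
            f"regions need {sum(budgets.values())} voxels but only {len(pool)} interior voxels exist"
        )

    # sequential claim, largest budgets first: each region takes its
    # `budget` best-ranked unclaimed voxels along its ellipsoidal field
    claimed = np.zeros(pool.size, dtype=bool)
    territories: dict[int, np.ndarray] = {}
    for code in sorted(budgets, key=lambda c: (-budgets[c], c)):
        _, (ux, uy, uz), (rx, ry, rz) = _LAYOUT[code]
        if hemis[code] == "L":
            ux = -ux
        d2 = (
            ((pool_u[0] - ux) / rx) ** 2
            + ((pool_u[1] - uy) / ry) ** 2
            + ((pool_u[2] - uz) / rz) ** 2
        )
        order = np.argsort(d2, kind="stable")
        free = order[~claimed[order]][: budgets[code]]
        if free.size < budgets[code]:
            raise PhantomSizingError(f"region {code} cannot claim {budgets[code]} voxels")
        claimed[free] = True
        territories[code] = pool[free]

    claimed_flat = np.zeros(np.prod(shape), dtype=bool)
    for t in territories.values():
        claimed_flat[t] = True

    wm_zone = (norm <= _WM_NORM).ravel() & ~claimed_flat
    wm_flat = np.flatnonzero(wm_zone)
    shell = head_mask.ravel() & (norm > _WM_NORM).ravel() & ~claimed_flat
    shell_csf_flat = np.flatnonzero(shell)

    # healthy (atlas) white matter: template WM plus the expansion
    # reserve of the ventricles (voxels beyond the healthy ventricle)
    healthy_wm = wm_zone.copy()
    vent_codes = [c for c in territories if regions.frame.set_index("code").loc[c, "mask_class"] == "CSF"]
    for c in vent_codes:
        healthy_wm[territories[c][counts[c]:]] = True

    # lesion ordering: WM voxels by distance to a seed abutting the
    # right lateral ventricle (code 45); lesions grow as a compact blob
    seed_source = 45 if 45 in territories else int(regions.codes[0])
    seed_flat = territories[seed_source][counts[seed_source] - 1]
    seed_xyz = np.array(np.unravel_index(seed_flat, shape), dtype=float)
    wm_xyz = np.stack(np.unravel_index(wm_flat, shape)).astype(float)
    d2seed = ((wm_xyz - seed_xyz[:, None]) ** 2).sum(axis=0)
    lesion_order = wm_flat[np.argsort(d2seed, kind="stable")]

    tpl = PhantomTemplate(
        spec_key=key,
        grid_shape=shape,
        head_mask=head_mask,
        head_voxels=head_voxels,
        territories=territories,
        template_counts=counts,
        wm_flat=wm_flat,
        healthy_wm_mask=healthy_wm.reshape(shape),
        shell_csf_flat=shell_csf_flat,
        lesion_order=lesion_order,
        region_table=regions,
    )
    _TEMPLATE_CACHE[key] = tpl
    return tpl


# ---------------------------------------------------------------------------
# per-subject generation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """All per-subject phantom artifacts.

    ``labels`` / ``tissue`` / ``wm_gm_mask`` are the triple every real
    target image provides; the remaining masks are ground-truth extras
    only a simulator can know (true ICV, the healthy-atlas WM mask used
    to simulate propagated atlas WM segmentations, and the injected
    lesion).
    """

    record: SubjectRecord
    labels: LabelVolume
    tissue: TissueMaps
    wm_gm_mask: BinaryMask
    icv_mask: BinaryMask
    atlas_wm_mask: BinaryMask
    lesion_mask: BinaryMask
    lesion_volume_mm3: float


def generate_subject(
    spec: PhantomSpec,
    record: SubjectRecord,
    template: PhantomTemplate | None = None,
) -> SubjectData:
    """Generate one subject's label volume, tissue maps and brain mask.

    Region voxel counts are the healthy template counts scaled by the
    diagnosis effect and lognormal inter-subject noise; the subject's
    physical size is set by scaling the voxel edge so that the head
    ellipsoid hits ``spec.icv_target``. Injected lesion voxels lie in
    the white-matter compartment adjacent to the right ventricle and
    have their GM probability raised above the WM probability.
    """
    if record.diagnosis not in spec.effect_table:
        raise KeyError(f"diagnosis {record.diagnosis!r} has no row in the effect table")
    tpl = template if template is not None else build_template(spec)
    shape = tpl.grid_shape
    nvox = int(np.prod(shape))
    rng = np.random.default_rng(subject_seed(spec.seed, record.subject_id))

    # isotropic voxel scaling realizes the target intracranial volume
    base_head_mm3 = tpl.head_voxels * float(spec.voxel_size) ** 3
    scale = (spec.icv_target / base_head_mm3) ** (1.0 / 3.0)
    vs = (spec.voxel_size * scale,) * 3
    voxel_volume = float(np.prod(vs))

    effects = spec.effect_table[record.diagnosis]
    labels_flat = np.zeros(nvox, dtype=np.int16)
    subject_counts: dict[int, int] = {}
    # draw per-region noise in fixed code order for reproducibility
    sigma = np.sqrt(np.log(1.0 + spec.volume_noise_cv**2))
    for code in sorted(tpl.territories):
        noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if spec.volume_noise_cv > 0 else 1.0
        target = tpl.template_counts[code] * (1.0 + effects.get(code, 0.0)) * noise
        n = int(np.clip(round(target), 1, tpl.territories[code].size))
        subject_counts[code] = n
        labels_flat[tpl.territories[code][:n]] = code

    # compartments
    mask_class = tpl.region_table.mask_class_map()
    vent_flat, gap_csf_flat, gap_wm_flat = [], [], []
    for code, terr in tpl.territories.items():
        n = subject_counts[code]
        if mask_class[code] == "CSF":
            vent_flat.append(terr[:n])
            gap_wm_flat.append(terr[n:])     # unexpanded ventricle reserve stays WM
        else:
            gap_csf_flat.append(terr[n:])    # atrophy gap fills with CSF
    vent_flat = np.concatenate(vent_flat) if vent_flat else np.empty(0, dtype=np.int64)
    gap_csf_flat = np.concatenate(gap_csf_flat) if gap_csf_flat else np.empty(0, dtype=np.int64)
    gap_wm_flat = np.concatenate(gap_wm_flat) if gap_wm_flat else np.empty(0, dtype=np.int64)

    wm_subject = np.concatenate([tpl.wm_flat, gap_wm_flat])

    # lesion voxels: nearest-N white-matter voxels to the ventricle seed
    n_lesion = int(round(spec.wmd_lesion_volume / voxel_volume))
    if n_lesion > tpl.lesion_order.size:
        raise PhantomSizingError(
            f"requested lesion volume {spec.wmd_lesion_volume} mm^3 exceeds the "
            f"white-matter compartment ({tpl.lesion_order.size * voxel_volume:.0f} mm^3)"
        )
    lesion_flat = tpl.lesion_order[:n_lesion]
    lesion_mask_flat = np.zeros(nvox, dtype=bool)
    lesion_mask_flat[lesion_flat] = True

    # tissue probabilities (dominant channel ~0.9 with mild noise)
    csf = np.zeros(nvox, dtype=np.float32)
    gm = np.zeros(nvox, dtype=np.float32)
    wm = np.zeros(nvox, dtype=np.float32)

    def _dominant(dst, idx):
        dst[idx] = 0.86 + 0.08 * rng.random(idx.size)

    gm_like = labels_flat > 0
    gm_like[vent_flat] = False
    _dominant(csf, tpl.shell_csf_flat)
    _dominant(csf, vent_flat)
    _dominant(csf, gap_csf_flat)
    _dominant(wm, wm_subject)
    _dominant(gm, np.flatnonzero(gm_like))
    gm[wm_subject] = 0.04
    # lesion: hypointense WM classifies as gray matter
    gm[lesion_flat] = 0.52 + 0.06 * rng.random(lesion_flat.size)
    wm[lesion_flat] = 0.30 + 0.04 * rng.random(lesion_flat.size)

    s_b_flat = np.zeros(nvox, dtype=bool)
    s_b_flat[wm_subject] = True
    s_b_flat[np.flatnonzero(gm_like)] = True

    data = SubjectData(
        record=record,
        labels=LabelVolume(labels_flat.reshape(shape), vs, code_table_ref="phantom-default"),
        tissue=TissueMaps(csf.reshape(shape), gm.reshape(shape), wm.reshape(shape), vs),
        wm_gm_mask=BinaryMask(s_b_flat.reshape(shape), vs),
        icv_mask=BinaryMask(tpl.head_mask.copy(), vs),
        atlas_wm_mask=BinaryMask(tpl.healthy_wm_mask.copy(), vs),
        lesion_mask=BinaryMask(lesion_mask_flat.reshape(shape), vs),
        lesion_volume_mm3=n_lesion * voxel_volume,
    )
    return data


# ---------------------------------------------------------------------------
# simulated atlas candidates
# ---------------------------------------------------------------------------

def perturb_atlas_labels(
    truth: LabelVolume,
    n_atlases: int,
    jitter: float,
    seed: int,
) -> list[LabelVolume]:
    """Simulate propagated atlas segmentations by boundary jitter.

    Each candidate equals ``truth`` except on the 1-voxel shell around
    region boundaries, where every voxel independently flips with
    probability ``jitter`` to the code of a uniformly chosen differing
    6-neighbor. Interior voxels never change, so majority vote recovers
    the truth in expectation for ``jitter < 0.5``.
    """
    if n_atlases < 2:
        raise ValueError(f"n_atlases must be >= 2 (vote fusion needs candidates), got {n_atlases}")
    if not 0.0 <= jitter < 0.5:
        raise ValueError(f"jitter must satisfy 0 <= jitter < 0.5, got {jitter}")

    grid = truth.grid
    neighbors = _face_neighbors(grid)              # (6, *shape)
    boundary = (neighbors != grid[None]).any(axis=0)
    b_idx = np.flatnonzero(boundary.ravel())
    nb = neighbors.reshape(6, -1)[:, b_idx]        # (6, n_boundary)
    own = grid.ravel()[b_idx]
    differs = nb != own[None]

    out = []
    streams = np.random.SeedSequence(seed).spawn(n_atlases)
    for ss in streams:
        rng = np.random.default_rng(ss)
        flip = rng.random(b_idx.size) < jitter
        new_flat = grid.ravel().copy()
        if flip.any():
            scores = rng.random((6, b_idx.size))
            scores[~differs] = -1.0
            choice = scores.argmax(axis=0)
            new_codes = nb[choice, np.arange(b_idx.size)]
            new_flat[b_idx[flip]] = new_codes[flip]
        out.append(LabelVolume(new_flat.reshape(grid.shape), truth.voxel_size, truth.code_table_ref))
    return out


def perturb_binary_mask(mask: BinaryMask, n_atlases: int, jitter: float, seed: int) -> list[BinaryMask]:
    """Boundary-jittered copies of a binary mask (0/1 treated as codes)."""
    as_labels = LabelVolume(mask.grid.astype(np.int16), mask.voxel_size)
    return [
        BinaryMask(lv.grid.astype(bool), mask.voxel_size)
        for lv in perturb_atlas_labels(as_labels, n_atlases, jitter, seed)
    ]


def _face_neighbors(grid: np.ndarray) -> np.ndarray:
    """Stack of the 6 face-neighbor grids, edge-replicated (no wrap)."""
    out = np.empty((6,) + grid.shape, dtype=grid.dtype)
    k = 0
    for axis in range(3):
        for shift in (-1, 1):
            padded = np.pad(grid, [(1, 1) if a == axis else (0, 0) for a in range(3)], mode="edge")
            sl = [slice(None)] * 3
            sl[axis] = slice(1 + shift, grid.shape[axis] + 1 + shift)
            out[k] = padded[tuple(sl)]
            k += 1
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: PhantomSpec,
    n_per_group: dict[str, int],
    seed: int | None = None,
    lesion_volume_sampler=None,
    field_strength: float = 1.5,
) -> tuple[list[SubjectRecord], dict[str, SubjectData]]:
    """Generate a full cohort of synthetic subjects.

    Per subject, the intracranial volume is drawn from the cohort ICV
    distribution (normal, mean 1.41 l, SD 0.143 l, truncated to
    1.0-1.9 l) and region volumes scale with it before group effects
    apply (voxel-size scaling). ``lesion_volume_sampler(rng) -> mm^3``
    optionally draws a per-subject WMD load; otherwise every subject
    uses ``spec.wmd_lesion_volume``.
    """
    counts = {dx: int(n) for dx, n in n_per_group.items() if int(n) > 0}
    unknown = set(counts) - set(DIAGNOSES)
    if unknown:
        raise ValueError(f"unknown diagnosis groups {sorted(unknown)}")
    if not counts:
        raise ValueError("n_per_group must request at least one subject")

    root = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(root)
    template = build_template(spec)

    records: list[SubjectRecord] = []
    data: dict[str, SubjectData] = {}
    for dx in DIAGNOSES:
        for i in range(counts.get(dx, 0)):
            sid = f"{dx}-{i:03d}"
            gender = GENDERS[int(rng.integers(2))]
            icv = float(rng.normal(ICV_MEAN_MM3, ICV_SD_MM3))
            while not ICV_RANGE_MM3[0] <= icv <= ICV_RANGE_MM3[1]:
                icv = float(rng.normal(ICV_MEAN_MM3, ICV_SD_MM3))
            lesion = (
                float(lesion_volume_sampler(rng))
                if lesion_volume_sampler is not None
                else spec.wmd_lesion_volume
            )
            sub_spec = dataclasses.replace(
                spec, icv_target=icv, wmd_lesion_volume=lesion, seed=root
            )
            record = SubjectRecord(
                subject_id=sid,
                diagnosis=dx,
                gender=gender,
                field_strength=field_strength,
                image_ids=(f"I{sid}",),
            )
            records.append(record)
            data[sid] = generate_subject(sub_spec, record, template=template)
    return records, data
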