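"""Configuration and the end-to-end pipeline driver.

The driver chains every stage on a synthetic cohort: phantom generation
-> simulated atlas candidates -> vote fusion -> tissue discretization and
intracranial mask -> tissue-class masking -> volumetry and asymmetry ->
WMD indexing -> outlier QC and group statistics. It emits five CSV
reports (volumes, asymmetry, wmhi, outliers, group_tests) plus a
provenance JSON; every report embeds the configuration hash and re-runs
with identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BinaryMask
from .fusion import bisection_precision, fuse_binary, vote_fuse
from .masks import build_icv_mask, discretize_tissue, mask_labels
from .morphometry import aggregate_superregions, asymmetry_indices, measure_volumes
from .phantom import (
    DIAGNOSES,
    PhantomSpec,
    generate_cohort,
    perturb_atlas_labels,
    perturb_binary_mask,
    subject_seed,
)
from .qc_stats import flag_outliers, group_test_matrix, tost_equivalence
from .wmhi import compute_wmd_mask, wmhi_index
from .io import write_report_csv

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "config_hash"]

log = logging.getLogger("atlasmorph")

REPORT_FILES = ("volumes.csv", "asymmetry.csv", "wmhi.csv", "outliers.csv", "group_tests.csv")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending image."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one serializable object."""

    # cohort / phantom
    n_per_group: dict[str, int] = field(default_factory=lambda: {"HS": 4, "AD": 4})
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: float = 3.0
    n_regions: int = 25
    volume_noise_cv: float = 0.06
    lesion_zero_fraction: float = 0.15
    lesion_median_mm3: float = 2500.0
    lesion_sigma: float = 1.0
    # atlas simulation / fusion
    n_atlases: int = 30
    jitter: float = 0.2
    fusion_mode: str = "all"
    # intracranial mask
    sigma_mm: float = 6.0
    threshold: float = 0.27
    kernel_is_fwhm: bool = False
    # wmd index
    wmhi_scale: float = 1.0e4
    # statistics
    outlier_z: float = 4.0
    tost_alpha: float = 0.05
    tost_epsilon_frac: float = 0.05
    group_pairings: list[tuple[str, str]] | None = None
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")
        if not 0.0 < self.tost_alpha < 1.0:
            raise ValueError("tost_alpha must be in (0, 1)")
        if self.tost_epsilon_frac <= 0:
            raise ValueError("tost_epsilon_frac must be positive")
        if self.fusion_mode not in ("all", "foreground"):
            raise ValueError(f"fusion_mode must be 'all' or 'foreground', got {self.fusion_mode}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if self.group_pairings is not None:
            d["group_pairings"] = [list(p) for p in self.group_pairings]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if d.get("group_pairings") is not None:
            d["group_pairings"] = [tuple(p) for p in d["group_pairings"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def _lesion_sampler(config: PipelineConfig):
    """Skewed per-subject WMD load: mostly small, some zero, long tail."""

    def sample(rng: np.random.Generator) -> float:
        if rng.random() < config.lesion_zero_fraction:
            return 0.0
        return float(rng.lognormal(np.log(config.lesion_median_mm3), config.lesion_sigma))

    return sample


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Returns a dict with the in-memory report DataFrames plus metadata.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    log.info(
        "pipeline start: sigma_mm=%s threshold=%s SE=3x3x3 outlier_z=%s "
        "tost(alpha=%s, epsilon_frac=%s) wmhi_scale=%s n_atlases=%s jitter=%s seed=%s config=%s",
        config.sigma_mm, config.threshold, config.outlier_z, config.tost_alpha,
        config.tost_epsilon_frac, config.wmhi_scale, config.n_atlases, config.jitter,
        config.seed, chash,
    )

    spec = PhantomSpec(
        grid_shape=config.grid_shape,
        voxel_size=config.voxel_size_mm,
        n_regions=config.n_regions,
        seed=config.seed,
        volume_noise_cv=config.volume_noise_cv,
    )
    regions = spec.region_table()
    records, cohort_data = generate_cohort(
        spec, config.n_per_group, seed=config.seed, lesion_volume_sampler=_lesion_sampler(config)
    )

    csf_codes = [int(c) for c, m in regions.mask_class_map().items() if m == "CSF"]
    vol_frames, wmhi_rows = [], []
    fused_first = None
    candidates_first = None
    for rec in records:
        sid = rec.subject_id
        image_id = rec.image_ids[0]
        sub = cohort_data[sid]
        stage = "atlas-simulation"
        try:
            atlas_seed = subject_seed(config.seed + 1_000_003, sid)
            candidates = perturb_atlas_labels(sub.labels, config.n_atlases, config.jitter, atlas_seed)
            stage = "fusion"
            fused = vote_fuse(candidates, mode=config.fusion_mode)
            if fused_first is None:
                fused_first, candidates_first = fused, candidates
            stage = "tissue-discretization"
            csf_m, gm_m, wm_m = discretize_tissue(sub.tissue)
            stage = "icv-mask"
            icv = build_icv_mask(
                sub.wm_gm_mask, csf_m,
                sigma_mm=config.sigma_mm, threshold=config.threshold,
                kernel_is_fwhm=config.kernel_is_fwhm,
            )
            stage = "tissue-masking"
            masked = mask_labels(fused, gm_m, csf_m, regions)
            stage = "volumetry"
            vol_frames.append(measure_volumes(masked, icv, regions, sid, image_id))
            stage = "wmd-index"
            m_w = fuse_binary(
                perturb_binary_mask(sub.atlas_wm_mask, config.n_atlases, config.jitter, atlas_seed)
            )
            m_v = BinaryMask(np.isin(fused.grid, csf_codes), fused.voxel_size)
            res = compute_wmd_mask(m_w, gm_m, m_v, sub.wm_gm_mask)
            res = wmhi_index(res, icv, scale=config.wmhi_scale)
            wmhi_rows.append(
                {
                    "subject_id": sid,
                    "image_id": image_id,
                    "wmhi": res.wmhi,
                    "vol_A_mm3": res.A.volume_mm3(),
                    "vol_B_mm3": res.B.volume_mm3(),
                    "icv_mm3": res.icv_mm3,
                    "injected_lesion_mm3": sub.lesion_volume_mm3,
                }
            )
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {stage!r} failed for image {image_id}: {exc}") from exc

    vols = pd.concat(vol_frames, ignore_index=True)
    wmhi_df = pd.DataFrame(wmhi_rows)
    asym = asymmetry_indices(vols, regions)
    superregions = aggregate_superregions(vols, regions)
    outliers = flag_outliers(vols, records, z_cutoff=config.outlier_z)
    outlier_df = pd.DataFrame(
        [dataclasses.asdict(f) for f in outliers.flags],
        columns=["image_id", "region_code", "z", "flagged"],
    )

    present = [dx for dx in DIAGNOSES if config.n_per_group.get(dx, 0) >= 2]
    pairings = config.group_pairings or [
        (a, b) for i, a in enumerate(present) for b in present[i + 1:]
    ]
    tests = group_test_matrix(vols, records, pairings)
    p_wide = tests.p.reset_index()

    # ICV equivalence across groups (per printed analysis protocol)
    tost_rows = []
    icv_by_group = {
        dx: vols[vols["subject_id"].str.startswith(dx)].groupby("image_id")["icv_mm3"].first()
        for dx in present
    }
    for a, b in pairings:
        try:
            r = tost_equivalence(
                icv_by_group[a], icv_by_group[b],
                alpha=config.tost_alpha, epsilon_frac=config.tost_epsilon_frac,
            )
            tost_rows.append({"pairing": f"{a}_vs_{b}", "p": r.p, "equivalent": r.equivalent})
        except ValueError:
            continue

    result = {
        "config_hash": chash,
        "volumes": vols,
        "asymmetry": asym,
        "superregions": superregions,
        "wmhi": wmhi_df,
        "outliers": outlier_df,
        "outlier_warnings": outliers.warnings,
        "group_tests": tests,
        "icv_tost": pd.DataFrame(tost_rows, columns=["pairing", "p", "equivalent"]),
    }
    if candidates_first is not None and config.n_atlases % 2 == 0 and config.n_atlases >= 4:
        bis = bisection_precision(candidates_first, seed=config.seed, mode=config.fusion_mode)
        result["bisection_jc_m"] = bis.jc_m

    write_report_csv(vols, out / "volumes.csv", chash)
    write_report_csv(asym, out / "asymmetry.csv", chash)
    write_report_csv(wmhi_df, out / "wmhi.csv", chash)
    write_report_csv(outlier_df, out / "outliers.csv", chash)
    write_report_csv(p_wide, out / "group_tests.csv", chash)

    provenance = {
        "config": config.to_dict(),
        "config_hash": chash,
        "version": __version__,
        "numpy": np.__version__,
        "n_subjects": len(records),
        "bisection_jc_m": result.get("bisection_jc_m"),
        "icv_tost": tost_rows,
        "outlier_warnings": outliers.warnings,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    log.info("pipeline done: %d subjects, reports in %s", len(records), out)
    return result
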