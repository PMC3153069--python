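"""Quality control and statistics on cohort volumetry.

Covers four independent concerns:

* **Outlier flagging** — normalized region volumes are converted to z
  scores within (diagnosis, gender, field strength) strata; regions with
  z strictly greater than 4 or strictly less than -4 are flagged for
  visual review (segmentation failures produce grossly wrong volumes).
* **Segmentation agreement** — per-region Jaccard (|A∩B|/|A∪B|) and Dice
  (2|A∩B|/(|A|+|B|)) between two co-gridded label volumes, plus the
  mean Jaccard over regions (JC_m) and its dispersion across subjects.
* **Group comparisons** — Welch unpaired two-tailed t-tests per region
  between selected diagnosis-group pairings. Raw p-values are reported:
  they rank regions against each other rather than test hypotheses, so
  no multiple-comparison correction is applied by default.
* **Equivalence testing** — two one-sided tests (TOST) on a group-mean
  difference with margin epsilon expressed as a fraction of the pooled
  mean (default 5%).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats import weightstats as _smw

from .containers import LabelVolume, check_same_geometry

__all__ = [
    "OutlierFlag",
    "OutlierReport",
    "AgreementReport",
    "GroupTestResult",
    "TostResult",
    "DEFAULT_Z_CUTOFF",
    "flag_outliers",
    "pairwise_agreement",
    "agreement_dispersion",
    "jc_to_dsc",
    "group_test_matrix",
    "tost_equivalence",
]

#: |z| beyond which a region volume is flagged (strict inequality)
DEFAULT_Z_CUTOFF = 4.0


# ---------------------------------------------------------------------------
# outlier flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierFlag:
    image_id: str
    region_code: int
    z: float
    flagged: bool


@dataclass
class OutlierReport:
    flags: list[OutlierFlag]
    warnings: list[str] = field(default_factory=list)


def _cohort_frame(cohort) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "diagnosis": rec.diagnosis,
                "gender": rec.gender,
                "field_strength": rec.field_strength,
            }
        )
    return pd.DataFrame(rows)


def flag_outliers(vols: pd.DataFrame, cohort, z_cutoff: float = DEFAULT_Z_CUTOFF) -> OutlierReport:
    """Flag region volumes with |z| > ``z_cutoff`` within their stratum.

    Strata are (diagnosis, gender, field strength); z scores use the
    per-stratum mean and sample SD (ddof=1) of the normalized volume.
    Strata with fewer than 3 images or zero SD produce no flags and are
    reported on the warnings channel instead.
    """
    meta = _cohort_frame(cohort)
    df = vols.merge(meta, on="subject_id", how="left", validate="many_to_one")
    orphans = df.loc[df["diagnosis"].isna(), "subject_id"].unique()
    if len(orphans):
        raise KeyError(f"images without cohort records: {sorted(map(str, orphans))}")
    flags: list[OutlierFlag] = []
    warn: list[str] = []
    strat_keys = ["diagnosis", "gender", "field_strength", "region_code"]
    for key, grp in df.groupby(strat_keys, sort=True):
        values = grp["normalized"].to_numpy(dtype=float)
        n = len(values)
        if n < 3:
            warn.append(f"stratum {key}: n={n} < 3, no z-scores computed")
            continue
        sd = values.std(ddof=1)
        if sd == 0:
            warn.append(f"stratum {key}: zero variance, no z-scores computed")
            continue
        z = (values - values.mean()) / sd
        hit = np.abs(z) > z_cutoff
        for image_id, code, zi in zip(grp["image_id"][hit], grp["region_code"][hit], z[hit]):
            flags.append(OutlierFlag(str(image_id), int(code), float(zi), True))
    flags.sort(key=lambda f: (f.image_id, f.region_code))
    return OutlierReport(flags=flags, warnings=warn)


# ---------------------------------------------------------------------------
# agreement metrics
# ---------------------------------------------------------------------------

def jc_to_dsc(jc: float) -> float:
    """Dice coefficient corresponding to a Jaccard coefficient.

    ``D = 2J / (1 + J)``; monotone on [0, 1] with fixed points 0 and 1
    (e.g. a mean JC of 0.802 corresponds to a DSC of 0.890).
    """
    jc = float(jc)
    if not 0.0 <= jc <= 1.0:
        raise ValueError(f"Jaccard coefficient must be in [0, 1], got {jc}")
    return 2.0 * jc / (1.0 + jc)


@dataclass
class AgreementReport:
    """Per-region overlap between two segmentations of the same head.

    ``per_region`` has one row per code present in either volume, with
    columns ``jc`` and ``dsc``; ``jc_m`` is the unweighted mean JC over
    those regions (both-empty regions are undefined 0/0 and excluded —
    they never appear in the union of present codes).
    """

    per_region: pd.DataFrame
    jc_m: float


def pairwise_agreement(a: LabelVolume, b: LabelVolume) -> AgreementReport:
    """Jaccard and Dice per region between two co-gridded label volumes."""
    check_same_geometry(a, b)
    codes = np.union1d(a.codes(), b.codes())
    rows = []
    for code in codes:
        in_a = a.grid == code
        in_b = b.grid == code
        inter = int((in_a & in_b).sum())
        union = int(in_a.sum()) + int(in_b.sum()) - inter
        jc = inter / union if union else np.nan
        dsc = 2.0 * inter / (in_a.sum() + in_b.sum()) if union else np.nan
        rows.append({"region_code": int(code), "jc": jc, "dsc": dsc})
    per_region = pd.DataFrame(rows, columns=["region_code", "jc", "dsc"]).set_index("region_code")
    jc_m = float(per_region["jc"].mean()) if len(per_region) else np.nan
    return AgreementReport(per_region=per_region, jc_m=jc_m)


def agreement_dispersion(reports: list[AgreementReport]) -> pd.DataFrame:
    """Across-subject spread of per-region JC from several report pairs.

    Returns, per region code, the mean JC and its standard deviation
    expressed as a percentage of the mean (the per-region consistency
    figure used to compare acquisitions).
    """
    if not reports:
        return pd.DataFrame(columns=["jc_mean", "jc_sigma_pct"])
    wide = pd.concat([r.per_region["jc"] for r in reports], axis=1)
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    out = pd.DataFrame({"jc_mean": mean, "jc_sigma_pct": 100.0 * sd / mean})
    out.index.name = "region_code"
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Per-region Welch t-test p/t matrices over diagnosis-group pairings.

    ``p`` and ``t`` are DataFrames indexed by region code with one column
    per pairing (named "A_vs_B"); ``rank`` holds the column-wise rank of
    p (1 = most significant), for heatmap rendering.
    """

    p: pd.DataFrame
    t: pd.DataFrame
    rank: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def group_test_matrix(
    vols: pd.DataFrame,
    cohort,
    pairings: list[tuple[str, str]],
) -> GroupTestResult:
    """Welch unpaired two-tailed t-tests per region and group pairing.

    Raw (uncorrected) p-values; pairings where either group has fewer
    than 2 images are skipped with a warning.
    """
    meta = _cohort_frame(cohort)
    df = vols.merge(meta, on="subject_id", how="left", validate="many_to_one")
    codes = sorted(df["region_code"].unique())
    p = {}
    t = {}
    warn: list[str] = []
    for g1, g2 in pairings:
        col = f"{g1}_vs_{g2}"
        x_all = df[df["diagnosis"] == g1]
        y_all = df[df["diagnosis"] == g2]
        n1 = x_all["image_id"].nunique()
        n2 = y_all["image_id"].nunique()
        if n1 < 2 or n2 < 2:
            warn.append(f"pairing {col}: group sizes {n1}/{n2} < 2, skipped")
            continue
        p_col, t_col = [], []
        for code in codes:
            x = x_all.loc[x_all["region_code"] == code, "normalized"].to_numpy(dtype=float)
            y = y_all.loc[y_all["region_code"] == code, "normalized"].to_numpy(dtype=float)
            res = sp_stats.ttest_ind(x, y, equal_var=False)
            t_col.append(float(res.statistic))
            p_col.append(float(res.pvalue))
        p[col] = p_col
        t[col] = t_col
    index = pd.Index(codes, name="region_code")
    p_df = pd.DataFrame(p, index=index)
    t_df = pd.DataFrame(t, index=index)
    rank = p_df.rank(axis=0, method="min")
    return GroupTestResult(p=p_df, t=t_df, rank=rank, warnings=warn)


# ---------------------------------------------------------------------------
# equivalence testing
# ---------------------------------------------------------------------------

@dataclass
class TostResult:
    p: float
    equivalent: bool
    epsilon: float
    alpha: float


def tost_equivalence(
    x,
    y,
    alpha: float = 0.05,
    epsilon_frac: float = 0.05,
) -> TostResult:
    """Two one-sided tests of mean equivalence between two samples.

    The margin is ``epsilon = epsilon_frac * |pooled mean|`` (pooled over
    both samples). Both one-sided Welch tests of the mean difference
    against -epsilon and +epsilon must reject; the reported p is the
    larger of the two, and ``equivalent`` is ``p < alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if epsilon_frac <= 0:
        raise ValueError("epsilon_frac must be positive")
    pooled_mean = np.concatenate([x, y]).mean()
    if pooled_mean == 0:
        raise ValueError("pooled mean is zero; fractional equivalence margin undefined")
    eps = epsilon_frac * abs(pooled_mean)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        p, _, _ = _smw.ttost_ind(x, y, -eps, eps, usevar="unequal")
    p = float(p)
    return TostResult(p=p, equivalent=bool(p < alpha), epsilon=float(eps), alpha=float(alpha))
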