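"""Outlier flagging, agreement metrics, group tests and TOST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from atlasmorph.containers import LabelVolume
from atlasmorph.phantom import SubjectRecord
from atlasmorph.qc_stats import (
    agreement_dispersion,
    flag_outliers,
    group_test_matrix,
    jc_to_dsc,
    pairwise_agreement,
    tost_equivalence,
)

from conftest import random_label_volume


def _cohort(values_by_subject, diagnosis="HS"):
    return [
        SubjectRecord(sid, diagnosis, "F", 1.5, (f"I{sid}",))
        for sid in values_by_subject
    ]


def _volume_table(values_by_subject, code=1):
    rows = []
    for sid, v in values_by_subject.items():
        rows.append(
            {"subject_id": sid, "image_id": f"I{sid}", "region_code": code,
             "raw_mm3": v, "normalized": v, "icv_mm3": 1.0}
        )
    return pd.DataFrame(rows)


class TestFlagOutliers:
    def test_extreme_value_flagged(self):
        # 20 values at 100 plus one at 150: z ~ 4.37 > 4
        values = {f"s{i}": 100.0 for i in range(20)}
        values["s_out"] = 150.0
        report = flag_outliers(_volume_table(values), _cohort(values))
        assert [f.image_id for f in report.flags] == ["Is_out"]
        assert report.flags[0].z == pytest.approx(4.37, abs=0.01)

    def test_strict_inequality_at_the_cutoff(self):
        # one deviant among n constants gives z = n/sqrt(n+1):
        # n=16 -> z=3.88 (not flagged), n=17 -> z=4.007 (flagged)
        for n, expect in ((16, 0), (17, 1)):
            values = {f"s{i}": 10.0 for i in range(n)}
            values["dev"] = 20.0
            report = flag_outliers(_volume_table(values), _cohort(values))
            assert len(report.flags) == expect, f"n={n}"
            if expect:
                assert report.flags[0].z == pytest.approx(n / np.sqrt(n + 1))

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(0)
        values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(50, 5, 30))}
        values["big"] = 120.0
        base = flag_outliers(_volume_table(values), _cohort(values))
        scaled = {k: 3.0 * v + 7.0 for k, v in values.items()}
        again = flag_outliers(_volume_table(scaled), _cohort(scaled))
        assert [(f.image_id, round(f.z, 10)) for f in base.flags] == [
            (f.image_id, round(f.z, 10)) for f in again.flags
        ]

    def test_degenerate_strata_warn_instead_of_flagging(self):
        constant = {f"s{i}": 5.0 for i in range(6)}
        report = flag_outliers(_volume_table(constant), _cohort(constant))
        assert not report.flags
        assert any("zero variance" in w for w in report.warnings)
        tiny = {"a": 1.0, "b": 2.0}
        report = flag_outliers(_volume_table(tiny), _cohort(tiny))
        assert not report.flags
        assert any("n=2" in w for w in report.warnings)

    def test_unjoined_image_rejected(self):
        vols = _volume_table({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(KeyError, match="without cohort"):
            flag_outliers(vols, _cohort({"a": 1.0, "b": 2.0}))


class TestPairwiseAgreement:
    def test_identity_gives_unity(self):
        rng = np.random.default_rng(1)
        vol = random_label_volume(rng)
        report = pairwise_agreement(vol, vol.copy())
        assert report.jc_m == pytest.approx(1.0)
        assert (report.per_region["dsc"] == 1.0).all()

    def test_disjoint_maps_give_zero(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        b = np.zeros((4, 4, 4), dtype=np.int16)
        a[0], b[1] = 1, 1
        report = pairwise_agreement(LabelVolume(a, 1.0), LabelVolume(b, 1.0))
        assert report.per_region.loc[1, "jc"] == 0.0
        assert report.per_region.loc[1, "dsc"] == 0.0
        assert report.jc_m == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_set_arithmetic_oracle_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = random_label_volume(rng, n_codes=3)
        b = random_label_volume(rng, n_codes=3)
        fwd = pairwise_agreement(a, b)
        rev = pairwise_agreement(b, a)
        for code in fwd.per_region.index:
            sa = set(map(tuple, np.argwhere(a.grid == code)))
            sb = set(map(tuple, np.argwhere(b.grid == code)))
            jc = len(sa & sb) / len(sa | sb)
            dsc = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert fwd.per_region.loc[code, "jc"] == pytest.approx(jc, abs=1e-12)
            assert fwd.per_region.loc[code, "dsc"] == pytest.approx(dsc, abs=1e-12)
        assert fwd.jc_m == pytest.approx(rev.jc_m)

    def test_dice_jaccard_identity_per_row(self):
        rng = np.random.default_rng(9)
        a = random_label_volume(rng, n_codes=4)
        b = random_label_volume(rng, n_codes=4)
        report = pairwise_agreement(a, b)
        for _, row in report.per_region.iterrows():
            assert row["dsc"] == pytest.approx(jc_to_dsc(row["jc"]), abs=1e-12)

    def test_dispersion_across_subjects(self):
        rng = np.random.default_rng(3)
        reports = []
        for _ in range(5):
            a = random_label_volume(rng, n_codes=2)
            b = random_label_volume(rng, n_codes=2)
            reports.append(pairwise_agreement(a, b))
        disp = agreement_dispersion(reports)
        jcs = np.array([r.per_region.loc[1, "jc"] for r in reports])
        assert disp.loc[1, "jc_mean"] == pytest.approx(jcs.mean())
        assert disp.loc[1, "jc_sigma_pct"] == pytest.approx(100 * jcs.std(ddof=1) / jcs.mean())


class TestJcToDsc:
    @pytest.mark.parametrize(
        "jc,dsc",
        [(0.802, 0.890), (0.691, 0.817), (0.800, 0.889), (0.0, 0.0), (1.0, 1.0)],
    )
    def test_known_correspondences(self, jc, dsc):
        assert round(jc_to_dsc(jc), 3) == dsc

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            jc_to_dsc(1.2)
        with pytest.raises(ValueError):
            jc_to_dsc(-0.1)


def _two_group_cohort(x, y):
    records, rows = [], []
    for name, dx, sample in (("h", "HS", x), ("a", "AD", y)):
        for i, v in enumerate(sample):
            sid = f"{name}{i}"
            records.append(SubjectRecord(sid, dx, "M", 1.5, (f"I{sid}",)))
            rows.append(
                {"subject_id": sid, "image_id": f"I{sid}", "region_code": 1,
                 "raw_mm3": v, "normalized": v, "icv_mm3": 1.0}
            )
    return records, pd.DataFrame(rows)


class TestGroupTestMatrix:
    def test_identical_groups_give_p_one(self):
        sample = [10.0, 11.0, 12.0, 13.0]
        records, vols = _two_group_cohort(sample, sample)
        res = group_test_matrix(vols, records, [("HS", "AD")])
        assert res.t.loc[1, "HS_vs_AD"] == pytest.approx(0.0)
        assert res.p.loc[1, "HS_vs_AD"] == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 2, 12)
        y = rng.normal(12, 3, 17)
        records, vols = _two_group_cohort(x, y)
        res = group_test_matrix(vols, records, [("HS", "AD")])
        # independent closed-form Welch oracle
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * sp_stats.t.sf(abs(t), df)
        assert res.t.loc[1, "HS_vs_AD"] == pytest.approx(t, abs=1e-8)
        assert res.p.loc[1, "HS_vs_AD"] == pytest.approx(p, abs=1e-8)

    def test_small_group_skipped_with_warning(self):
        records, vols = _two_group_cohort([1.0, 2.0, 3.0], [5.0])
        res = group_test_matrix(vols, records, [("HS", "AD")])
        assert res.p.empty
        assert any("skipped" in w for w in res.warnings)


class TestTostEquivalence:
    def test_identical_large_samples_are_equivalent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(100, 5, 200)
        res = tost_equivalence(x, x.copy(), alpha=0.05, epsilon_frac=0.05)
        assert res.equivalent and res.p < 1e-6

    def test_shift_at_margin_is_not_equivalent(self):
        rng = np.random.default_rng(6)
        x = rng.normal(100, 1, 400)
        y = x + 0.05 * np.concatenate([x, x + 0.05 * x]).mean()  # ~ shift of epsilon
        res = tost_equivalence(x, y, alpha=0.05, epsilon_frac=0.05)
        assert not res.equivalent
        assert res.p > 0.4  # boundary: one-sided p near 0.5

    def test_matches_independent_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.normal(50, 4, 25)
        y = rng.normal(51, 5, 30)
        eps_frac = 0.05
        res = tost_equivalence(x, y, epsilon_frac=eps_frac)
        # independently coded one-sided Welch tests against +-epsilon
        eps = eps_frac * abs(np.concatenate([x, y]).mean())
        d = x.mean() - y.mean()
        se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_lower = sp_stats.t.sf((d + eps) / se, df)     # H0: d <= -eps
        p_upper = sp_stats.t.cdf((d - eps) / se, df)    # H0: d >= +eps
        assert res.p == pytest.approx(max(p_lower, p_upper), abs=1e-8)
        assert res.epsilon == pytest.approx(eps)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            tost_equivalence([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="pooled mean"):
            tost_equivalence([-1.0, 1.0], [-2.0, 2.0])
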