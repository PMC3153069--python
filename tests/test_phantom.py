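"""Synthetic phantom generator: determinism, volume control, lesions,
atlas jitter and cohort structure."""

import dataclasses

import numpy as np
import pytest

from atlasmorph.fusion import vote_fuse
from atlasmorph.masks import discretize_tissue
from atlasmorph.morphometry import measure_volumes
from atlasmorph.phantom import (
    ICV_RANGE_MM3,
    PhantomSizingError,
    PhantomSpec,
    SubjectRecord,
    build_template,
    generate_cohort,
    generate_subject,
    perturb_atlas_labels,
    subject_seed,
)
from atlasmorph.qc_stats import group_test_matrix


def _record(sid="HS-000", dx="HS"):
    return SubjectRecord(sid, dx, "F", 1.5, (f"I{sid}",))


class TestGenerateSubject:
    def test_bit_identical_under_same_seed(self, small_spec):
        a = generate_subject(small_spec, _record())
        b = generate_subject(small_spec, _record())
        assert np.array_equal(a.labels.grid, b.labels.grid)
        assert np.array_equal(a.tissue.gm, b.tissue.gm)
        assert np.array_equal(a.wm_gm_mask.grid, b.wm_gm_mask.grid)
        c = generate_subject(dataclasses.replace(small_spec, seed=99), _record())
        assert not np.array_equal(a.labels.grid, c.labels.grid)

    def test_effect_scales_region_volume(self, small_spec):
        """-20% hippocampus yields a volume within 5% of 0.8x healthy."""
        spec = dataclasses.replace(
            small_spec,
            volume_noise_cv=0.0,
            effect_table={"HS": {}, "AD": {2: -0.20}},
        )
        tpl = build_template(spec)
        hs = generate_subject(spec, _record())
        ad = generate_subject(spec, _record("AD-000", "AD"))
        vox = hs.labels.voxel_volume
        hs_vol = (hs.labels.grid == 2).sum() * vox
        ad_vol = (ad.labels.grid == 2).sum() * vox
        assert hs_vol == pytest.approx(tpl.template_counts[2] * vox)
        assert ad_vol == pytest.approx(0.8 * hs_vol, rel=0.05)

    def test_icv_target_met_and_volumes_scale_with_it(self, small_spec):
        for icv in (1.1e6, 1.8e6):
            spec = dataclasses.replace(small_spec, icv_target=icv, volume_noise_cv=0.0)
            sub = generate_subject(spec, _record())
            assert sub.icv_mask.volume_mm3() == pytest.approx(icv, rel=1e-6)
        small = generate_subject(
            dataclasses.replace(small_spec, icv_target=1.1e6, volume_noise_cv=0.0), _record()
        )
        large = generate_subject(
            dataclasses.replace(small_spec, icv_target=1.8e6, volume_noise_cv=0.0), _record()
        )
        v_small = (small.labels.grid == 1).sum() * small.labels.voxel_volume
        v_large = (large.labels.grid == 1).sum() * large.labels.voxel_volume
        assert v_large / v_small == pytest.approx(1.8 / 1.1, rel=1e-6)

    def test_no_lesion_means_no_gm_over_wm_inside_wm(self, small_spec):
        sub = generate_subject(dataclasses.replace(small_spec, wmd_lesion_volume=0.0), _record())
        tpl = build_template(small_spec)
        wm_compartment = np.zeros(sub.labels.grid.size, dtype=bool)
        wm_compartment[tpl.wm_flat] = True
        gm_gt_wm = (sub.tissue.gm > sub.tissue.wm).ravel()
        assert not (gm_gt_wm & wm_compartment).any()
        assert sub.lesion_mask.count() == 0

    def test_lesion_volume_and_placement(self, small_spec):
        spec = dataclasses.replace(small_spec, wmd_lesion_volume=2.0e4)
        sub = generate_subject(spec, _record("AD-001", "AD"))
        vox = sub.labels.voxel_volume
        assert sub.lesion_mask.volume_mm3() == pytest.approx(2.0e4, abs=vox)
        # every lesion voxel is in the white-matter compartment...
        tpl = build_template(small_spec)
        lesion_flat = np.flatnonzero(sub.lesion_mask.grid.ravel())
        assert np.isin(lesion_flat, tpl.wm_flat).all()
        # ...and classifies as gray matter (hypointense WM)
        _, gm_m, wm_m = discretize_tissue(sub.tissue)
        assert gm_m.grid[sub.lesion_mask.grid].all()
        # lesions never overlap region labels
        assert not (sub.lesion_mask.grid & (sub.labels.grid > 0)).any()

    def test_unknown_diagnosis_and_sizing_errors(self, small_spec):
        spec = dataclasses.replace(small_spec, effect_table={"HS": {}})
        with pytest.raises(KeyError, match="AD"):
            generate_subject(spec, _record("x", "AD"))
        with pytest.raises(PhantomSizingError):
            PhantomSpec(grid_shape=(8, 8, 8))

    def test_tissue_probabilities_valid(self, hs_subject):
        total = hs_subject.tissue.csf + hs_subject.tissue.gm + hs_subject.tissue.wm
        assert total.max() <= 1.0 + 1e-3
        # brain mask excludes ventricles and contains the WM compartment
        vent = np.isin(hs_subject.labels.grid, [45, 46, 47, 48])
        assert not (hs_subject.wm_gm_mask.grid & vent).any()


class TestPerturbAtlasLabels:
    def test_zero_jitter_reproduces_truth(self, hs_subject):
        for cand in perturb_atlas_labels(hs_subject.labels, 3, 0.0, seed=1):
            assert np.array_equal(cand.grid, hs_subject.labels.grid)

    def test_changes_confined_to_boundary_shell(self, hs_subject):
        truth = hs_subject.labels.grid
        from atlasmorph.phantom import _face_neighbors

        boundary = (_face_neighbors(truth) != truth[None]).any(axis=0)
        for cand in perturb_atlas_labels(hs_subject.labels, 4, 0.3, seed=2):
            diff = cand.grid != truth
            assert not (diff & ~boundary).any()

    def test_disagreement_rate_near_jitter(self, hs_subject):
        truth = hs_subject.labels.grid
        from atlasmorph.phantom import _face_neighbors

        boundary = (_face_neighbors(truth) != truth[None]).any(axis=0)
        cands = perturb_atlas_labels(hs_subject.labels, 40, 0.2, seed=3)
        rates = [float((c.grid != truth)[boundary].mean()) for c in cands]
        assert np.mean(rates) == pytest.approx(0.2, abs=0.01)

    def test_majority_vote_recovers_truth(self, hs_subject):
        cands = perturb_atlas_labels(hs_subject.labels, 30, 0.2, seed=4)
        fused = vote_fuse(cands)
        agreement = (fused.grid == hs_subject.labels.grid).mean()
        assert agreement > 0.99

    def test_preconditions(self, hs_subject):
        with pytest.raises(ValueError, match="n_atlases"):
            perturb_atlas_labels(hs_subject.labels, 1, 0.1, seed=0)
        with pytest.raises(ValueError, match="jitter"):
            perturb_atlas_labels(hs_subject.labels, 3, 0.5, seed=0)

    def test_flipped_codes_come_from_neighbors(self, hs_subject):
        truth = hs_subject.labels.grid
        from atlasmorph.phantom import _face_neighbors

        nb = _face_neighbors(truth)
        for cand in perturb_atlas_labels(hs_subject.labels, 2, 0.4, seed=5):
            changed = np.argwhere(cand.grid != truth)
            for x, y, z in changed[:200]:
                assert cand.grid[x, y, z] in nb[:, x, y, z]


class TestGenerateCohort:
    def test_group_counts_and_record_fields(self, small_spec):
        records, data = generate_cohort(small_spec, {"HS": 4, "AD": 4}, seed=0)
        assert len(records) == 8 and len(data) == 8
        assert {r.diagnosis for r in records} == {"HS", "AD"}
        for r in records:
            icv = data[r.subject_id].icv_mask.volume_mm3()
            assert ICV_RANGE_MM3[0] <= icv <= ICV_RANGE_MM3[1]

    def test_cohort_is_deterministic(self, small_spec):
        r1, d1 = generate_cohort(small_spec, {"HS": 2, "AD": 2}, seed=3)
        r2, d2 = generate_cohort(small_spec, {"HS": 2, "AD": 2}, seed=3)
        assert [r.subject_id for r in r1] == [r.subject_id for r in r2]
        for sid in d1:
            assert np.array_equal(d1[sid].labels.grid, d2[sid].labels.grid)
            assert d1[sid].labels.voxel_size == d2[sid].labels.voxel_size

    def test_group_effect_detectable_at_modest_n(self, small_spec):
        """-20% hippocampus separates 12 HS vs 12 AD at p < 0.01."""
        spec = dataclasses.replace(
            small_spec, effect_table={"HS": {}, "AD": {1: -0.20, 2: -0.20}}
        )
        records, data = generate_cohort(spec, {"HS": 12, "AD": 12}, seed=7)
        frames = []
        for r in records:
            sub = data[r.subject_id]
            frames.append(
                measure_volumes(sub.labels, sub.icv_mask, spec.region_table(),
                                r.subject_id, r.image_ids[0])
            )
        import pandas as pd

        vols = pd.concat(frames, ignore_index=True)
        res = group_test_matrix(vols, records, [("HS", "AD")])
        assert res.p.loc[1, "HS_vs_AD"] < 0.01
        assert res.p.loc[2, "HS_vs_AD"] < 0.01

    def test_single_group_cohort_errors_cleanly_downstream(self, small_spec):
        records, data = generate_cohort(small_spec, {"HS": 3}, seed=1)
        assert {r.diagnosis for r in records} == {"HS"}
        import pandas as pd

        frames = [
            measure_volumes(data[r.subject_id].labels, data[r.subject_id].icv_mask,
                            small_spec.region_table(), r.subject_id, r.image_ids[0])
            for r in records
        ]
        res = group_test_matrix(pd.concat(frames, ignore_index=True), records, [("HS", "AD")])
        assert res.p.empty and res.warnings

    def test_empty_request_rejected(self, small_spec):
        with pytest.raises(ValueError, match="at least one"):
            generate_cohort(small_spec, {"HS": 0}, seed=0)


def test_subject_seed_is_stable_and_bounded():
    s1 = subject_seed(42, "HS-000")
    assert s1 == subject_seed(42, "HS-000")
    assert s1 != subject_seed(42, "HS-001")
    assert 0 <= s1 < 2**31
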