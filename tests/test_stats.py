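"""Fat quantification and group statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from adiposeg.core import FatVolumes, LabelMap, SAT, VAT
from adiposeg.stats import cohort_report, fat_volumes, pearson, \
    ttest_two_tailed, vat_sat_ratio


class TestFatVolumes:
    def test_empty_mask_zero_and_ratio_undefined(self):
        f = fat_volumes(LabelMap(np.zeros((4, 4, 4), int), spacing=(1, 1, 1)))
        assert f.sat_ml == 0.0 and f.vat_ml == 0.0
        with pytest.raises(ValueError, match="ratio undefined"):
            _ = f.ratio

    def test_1000_voxels_at_1p2mm_is_1p728_ml(self):
        classes = np.zeros((10, 10, 10), int)
        classes.ravel()[:1000] = VAT
        f = fat_volumes(LabelMap(classes, spacing=(1.2, 1.2, 1.2)))
        assert f.vat_ml == pytest.approx(1.728)

    def test_scaling_to_a_million_voxels(self):
        classes = np.full((100, 100, 100), SAT)
        f = fat_volumes(LabelMap(classes, spacing=(1.2, 1.2, 1.2)))
        assert f.sat_ml == pytest.approx(1728.0)

    def test_volume_additive_over_slices(self, clean_volume):
        _, gt = clean_volume
        total = fat_volumes(gt)
        per_slice = [fat_volumes(LabelMap(gt.classes[:, :, z:z + 1],
                                          spacing=gt.spacing))
                     for z in range(gt.shape[2])]
        assert total.sat_ml == pytest.approx(sum(f.sat_ml for f in per_slice))
        assert total.vat_ml == pytest.approx(sum(f.vat_ml for f in per_slice))

    def test_ratio_invariant_under_uniform_spacing_scale(self, clean_volume):
        _, gt = clean_volume
        f1 = fat_volumes(gt)
        scaled = LabelMap(gt.classes, spacing=tuple(2.0 * s
                                                    for s in gt.spacing))
        f2 = fat_volumes(scaled)
        assert f2.sat_ml == pytest.approx(8.0 * f1.sat_ml)
        assert f2.ratio == pytest.approx(f1.ratio)


class TestRatio:
    def test_half_and_unity(self):
        assert vat_sat_ratio(FatVolumes(sat_ml=4000, vat_ml=2000)) == 0.5
        assert vat_sat_ratio(FatVolumes(sat_ml=3.0, vat_ml=3.0)) == 1.0

    def test_zero_sat_guard(self):
        with pytest.raises(ValueError):
            vat_sat_ratio(FatVolumes(sat_ml=0.0, vat_ml=1.0))


class TestTTest:
    def test_identical_samples_t_zero_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = ttest_two_tailed(a, a.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_statistic(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        t, p = ttest_two_tailed(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_type_one_error_calibrated(self):
        """Null rejection rate ≈ 5% over 1000 replicates."""
        rng = np.random.default_rng(123)
        a = rng.normal(0, 1, (1000, 34))
        b = rng.normal(0, 1, (1000, 34))
        p = sps.ttest_ind(a, b, axis=1, equal_var=True).pvalue
        # sanity-tie our scalar implementation to a handful of rows
        for i in range(5):
            assert ttest_two_tailed(a[i], b[i])[1] == pytest.approx(p[i])
        rate = float((p < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_power_at_effect_size_one(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(200):
            a = rng.normal(0, 1, 34)
            b = rng.normal(1, 1, 34)
            hits += ttest_two_tailed(a, b)[1] < 0.05
        assert hits / 200 >= 0.95

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_tailed([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            ttest_two_tailed([2.0, 2.0], [2.0, 2.0])


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_r_approaches_one_as_noise_shrinks(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 200)
        rs = []
        for sigma in (3.0, 1.0, 0.3, 0.01):
            rs.append(pearson(x, 2 * x + rng.normal(0, sigma, x.size)))
        assert all(b > a for a, b in zip(rs, rs[1:]))
        assert rs[-1] > 0.999

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCohortReport:
    @staticmethod
    def _cohort(n=6, seed=0):
        from adiposeg.core import CohortManifest, SubjectRecord
        rng = np.random.default_rng(seed)
        subjects, maps = [], {}
        for i in range(n):
            group = "patient" if i < n // 2 else "control"
            subjects.append(SubjectRecord(f"s{i}", group, 55.0, 24.0,
                                          split="test"))
            classes = np.zeros((8, 8, 4), int)
            classes[:3] = SAT
            classes[4:5, 4:5, :] = VAT
            if group == "patient":
                classes[4:6, 4:6, :] = VAT
            # deterministic subject-level jitter so per-group volumes are
            # non-constant (Pearson r needs variance)
            jitter = 1 + i % 3
            classes[6, 6, :jitter] = VAT
            classes[7, :2 + jitter, :] = SAT
            maps[f"s{i}"] = LabelMap(classes, spacing=(2, 2, 2))
        return CohortManifest(subjects=subjects), maps

    def test_identical_sources_perfect_agreement(self):
        manifest, maps = self._cohort()
        rep = cohort_report(manifest, maps, maps)
        assert all(r == pytest.approx(1.0) for r in rep.pearson_r.values())
        assert rep.ratio_stats.mean_a > rep.ratio_stats.mean_b

    def test_row_count_equals_test_subjects(self):
        manifest, maps = self._cohort(8)
        rep = cohort_report(manifest, maps, maps)
        assert len(rep.volumes) == 8

    def test_missing_subjects_excluded_with_warning(self):
        manifest, maps = self._cohort(6)
        partial = {k: v for k, v in maps.items() if k != "s1"}
        with pytest.warns(UserWarning, match="missing"):
            rep = cohort_report(manifest, partial, maps)
        assert rep.excluded == ["s1"]
        assert len(rep.volumes) == 5
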