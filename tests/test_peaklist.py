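import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidmsi.core_io import SectionMeta
from lipidmsi.peaklist import (
    CandidateMass,
    FilterConfig,
    MasterPeakList,
    ReplicatedPeak,
    build_master_list,
    common_across_tech_reps,
    cv,
    cv_gate,
    isotope_filter,
    log2fc_consistency_gate,
    matrix_peak_filter,
    merge_by_ppm,
    rank_auc,
)
from lipidmsi.preprocess import Peak, PeakList

from conftest import make_section


def plist(mzs, section_id="r1", region="tumor", intensity=1.0):
    return PeakList(section_id, region, [Peak(m, intensity, 10.0) for m in mzs])


class TestMergeByPpm:
    def test_214_ppm_gap_merges(self):
        clusters = merge_by_ppm([plist([700.000]), plist([700.150], "r2")])
        assert len(clusters) == 1

    def test_229_ppm_gap_splits(self):
        clusters = merge_by_ppm([plist([700.000]), plist([700.160], "r2")])
        assert len(clusters) == 2

    def test_identical_lists(self):
        mzs = [600.0, 700.0, 800.0]
        clusters = merge_by_ppm([plist(mzs, "r1"), plist(mzs, "r2"), plist(mzs, "r3")])
        assert len(clusters) == 3
        assert all(len(c.members) == 3 for c in clusters)

    def test_representative_within_member_range(self):
        clusters = merge_by_ppm([plist([700.00], intensity=1.0), plist([700.10], "r2", intensity=9.0)])
        (c,) = clusters
        assert 700.00 <= c.rep_mz <= 700.10
        assert c.rep_mz > 700.05  # pulled toward the stronger member

    @staticmethod
    def _brute_force(mzs, ppm):
        # transitive closure over all pairwise <= ppm relations
        n = len(mzs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                lo, hi = sorted((mzs[i], mzs[j]))
                if (hi - lo) / lo * 1e6 <= ppm:
                    parent[find(i)] = find(j)
        return len({find(i) for i in range(n)})

    @given(st.lists(st.floats(min_value=500, max_value=1300), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_matches_transitive_closure_oracle(self, mzs):
        clusters = merge_by_ppm([plist(sorted(set(mzs)))], 220.0)
        assert len(clusters) == self._brute_force(sorted(set(mzs)), 220.0)


class TestCommonAcrossReps:
    def test_full_coverage_kept(self):
        clusters = merge_by_ppm([plist([700.0], f"r{i}") for i in (1, 2, 3)])
        assert len(common_across_tech_reps(clusters, ["r1", "r2", "r3"])) == 1

    def test_partial_coverage_dropped(self):
        clusters = merge_by_ppm([plist([700.0], "r1"), plist([700.0], "r3")])
        assert common_across_tech_reps(clusters, ["r1", "r2", "r3"]) == []

    def test_planted_common_masses_survive(self):
        common = [600.0, 650.0, 700.0, 750.0, 800.0]
        lists = [plist(sorted(common + [810.0]), "r1"),
                 plist(sorted(common + [820.0]), "r2"),
                 plist(sorted(common + [830.0]), "r3")]
        clusters = merge_by_ppm(lists)
        out = common_across_tech_reps(clusters, ["r1", "r2", "r3"])
        assert sorted(round(p.mz, 1) for p in out) == common


class TestCV:
    @pytest.mark.parametrize("values,expected", [
        ([2, 2, 2], 0.0),
        ([1, 2, 3], 50.0),
        ([10, 30], 70.710678),
    ])
    def test_values(self, values, expected):
        assert cv(values) == pytest.approx(expected, abs=1e-4)

    def test_zero_mean_is_nan(self):
        assert np.isnan(cv([-1.0, 1.0]))

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            cv([1.0])


class TestCVGate:
    def _peak(self, intensities):
        return ReplicatedPeak(700.0, {f"r{i+1}": v for i, v in enumerate(intensities)})

    def test_zero_cv_kept(self):
        assert len(cv_gate([self._peak([1, 1, 1])], 45.0)) == 1

    def test_cv_50_dropped_at_45(self):
        assert cv_gate([self._peak([1, 2, 3])], 45.0) == []

    def test_boundary_is_strict(self):
        # two values constructed so the CV is exactly 45.0
        c = 0.45 / np.sqrt(2)
        vals = [1.0, (1 + c) / (1 - c)]
        p = self._peak(vals)
        assert cv(vals) == pytest.approx(45.0, abs=1e-9)
        assert cv_gate([p], 45.0) == []

    def test_gate_is_pure_and_idempotent(self):
        peaks = [self._peak(v) for v in ([1, 1, 1], [1, 2, 3], [5, 5, 6])]
        once = cv_gate(peaks, 45.0)
        assert set(id(p) for p in once) <= set(id(p) for p in peaks)
        assert cv_gate(once, 45.0) == once


class TestLog2FCGate:
    def _rp(self, mz, vals):
        return ReplicatedPeak(mz, {f"r{i+1}": v for i, v in enumerate(vals)})

    def test_constant_fc_kept(self):
        t = [self._rp(700.0, [2, 4, 8])]
        n = [self._rp(700.0, [1, 2, 4])]  # fc = 1,1,1
        assert len(log2fc_consistency_gate(t, n)) == 1

    def test_fc_cv_50_kept_at_60(self):
        t = [self._rp(700.0, [2 ** 0.5, 2.0, 2 ** 1.5])]
        n = [self._rp(700.0, [1.0, 1.0, 1.0])]  # fc = 0.5, 1.0, 1.5 -> CV 50
        assert len(log2fc_consistency_gate(t, n, 60.0)) == 1
        assert log2fc_consistency_gate(t, n, 45.0) == []

    def test_missing_necrosis_rep_excluded(self):
        t = [self._rp(700.0, [2, 2, 2])]
        n = [ReplicatedPeak(700.0, {"r1": 1.0, "r3": 1.0})]
        assert log2fc_consistency_gate(t, n) == []


class TestMatrixFilter:
    def _dataset(self, on_level, off_level, seed=0):
        axis = np.arange(500.0, 520.0, 0.1)
        rng = np.random.default_rng(seed)
        n = 64
        labels = ["tumor"] * 32 + ["off_tissue"] * 32
        inten = np.zeros((n, axis.size))
        j = np.searchsorted(axis, 510.0)
        inten[:32, j] = on_level * (1 + 0.05 * rng.standard_normal(32))
        inten[32:, j] = off_level * (1 + 0.05 * rng.standard_normal(32))
        return make_section(np.clip(inten, 0, None), axis, labels=labels)

    def test_matrix_peak_removed(self):
        ds = self._dataset(on_level=1.0, off_level=10.0)
        kept, removed, aucs = matrix_peak_filter(ds, [510.0])
        assert removed == [510.0] and kept == []
        assert aucs[510.0] > 0.99

    def test_tissue_peak_kept(self):
        ds = self._dataset(on_level=10.0, off_level=1.0)
        kept, removed, aucs = matrix_peak_filter(ds, [510.0])
        assert kept == [510.0]
        assert aucs[510.0] < 0.01

    def test_identical_distributions_kept(self):
        axis = np.arange(500.0, 520.0, 0.1)
        inten = np.ones((10, axis.size))
        labels = ["tumor"] * 5 + ["off_tissue"] * 5
        ds = make_section(inten, axis, labels=labels)
        kept, removed, aucs = matrix_peak_filter(ds, [510.0])
        assert kept == [510.0]
        assert aucs[510.0] == pytest.approx(0.5)

    def test_no_off_tissue_warns_and_skips(self):
        axis = np.arange(500.0, 520.0, 0.1)
        ds = make_section(np.ones((4, axis.size)), axis, labels=["tumor"] * 4)
        with pytest.warns(UserWarning):
            kept, removed, _ = matrix_peak_filter(ds, [510.0])
        assert kept == [510.0] and removed == []


class TestIsotopeFilter:
    def test_smaller_plus_one_removed(self):
        out = isotope_filter([(740.52, 10.0), (741.523, 4.0)])
        assert out == [(740.52, 10.0)]

    def test_larger_plus_one_kept(self):
        peaks = [(740.52, 4.0), (741.523, 10.0)]
        assert isotope_filter(peaks) == peaks

    def test_isolated_peak_kept(self):
        assert isotope_filter([(740.52, 1.0)]) == [(740.52, 1.0)]

    def test_idempotent(self):
        peaks = [(700.0, 5.0), (701.003, 2.0), (750.0, 3.0)]
        once = isotope_filter(peaks)
        assert isotope_filter(once) == once


class TestRankAUC:
    def test_perfect_separation(self):
        assert rank_auc([4, 5, 6], [1, 2, 3]) == 1.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pos = rng.integers(0, 8, size=50).astype(float)
            neg = rng.integers(0, 8, size=50).astype(float)
            brute = np.mean([
                1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg
            ])
            assert rank_auc(pos, neg) == pytest.approx(brute, abs=1e-12)


class TestBuildMasterList:
    def _cands(self, mz, intensity=5.0):
        return CandidateMass(mz, intensity, frozenset({"tumor"}))

    def test_two_of_eight_samples_kept(self):
        per_sample = {f"B{i}": [] for i in range(1, 9)}
        per_sample["B1"] = [self._cands(700.0)]
        per_sample["B2"] = [self._cands(700.01)]
        master = build_master_list(per_sample)
        assert len(master) == 1
        assert master.entries[0].bio_samples == ("B1", "B2")

    def test_single_sample_dropped(self):
        per_sample = {"B1": [self._cands(700.0)], "B2": []}
        assert len(build_master_list(per_sample)) == 0

    def test_low_mean_intensity_dropped(self):
        per_sample = {"B1": [self._cands(700.0, 0.9)], "B2": [self._cands(700.0, 0.9)]}
        assert len(build_master_list(per_sample)) == 0

    def test_isotope_recheck(self):
        per_sample = {
            "B1": [self._cands(700.0, 10.0), self._cands(701.003, 4.0)],
            "B2": [self._cands(700.0, 10.0), self._cands(701.003, 4.0)],
        }
        master = build_master_list(per_sample)
        assert len(master) == 1
        assert master.entries[0].mz == pytest.approx(700.0, abs=1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        per_sample = {
            f"B{i}": [self._cands(float(m)) for m in rng.choice([600.0, 650.0, 700.0, 750.0], 3, replace=False)]
            for i in range(1, 5)
        }
        m1 = build_master_list(per_sample)
        m2 = build_master_list(dict(reversed(list(per_sample.items()))))
        np.testing.assert_allclose(m1.mz, m2.mz)


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(ppm_window=0)
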