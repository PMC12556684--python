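import numpy as np
import pandas as pd
import pytest

from drseg import evaluate as ev
from drseg.volio import FS35_LUT, LabeledVolume


def _mask(shape, coords):
    m = np.zeros(shape, bool)
    for c in coords:
        m[c] = True
    return m


class TestDice:
    def test_identical_nonempty(self):
        g = _mask((4, 4, 4), [(1, 1, 1), (2, 2, 2)])
        assert ev.dice_coefficient(g, g) == 1.0

    def test_disjoint(self):
        g = _mask((4, 4, 4), [(0, 0, 0)])
        p = _mask((4, 4, 4), [(3, 3, 3)])
        assert ev.dice_coefficient(g, p) == 0.0

    def test_counting_oracle(self):
        g = np.zeros((4, 4, 4), bool)
        p = np.zeros((4, 4, 4), bool)
        g.flat[:8] = True
        p.flat[4:12] = True  # |G|=8, |P|=8, |G∩P|=4
        assert ev.dice_coefficient(g, p) == 0.5

    def test_symmetry(self, rng):
        g = rng.random((6, 6, 6)) > 0.5
        p = rng.random((6, 6, 6)) > 0.5
        assert ev.dice_coefficient(g, p) == ev.dice_coefficient(p, g)

    def test_both_empty_raises(self):
        z = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError, match="missing"):
            ev.dice_coefficient(z, z)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.dice_coefficient(np.ones((2, 2, 2), bool), np.ones((3, 3, 3), bool))


class TestASD:
    def test_identical_zero(self):
        g = _mask((6, 6, 6), [(2, 2, 2), (2, 2, 3), (3, 2, 2)])
        assert ev.average_surface_distance(g, g, (1, 1, 1)) == 0.0

    def test_single_voxels_one_apart(self):
        g = _mask((6, 6, 6), [(2, 2, 2)])
        p = _mask((6, 6, 6), [(3, 2, 2)])
        assert ev.average_surface_distance(g, p, (1, 1, 1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_parallel_plates_bruteforce_oracle(self, k):
        shape = (8, 6, 6)
        g = np.zeros(shape, bool)
        p = np.zeros(shape, bool)
        g[1] = True
        p[1 + k] = True
        spacing = (0.7, 0.7, 0.7)
        got = ev.average_surface_distance(g, p, spacing)

        # brute-force all-pairs oracle over every boundary voxel center
        def surf(m):
            pts = []
            for idx in np.argwhere(m):
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)):
                    j = idx + d
                    if np.any(j < 0) or np.any(j >= np.array(shape)) or not m[tuple(j)]:
                        pts.append(idx * np.array(spacing))
                        break
            return np.array(pts)

        sg, sp = surf(g), surf(p)
        dg = [min(np.linalg.norm(a - b) for b in sp) for a in sg]
        dp = [min(np.linalg.norm(a - b) for b in sg) for a in sp]
        oracle = (sum(dg) + sum(dp)) / (len(sg) + len(sp))
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(k * 0.7, abs=1e-9)

    def test_symmetric(self, rng):
        g = rng.random((6, 6, 6)) > 0.4
        p = rng.random((6, 6, 6)) > 0.4
        a = ev.average_surface_distance(g, p, (1, 1, 1))
        b = ev.average_surface_distance(p, g, (1, 1, 1))
        assert a == pytest.approx(b)

    def test_scales_with_spacing(self):
        g = _mask((8, 8, 8), [(2, 2, 2)])
        p = _mask((8, 8, 8), [(5, 2, 2)])
        a = ev.average_surface_distance(g, p, (1, 1, 1))
        b = ev.average_surface_distance(g, p, (2, 2, 2))
        assert b == pytest.approx(2 * a)

    def test_empty_raises(self):
        g = _mask((4, 4, 4), [(1, 1, 1)])
        with pytest.raises(ValueError, match="missing"):
            ev.average_surface_distance(g, np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestEvaluateLabelmaps:
    def test_perfect_prediction(self, fs35_pair):
        gt, pred = fs35_pair
        rep = ev.evaluate_labelmaps(gt, pred, ev.default_exclusion_policy())
        inc = rep.included()
        assert (inc["dsc"] == 1.0).all()
        assert (inc["asd_mm"] == 0.0).all()
        assert rep.overall_median_dsc == 1.0

    def test_27_of_35_summarized(self, fs35_pair):
        gt, pred = fs35_pair
        rep = ev.evaluate_labelmaps(gt, pred, ev.default_exclusion_policy())
        assert len(rep.records) == 35
        assert rep.n_summarized() == 27

    def test_missing_label_convention(self):
        data = np.zeros((6, 6, 6), np.int32)
        data[:2] = 2
        data[4:] = 3
        gt = LabeledVolume(data, np.eye(4), {2: ("a", (0,) * 3), 3: ("b", (0,) * 3)})
        pred_data = data.copy()
        pred_data[pred_data == 3] = 0  # label 3 not segmented
        pred = LabeledVolume(pred_data, np.eye(4), gt.lut)
        rep = ev.evaluate_labelmaps(gt, pred)
        row = rep.records.set_index("label").loc[3]
        assert row["dsc"] == 0.0
        assert np.isnan(row["asd_mm"])
        assert bool(row["missing"])

    def test_absent_from_both_dropped(self):
        data = np.ones((4, 4, 4), np.int32)
        lut = {1: ("a", (0,) * 3), 9: ("ghost", (0,) * 3)}
        gt = LabeledVolume(data, np.eye(4), lut)
        rep = ev.evaluate_labelmaps(gt, gt.copy())
        assert 9 not in set(rep.records["label"])


class TestVolumes:
    def test_empty_label_zero(self):
        seg = LabeledVolume(np.zeros((4, 4, 4), np.int32), np.eye(4),
                            {7: ("x", (0,) * 3)})
        assert ev.label_volumes(seg).loc[7] == 0.0

    def test_isotropic_07(self):
        data = np.zeros((10, 10, 10), np.int32)
        data.flat[:100] = 5
        aff = np.diag([0.7, 0.7, 0.7, 1.0])
        seg = LabeledVolume(data, aff, {5: ("x", (0,) * 3)})
        assert ev.label_volumes(seg).loc[5] == pytest.approx(100 * 0.343)

    def test_anisotropic_determinant(self):
        data = np.zeros((5, 5, 5), np.int32)
        data.flat[:10] = 2
        aff = np.diag([0.5, 0.5, 1.0, 1.0])
        seg = LabeledVolume(data, aff, {2: ("x", (0,) * 3)})
        assert ev.label_volumes(seg).loc[2] == pytest.approx(2.5)

    def test_volume_conservation(self, small_phantom):
        vols = ev.label_volumes(small_phantom)
        bg = int((small_phantom.data == 0).sum()) * small_phantom.voxel_volume
        total = np.prod(small_phantom.shape) * small_phantom.voxel_volume
        assert vols.sum() + bg == pytest.approx(total)


def _records(values, group, tiv=1000.0):
    return [ev.VolumetryRecord(subject=f"s{i}", group=group,
                               roi_volumes_mm3={1: v}, tiv_mm3=tiv)
            for i, v in enumerate(values)]


class TestGroupVolumeTest:
    def test_identical_groups_not_significant(self):
        a = _records([10.0, 11.0, 12.0], "A")
        b = _records([10.0, 11.0, 12.0], "B")
        u, p, thr, sig = ev.group_volume_test(a, b, 1, n_comparisons=1)
        assert p > 0.9
        assert not sig

    def test_bonferroni_threshold_nine_comparisons(self):
        a = _records([1.0, 2.0], "A")
        b = _records([3.0, 4.0], "B")
        _u, _p, thr, _sig = ev.group_volume_test(a, b, 1, n_comparisons=9)
        assert thr == pytest.approx(0.05 / 9)
        assert thr == pytest.approx(0.0056, abs=1e-4)  # printed as < 0.006

    def test_separated_samples_exact_p(self):
        a = _records([1.0, 2.0, 3.0, 4.0, 5.0], "A")
        b = _records([10.0, 11.0, 12.0, 13.0, 14.0], "B")
        u, p, _thr, _sig = ev.group_volume_test(a, b, 1)
        assert u in (0.0, 25.0)
        assert p == pytest.approx(2 / 252)

    def test_degenerate_all_identical(self):
        a = _records([5.0, 5.0], "A")
        b = _records([5.0, 5.0, 5.0], "B")
        _u, p, _thr, sig = ev.group_volume_test(a, b, 1)
        assert p == 1.0 and not sig

    def test_matches_exact_enumeration_oracle(self, rng):
        # independent oracle: enumerate all label assignments, count U stats
        from itertools import combinations

        for trial in range(5):
            a = rng.random(4)
            b = rng.random(5)
            u, p, _t, _s = ev.group_volume_test(_records(a, "A"), _records(b, "B"), 1)
            pooled = np.concatenate([a, b])

            def ustat(sel):
                x = pooled[list(sel)]
                y = np.delete(pooled, list(sel))
                return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

            obs = ustat(range(4))
            mu = 4 * 5 / 2
            stats = [ustat(c) for c in combinations(range(9), 4)]
            p_ref = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in stats])
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestSummaries:
    def _report(self, dscs, subject):
        df = pd.DataFrame({"label": range(1, len(dscs) + 1), "dsc": dscs,
                           "asd_mm": [0.1] * len(dscs),
                           "gt_mm3": 1.0, "pred_mm3": 1.0,
                           "excluded": False, "missing": False})
        return ev.EvalReport(df, subject=subject)

    def test_single_subject_degenerate_ci(self):
        rep = self._report([0.8, 0.9], "s0")
        table = ev.summarize_cohort([rep], n_boot=100)
        row = table[table["label"] == "overall"].iloc[0]
        assert row["dsc_median"] == pytest.approx(0.85)

    def test_identical_values_zero_width_ci(self):
        reps = [self._report([0.7, 0.7, 0.7], f"s{i}") for i in range(3)]
        table = ev.summarize_cohort(reps, n_boot=200)
        row = table[table["label"] == 1].iloc[0]
        assert row["dsc_lo"] == row["dsc_hi"] == row["dsc_median"] == 0.7

    def test_bootstrap_matches_reference_quantiles(self):
        # independent bootstrap reimplementation with the same seed
        values = np.arange(20, dtype=float)
        med, lo, hi = ev.bootstrap_median_ci(values, n_boot=5000, seed=11)
        rng = np.random.default_rng(11)
        idx = rng.integers(0, 20, size=(5000, 20))
        meds = np.median(values[idx], axis=1)
        assert med == np.median(values)
        assert lo == pytest.approx(np.quantile(meds, 0.025))
        assert hi == pytest.approx(np.quantile(meds, 0.975))

    def test_dsc_invariant_to_relabeling_and_translation(self, rng):
        g = rng.random((6, 6, 6)) > 0.5
        p = rng.random((6, 6, 6)) > 0.5
        base = ev.dice_coefficient(g, p)
        gt = np.roll(g, 2, axis=0)
        pt = np.roll(p, 2, axis=0)
        assert ev.dice_coefficient(gt, pt) == base
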