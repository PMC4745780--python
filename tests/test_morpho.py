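import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from organotrack.morpho import (GroupComparison, compare_groups, heatmap_matrix,
                                inhibition_percent, measure_field,
                                measure_organoid, normalize_growth_to_control,
                                smooth_curve)
from organotrack.synth import generate_organoid_field


def mw_permutation_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by exhaustive enumeration (no ties)."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    obs_u = sum(1 for a in x for b in y if a > b)
    obs = min(obs_u, n1 * n2 - obs_u)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for a in xs for b in ys if a > b)
        if min(u, n1 * n2 - u) <= obs:
            count += 1
        total += 1
    return count / total


class TestMeasureOrganoid:
    def test_disc_is_round_with_no_appendages(self):
        mask = np.zeros((96, 96), bool)
        rr, cc = draw_disk((48, 48), 20)
        mask[rr, cc] = True
        rec = measure_organoid(mask, np.full(mask.shape, 100.0))
        assert rec.Roundness == pytest.approx(1.0, rel=0.05)
        assert rec.AppNumber == 0
        assert rec.MaxApp == 0 and rec.MedApp == 0
        assert rec.Density == 100.0
        assert rec.Area == mask.sum()

    def test_single_appendage_length(self):
        img, truths = generate_organoid_field(1, appendage_spec=[(1, 30.0)],
                                              seed=3)
        rec = measure_organoid(truths[0]["mask"], img)
        assert rec.AppNumber == 1
        assert rec.MaxApp == pytest.approx(30.0, abs=2.0)
        # stripping the appendage restores roundness
        assert rec.FiltRound > rec.Roundness

    def test_multi_appendage_counts(self):
        img, truths = generate_organoid_field(3, appendage_spec=[(3, 25.0)],
                                              seed=5)
        for t in truths:
            rec = measure_organoid(t["mask"], img)
            assert rec.AppNumber == t["appendage_count"]
            assert rec.MaxApp == pytest.approx(25.0, abs=2.5)

    def test_roundness_invariant_to_pose(self):
        recs = []
        for center in ((30, 30), (60, 70)):
            mask = np.zeros((96, 96), bool)
            rr, cc = draw_disk(center, 17)
            mask[rr, cc] = True
            recs.append(measure_organoid(mask, np.ones(mask.shape)))
        assert recs[0].Roundness == pytest.approx(recs[1].Roundness, rel=0.05)

    def test_cell_number_scaling(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 15)
        mask[rr, cc] = True
        rec = measure_organoid(mask, np.ones(mask.shape))
        assert rec.CellNumber == pytest.approx(rec.Area / 250.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_organoid(np.zeros((8, 8), bool), np.zeros((8, 8)))

    def test_measure_field_one_row_per_object(self):
        img, truths = generate_organoid_field(4, seed=6)
        mask = np.zeros_like(img, dtype=bool)
        for t in truths:
            mask |= t["mask"]
        df = measure_field(mask, img)
        assert len(df) == 4
        assert set(df.columns) >= {"Area", "Roundness", "MaxApp"}


class TestCompareGroups:
    def _groups(self, rng, delta=0.0, n=12):
        mk = lambda shift: pd.DataFrame({
            "Area": rng.normal(100 + shift, 10, n),
            "Roundness": np.clip(rng.normal(0.9, 0.05, n), 0.01, 1.0)})
        return {"control": mk(0.0), "treated": mk(delta)}

    def test_identical_group_vs_itself(self, rng):
        df = pd.DataFrame({"Area": [1.0, 2, 3, 4, 5]})
        comps = compare_groups({"control": df, "same": df.copy()}, "control",
                               params=["Area"])
        assert comps[0].p_adjusted == 1.0
        assert comps[0].direction == "none"

    def test_exact_mannwhitney_p_for_separated_samples(self):
        groups = {"control": pd.DataFrame({"Area": [6.0, 7, 8, 9, 10]}),
                  "low": pd.DataFrame({"Area": [1.0, 2, 3, 4, 5]})}
        comps = compare_groups(groups, "control", params=["Area"])
        assert comps[0].p_raw == pytest.approx(0.007937, abs=1e-6)
        assert comps[0].direction == "decreased"

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("sizes", [(4, 5), (5, 6), (6, 6)])
    def test_mannwhitney_matches_permutation_oracle(self, seed, sizes):
        rng = np.random.default_rng(seed)
        n1, n2 = sizes
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        pool = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
        groups = {"control": pd.DataFrame({"Area": pool}),
                  "g": pd.DataFrame({"Area": x})}
        comps = compare_groups(groups, "control", params=["Area"])
        assert comps[0].p_raw == pytest.approx(
            mw_permutation_pvalue(x, pool), abs=1e-9)

    def test_bonferroni_monotone_and_capped(self, rng):
        groups = self._groups(rng, delta=5.0)
        comps = compare_groups(groups, "control",
                               params=["Area", "Roundness"])
        for c in comps:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0
        single = compare_groups(groups, "control", params=["Area"])
        assert single[0].p_adjusted == pytest.approx(single[0].p_raw)

    def test_power_on_shifted_groups(self, rng):
        groups = self._groups(rng, delta=30.0, n=50)
        comps = compare_groups(groups, "control", params=["Area"])
        assert comps[0].p_adjusted < 0.001
        assert comps[0].direction == "increased"

    def test_welch_ttest_variant(self, rng):
        groups = self._groups(rng, delta=30.0, n=20)
        comps = compare_groups(groups, "control", test="ttest",
                               params=["Area"])
        assert comps[0].test == "ttest"
        assert comps[0].p_raw < 0.001

    def test_unknown_test_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_groups(self._groups(rng), "control", test="bogus")

    def test_small_group_rejected(self):
        groups = {"control": pd.DataFrame({"Area": [1.0, 2, 3]}),
                  "g": pd.DataFrame({"Area": [1.0, 2]})}
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_groups(groups, "control", params=["Area"])


class TestHeatmap:
    def test_control_vs_itself_zero_fold(self):
        df = pd.DataFrame({"Area": [10.0, 20, 30, 40]})
        groups = {"control": df, "same": df.copy()}
        comps = compare_groups(groups, "control", params=["Area"])
        fold, pmat = heatmap_matrix(comps, groups, "control")
        assert fold.loc["Area", "same"] == 0.0

    def test_doubled_area_gives_log2_one(self):
        ctrl = pd.DataFrame({"Area": [10.0, 20, 30, 40]})
        dbl = pd.DataFrame({"Area": [20.0, 40, 60, 80]})
        groups = {"control": ctrl, "dbl": dbl}
        comps = compare_groups(groups, "control", params=["Area"])
        fold, _ = heatmap_matrix(comps, groups, "control")
        assert fold.loc["Area", "dbl"] == pytest.approx(1.0)

    def test_three_group_matrix_matches_medians(self, rng):
        groups = {"control": pd.DataFrame({"Area": rng.uniform(50, 150, 10)}),
                  "a": pd.DataFrame({"Area": rng.uniform(50, 150, 10)}),
                  "b": pd.DataFrame({"Area": rng.uniform(100, 300, 10)})}
        comps = compare_groups(groups, "control", params=["Area"])
        fold, _ = heatmap_matrix(comps, groups, "control")
        for g in ("a", "b"):
            expected = np.log2(np.median(groups[g]["Area"])
                               / np.median(groups["control"]["Area"]))
            assert fold.loc["Area", g] == pytest.approx(expected)


class TestGrowthNormalization:
    def test_treated_equals_control(self):
        c = np.array([10.0, 20, 40, 80])
        out = normalize_growth_to_control({"t": c.copy()}, c)
        np.testing.assert_allclose(out["t"], 100.0)
        assert inhibition_percent(c.copy(), c) == pytest.approx(0.0)

    def test_inhibition_sixty_three_percent(self):
        control = np.array([10.0, 30, 60, 100])
        treated = control.copy()
        treated[-1] = 0.37 * control[-1]
        assert inhibition_percent(treated, control) == pytest.approx(63.0)

    def test_zero_treated_full_inhibition(self):
        control = np.array([10.0, 30, 100])
        assert inhibition_percent(np.zeros(3), control) == pytest.approx(100.0)

    def test_time_base_mismatch_rejected(self):
        with pytest.raises(ValueError, match="time base"):
            normalize_growth_to_control({"t": np.ones(3)}, np.ones(4))

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_growth_to_control({}, np.array([1.0, 0.0, 2.0]))


def test_smooth_curve_preserves_flat_and_length():
    c = np.array([1.0, 1, 1, 1, 1, 1])
    np.testing.assert_allclose(smooth_curve(c, 5), c)
    noisy = np.array([0.0, 10, 0, 10, 0, 10, 0])
    out = smooth_curve(noisy, 3)
    assert len(out) == len(noisy)
    assert out[1:-1].std() < noisy[1:-1].std()
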