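"""Risk-region determination, clustering, redistribution and reduction."""

import numpy as np
import pytest
from scipy import stats

from plantarstat.gait import PeakPressureMap
from plantarstat.io import RegularGrid
from plantarstat.rroi import (
    CATEGORY_RROI_UNCHANGED,
    CATEGORY_SIG_DECREASE,
    CATEGORY_SIG_INCREASE,
    CATEGORY_UNCHANGED,
    ReductionReport,
    RedistributionModel,
    RiskRegionModel,
    RROIConfig,
    build_rroi,
    classify_cell,
    classify_map,
    redistribution_map,
    residual_reduction,
)

from conftest import make_mppm


class TestClassifyCell:
    def test_mean_at_or_above_threshold_always_in(self):
        for rule in ("not_significantly_below", "significantly_above",
                     "direct_threshold", "dispersion_band"):
            assert classify_cell(250.0, 40.0, 24, RROIConfig(rule=rule))

    def test_significantly_below_excluded_by_default_rule(self):
        # t = (170-200)/(30/sqrt(24)) = -4.899 < -t_crit(0.95, 23) = -1.714
        t = (170 - 200) / (30 / np.sqrt(24))
        assert t == pytest.approx(-4.899, abs=1e-3)
        assert stats.t.ppf(0.95, 23) == pytest.approx(1.714, abs=1e-3)
        assert not classify_cell(170.0, 30.0, 24)

    def test_high_variability_cell_retained_by_default_rule(self):
        # same mean, but SD large enough that it is not significantly below
        assert classify_cell(170.0, 90.0, 24)

    def test_dispersion_band_includes_illustrative_cell(self):
        # 170 +/- 30: within t_crit * SD of the threshold
        assert classify_cell(170.0, 30.0, 24, RROIConfig(rule="dispersion_band"))

    def test_zero_pressure_cell_never_in(self):
        for rule in ("not_significantly_below", "significantly_above",
                     "direct_threshold", "dispersion_band"):
            assert not classify_cell(0.0, 0.0, 24, RROIConfig(rule=rule))

    def test_zero_variance_decided_by_direct_comparison(self):
        for rule in ("not_significantly_below", "significantly_above",
                     "dispersion_band"):
            cfg = RROIConfig(rule=rule)
            assert classify_cell(200.0, 0.0, 24, cfg)
            assert not classify_cell(199.9, 0.0, 24, cfg)

    def test_statistical_rule_needs_n_ge_2(self):
        with pytest.raises(ValueError, match="n >= 2"):
            classify_cell(250.0, 10.0, 1)
        assert classify_cell(250.0, 10.0, 1, RROIConfig(rule="direct_threshold"))


class TestClassifyMapProperties:
    def random_mppms(self, n_maps=200, seed=0):
        rng = np.random.default_rng(seed)
        for _ in range(n_maps):
            shape = (rng.integers(2, 8), rng.integers(2, 8))
            yield (
                rng.uniform(0, 400, shape),
                rng.uniform(0, 80, shape),
                int(rng.integers(2, 60)),
            )

    def test_direct_threshold_subset_of_default(self):
        # the statistical rule is the conservative superset of the cut-off
        for mean, sd, n in self.random_mppms():
            direct = classify_map(mean, sd, n, RROIConfig(rule="direct_threshold"))
            default = classify_map(mean, sd, n, RROIConfig())
            assert np.all(default[direct])

    def test_monotone_in_alpha_default_rule(self):
        for mean, sd, n in self.random_mppms(50, seed=1):
            wide = classify_map(mean, sd, n, RROIConfig(alpha=0.01))
            narrow = classify_map(mean, sd, n, RROIConfig(alpha=0.10))
            assert np.all(wide[narrow])  # smaller alpha never shrinks the mask

    @pytest.mark.parametrize("rule", ["not_significantly_below",
                                      "significantly_above",
                                      "direct_threshold", "dispersion_band"])
    def test_monotone_in_threshold(self, rule):
        for mean, sd, n in self.random_mppms(50, seed=2):
            lo = classify_map(mean, sd, n, RROIConfig(threshold=150, rule=rule))
            hi = classify_map(mean, sd, n, RROIConfig(threshold=250, rule=rule))
            assert np.all(lo[hi])  # higher threshold never grows the mask


def flood_fill_label(mask, connectivity):
    """Independent labelling oracle: BFS flood fill."""
    neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        neigh += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    labels = np.zeros_like(mask, dtype=int)
    current = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                while stack:
                    rr, cc = stack.pop()
                    if labels[rr, cc]:
                        continue
                    labels[rr, cc] = current
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                                and mask[nr, nc] and labels[nr, nc] == 0):
                            stack.append((nr, nc))
    return labels, current


class TestBuildRROI:
    def test_all_zero_map_empty_mask(self):
        mask = build_rroi(make_mppm(np.zeros((4, 4)), np.zeros((4, 4)), 24))
        assert mask.is_empty
        assert mask.total_area_cm2 == 0.0
        assert mask.n_clusters == 0

    def test_area_is_quarter_cm2_per_cell(self):
        mean = np.zeros((10, 10))
        mean.ravel()[:82] = 300.0  # 82 super-threshold cells at 5 mm
        mask = build_rroi(make_mppm(mean, np.full((10, 10), 1.0), 24))
        assert mask.n_cells == 82
        assert mask.total_area_cm2 == pytest.approx(20.5)

    def test_cluster_area_additivity(self):
        mean = np.zeros((8, 8))
        mean[0:2, 0:2] = 300.0
        mean[5:7, 5:8] = 300.0
        mask = build_rroi(make_mppm(mean, np.ones((8, 8)), 24))
        assert mask.cluster_areas_cm2().sum() == pytest.approx(mask.total_area_cm2)

    @pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
    def test_diagonal_blobs_connectivity(self, connectivity, expected):
        mean = np.zeros((6, 6))
        mean[1:3, 1:3] = 300.0
        mean[3:5, 3:5] = 300.0  # touches the first blob only diagonally
        mppm = make_mppm(mean, np.ones((6, 6)), 24)
        mask = build_rroi(mppm, RROIConfig(connectivity=connectivity))
        assert mask.n_clusters == expected
        _, n_oracle = flood_fill_label(mask.in_rroi, connectivity)
        assert mask.n_clusters == n_oracle

    def test_labels_partition_matches_flood_fill(self):
        rng = np.random.default_rng(6)
        mean = np.where(rng.uniform(size=(12, 12)) < 0.3, 300.0, 0.0)
        mppm = make_mppm(mean, np.ones((12, 12)), 24)
        for conn in (4, 8):
            mask = build_rroi(mppm, RROIConfig(connectivity=conn))
            oracle, n = flood_fill_label(mask.in_rroi, conn)
            assert mask.n_clusters == n
            # same partition up to label renaming
            for lab in range(1, mask.n_clusters + 1):
                cells = mask.cluster_labels == lab
                assert len(np.unique(oracle[cells])) == 1


def constant_peak_maps(values_per_step, grid=None):
    values_per_step = np.asarray(values_per_step, dtype=float)
    grid = grid or RegularGrid((0, 0), 5.0, *values_per_step.shape[1:])
    return [PeakPressureMap(grid, v, i) for i, v in enumerate(values_per_step)]


class TestRedistributionMap:
    def make_steps(self, n=24, shape=(4, 4), seed=0, base=150.0):
        rng = np.random.default_rng(seed)
        return base + rng.normal(0, 10, (n, *shape)).clip(-100, None)

    def test_identical_conditions_nothing_significant(self):
        steps = self.make_steps()
        maps = constant_peak_maps(steps)
        rroi = build_rroi(make_mppm(steps.mean(0), steps.std(0, ddof=1), 24))
        out = redistribution_map(maps, maps, rroi)
        assert out.count(CATEGORY_SIG_DECREASE) == 0
        assert out.count(CATEGORY_SIG_INCREASE) == 0
        # R-ROI cells all flagged unchanged-R-ROI, others plain unchanged
        assert out.count(CATEGORY_RROI_UNCHANGED) == rroi.n_cells

    @pytest.mark.parametrize("noise_sd", [0.0, 3.0])
    def test_single_offloaded_cell_detected(self, noise_sd):
        # one cell lowered ~100 kPa on every step, all others untouched;
        # noise_sd=0 exercises the degenerate constant-difference limit
        steps = self.make_steps(base=250.0)
        lowered = steps.copy()
        rng = np.random.default_rng(1)
        lowered[:, 2, 2] -= 100.0 + rng.normal(0, noise_sd, steps.shape[0])
        ref_maps = constant_peak_maps(steps)
        alt_maps = constant_peak_maps(lowered)
        rroi = build_rroi(make_mppm(steps.mean(0), steps.std(0, ddof=1), 24))
        out = redistribution_map(ref_maps, alt_maps, rroi)
        decrease = out.category == CATEGORY_SIG_DECREASE
        assert decrease[2, 2]
        assert decrease.sum() == 1
        if noise_sd > 0:
            # cross-check the cell's paired t against the closed form
            d = lowered[:, 2, 2] - steps[:, 2, 2]
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p = 2 * stats.t.sf(abs(t), len(d) - 1)
            assert p < out.alpha

    def test_zero_variance_zero_difference_not_significant(self):
        steps = np.full((10, 3, 3), 220.0)
        maps = constant_peak_maps(steps)
        rroi = build_rroi(make_mppm(steps.mean(0), steps.std(0, ddof=1), 10))
        out = redistribution_map(maps, maps, rroi)
        assert out.count(CATEGORY_SIG_DECREASE) == 0
        assert out.count(CATEGORY_SIG_INCREASE) == 0

    def test_unequal_step_counts_rejected_in_paired_mode(self):
        steps = self.make_steps()
        rroi = build_rroi(make_mppm(steps.mean(0), steps.std(0, ddof=1), 24))
        with pytest.raises(ValueError, match="paired"):
            redistribution_map(
                constant_peak_maps(steps), constant_peak_maps(steps[:-1]), rroi
            )
        # Welch fallback accepts them
        out = redistribution_map(
            constant_peak_maps(steps), constant_peak_maps(steps[:-1]), rroi,
            RROIConfig(pairing="unpaired"),
        )
        assert out.pairing == "unpaired"

    def test_categories_exhaustive_and_exclusive(self):
        steps = self.make_steps(base=210.0)
        lowered = steps - 30.0
        rroi = build_rroi(make_mppm(steps.mean(0), steps.std(0, ddof=1), 24))
        out = redistribution_map(
            constant_peak_maps(steps), constant_peak_maps(lowered.clip(0)), rroi
        )
        assert set(np.unique(out.category)) <= {
            CATEGORY_UNCHANGED, CATEGORY_SIG_DECREASE,
            CATEGORY_SIG_INCREASE, CATEGORY_RROI_UNCHANGED,
        }
        # rroi_unchanged only inside the reference R-ROI
        assert np.all(rroi.in_rroi[out.category == CATEGORY_RROI_UNCHANGED])


class TestResidualReduction:
    def masked_mppm(self, mean_value, cells, shape=(6, 6), n=24):
        mean = np.zeros(shape)
        for r, c in cells:
            mean[r, c] = mean_value
        return make_mppm(mean, np.ones(shape), n)

    def test_optimal_when_alt_mask_empty(self):
        ref = self.masked_mppm(234.2, [(1, 1), (1, 2)])
        alt = self.masked_mppm(0.0, [])
        rroi_ref = build_rroi(ref)
        rroi_alt = build_rroi(alt)
        report = residual_reduction(ref, rroi_ref, alt, rroi_alt)
        assert report.optimal
        assert report.mean_reduction_kPa is None
        assert report.lower_bound_kPa == pytest.approx(34.2, abs=1e-9)

    def test_lower_bound_zero_at_threshold(self):
        ref = self.masked_mppm(200.0, [(0, 0)])
        report = residual_reduction(ref, build_rroi(ref), ref, build_rroi(ref))
        assert report.lower_bound_kPa == pytest.approx(0.0)

    def test_non_optimal_mean_reduction(self):
        ref = self.masked_mppm(250.0, [(1, 1), (2, 2)])
        alt = self.masked_mppm(220.0, [(4, 4)])
        report = residual_reduction(ref, build_rroi(ref), alt, build_rroi(alt))
        assert not report.optimal
        assert report.mean_reduction_kPa == pytest.approx(30.0)
        assert report.mean_reduction_pct == pytest.approx(100 * 30 / 250)

    def test_empty_reference_rejected(self):
        empty = self.masked_mppm(0.0, [])
        with pytest.raises(ValueError, match="reference"):
            residual_reduction(empty, build_rroi(empty), empty, build_rroi(empty))


class TestModelInterface:
    def test_risk_region_model_summary(self):
        rng = np.random.default_rng(14)
        steps = 230 + rng.normal(0, 15, (24, 5, 5))
        model = RiskRegionModel.from_peak_maps(constant_peak_maps(steps.clip(0)))
        res = model.fit()
        assert res.total_area_cm2 > 0
        text = res.summary()
        assert "R-ROI" in text and f"{res.total_area_cm2:.2f}" in text

    def test_fit_overrides_rule(self):
        rng = np.random.default_rng(15)
        steps = 190 + rng.normal(0, 25, (24, 5, 5))
        model = RiskRegionModel.from_peak_maps(constant_peak_maps(steps.clip(0)))
        conservative = model.fit()
        naive = model.fit(rule="direct_threshold")
        assert naive.mask.n_cells <= conservative.mask.n_cells

    def test_comparison_runs_with_empty_reference_region(self):
        rng = np.random.default_rng(17)
        steps = 80 + rng.normal(0, 8, (24, 4, 4))  # everything sub-threshold
        res = RedistributionModel(
            constant_peak_maps(steps), constant_peak_maps(steps + 5)
        ).fit()
        assert res.rroi_ref.is_empty
        assert res.reduction is None
        assert "n/a" in res.summary()

    def test_redistribution_model_end_to_end(self):
        rng = np.random.default_rng(16)
        steps = 240 + rng.normal(0, 12, (24, 5, 5))
        lowered = steps - 60
        res = RedistributionModel(
            constant_peak_maps(steps), constant_peak_maps(lowered.clip(0))
        ).fit()
        assert res.reduction is not None
        assert res.rroi_alt.total_area_cm2 <= res.rroi_ref.total_area_cm2
        assert "Redistribution" in res.summary()
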