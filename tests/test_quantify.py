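import numpy as np
import pandas as pd
import pytest

from hsrskit import (
    CalibrationFit,
    ConcentrationMaps,
    HyperspectralStack,
    WavenumberAxis,
    aggregate_location,
    central_line,
    compare_populations,
    estimate_concentration,
    extract_cell_features,
    fit_calibration,
    generate_calibration_series,
    population_summaries,
    sweep_threshold,
)
from hsrskit.segmentation import AggregateLabelMask, CellLabelMask


def horizontal_rod(shape=(40, 80), row=20, col_lo=10, col_hi=70, half_width=4):
    mask = np.zeros(shape, bool)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    t = np.clip(cc, col_lo, col_hi)
    dist = np.sqrt((rr - row) ** 2 + (cc - t) ** 2)
    mask[dist <= half_width] = True
    return mask


class TestCentralLine:
    def test_straight_rod_length(self):
        mask = horizontal_rod()
        line = central_line(mask)
        # pole-to-pole span is (70-10) + 2*4 = 68 px
        assert line.length == pytest.approx(68.0, abs=2.0)

    def test_degenerate_circle_errors(self):
        rr, cc = np.mgrid[:20, :20]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 9
        with pytest.raises(ValueError):
            central_line(disk)

    def test_too_small_mask_errors(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            central_line(mask)


class TestAggregateLocation:
    def test_midpoint_is_half(self):
        mask = horizontal_rod()
        d, L, dl = aggregate_location(mask, (20.0, 40.0), mode="centroid")
        assert dl == pytest.approx(0.5, abs=1.5 / L)

    def test_pole_is_one(self):
        mask = horizontal_rod()
        d, L, dl = aggregate_location(mask, (20.0, 73.0), mode="centroid")
        assert dl == pytest.approx(1.0, abs=1.5 / L)

    @pytest.mark.parametrize("frac", [0.6, 0.75, 0.9])
    def test_known_positions_both_modes(self, frac):
        mask = horizontal_rod()
        line = central_line(mask)
        # place the target at arclength frac*L from the left pole
        target = line.points[np.searchsorted(line.arclength, frac * line.length)]
        d, L, dl = aggregate_location(mask, tuple(target), mode="centroid")
        assert dl == pytest.approx(max(frac, 1 - frac), abs=1.5 / L)
        intensity = np.zeros(mask.shape)
        intensity[int(round(target[0])), int(round(target[1]))] = 5.0
        d2, _, dl2 = aggregate_location(mask, intensity, mode="maxline")
        assert abs(d2 - d) <= 1.5

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            aggregate_location(horizontal_rod(), (20.0, 40.0), mode="nope")


def uniform_inputs(cell_labels, agg_labels=None, parent=None, lim_value=2.0):
    """Trivial 3-frame stack + maps aligned with the given masks."""
    H, W = cell_labels.shape
    axis = WavenumberAxis(np.array([750.0, 760.0, 770.0]))
    stack = HyperspectralStack(axis=axis, data=np.ones((3, H, W)))
    lim = np.full((H, W), float(lim_value))
    maps = ConcentrationMaps(
        maps=np.stack([lim, np.ones((H, W)), np.ones((H, W))]),
        names=("limonene", "cell_body", "background"),
        residual_norm=np.zeros((H, W)),
    )
    cells = CellLabelMask(labels=cell_labels)
    aggs = AggregateLabelMask(
        labels=agg_labels if agg_labels is not None else np.zeros((H, W), np.int32),
        parent=parent or {},
    )
    return stack, maps, cells, aggs


class TestExtractFeatures:
    def test_rectangular_cell_basic_stats(self):
        labels = np.zeros((20, 30), np.int32)
        labels[5:9, 10:20] = 1  # 4 x 10 rectangle, area 40
        stack, maps, cells, aggs = uniform_inputs(labels, lim_value=2.0)
        cell_table, agg_table = extract_cell_features(stack, maps, cells, aggs)
        assert len(cell_table) == 1 and agg_table.empty
        row = cell_table.iloc[0]
        assert row["area_px"] == 40
        assert row["mean_limonene"] == pytest.approx(2.0)
        assert row["n_aggregates"] == 0
        assert row["peak760"] == pytest.approx(1.0)  # 760 frame of a ones-stack

    def test_rest_of_cell_excludes_aggregate(self):
        labels = np.zeros((20, 40), np.int32)
        labels[8:13, 5:35] = 1
        agg = np.zeros((20, 40), np.int32)
        agg[9:12, 28:31] = 1
        stack, maps, cells, aggs = uniform_inputs(labels, agg, {1: 1}, lim_value=1.0)
        # paint the aggregate hotter than the rest of the cell
        maps.maps[0][agg == 1] = 5.0
        cell_table, agg_table = extract_cell_features(stack, maps, cells, aggs)
        n_cell = (labels == 1).sum()
        n_agg = (agg == 1).sum()
        expected_rest = 1.0
        expected_whole = (5.0 * n_agg + 1.0 * (n_cell - n_agg)) / n_cell
        assert cell_table.iloc[0]["mean_limonene_rest"] == pytest.approx(expected_rest)
        assert cell_table.iloc[0]["mean_limonene"] == pytest.approx(expected_whole)
        assert agg_table.iloc[0]["mean_limonene"] == pytest.approx(5.0)
        assert agg_table.iloc[0]["total_limonene"] == pytest.approx(5.0 * n_agg)

    def test_misaligned_shapes_rejected(self):
        labels = np.zeros((10, 10), np.int32)
        stack, maps, cells, aggs = uniform_inputs(labels)
        bad_cells = CellLabelMask(labels=np.zeros((12, 12), np.int32))
        with pytest.raises(ValueError):
            extract_cell_features(stack, maps, bad_cells, aggs)

    def test_truth_masks_recover_generating_dl(self, dense_scene, noisy_render, noisy_maps):
        """Label-consistency: truth masks fed to quantify return the generating
        d/L within the 1.5/L pixelation tolerance."""
        stack, _ = noisy_render
        cells = CellLabelMask(labels=dense_scene.cell_labels,
                              pixel_size=dense_scene.params.pixel_size)
        aggs = AggregateLabelMask(labels=dense_scene.aggregate_labels,
                                  parent=dense_scene.aggregate_parent)
        _, agg_table = extract_cell_features(stack, noisy_maps, cells, aggs)
        truth = {a.aggregate_id: a for a in dense_scene.aggregates}
        assert len(agg_table) == len(truth)
        for _, row in agg_table.iterrows():
            t = truth[row["aggregate_id"]]
            assert row["dl_ratio"] == pytest.approx(t.dl_ratio, abs=1.5 / row["L_px"] + 0.01)
            assert row["mean_limonene"] == pytest.approx(t.concentration, abs=0.15)

    def test_dl_bounds_invariant(self, dense_scene, noisy_render, noisy_maps):
        stack, _ = noisy_render
        cells = CellLabelMask(labels=dense_scene.cell_labels)
        aggs = AggregateLabelMask(labels=dense_scene.aggregate_labels,
                                  parent=dense_scene.aggregate_parent)
        _, agg_table = extract_cell_features(stack, noisy_maps, cells, aggs)
        for _, row in agg_table.iterrows():
            L = row["L_px"]
            assert 0.5 - 1.5 / L <= row["dl_ratio_centroid"] <= 1.0 + 1.0 / L


class TestThresholdSweep:
    def test_separated_populations(self):
        chosen, curve = sweep_threshold(
            np.array([1.3, 1.5, 2.0]), np.array([0.2, 0.5, 0.9]),
            grid=np.arange(0.5, 1.55, 0.1),
        )
        assert chosen == pytest.approx(1.0)

    def test_identical_populations_give_none(self):
        vals = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            chosen, _ = sweep_threshold(vals, vals, grid=np.array([0.5, 1.0, 2.0]))
        assert chosen is None

    def test_curve_matches_brute_force_counting(self, rng):
        pos = rng.normal(1.5, 0.4, 500)
        ctl = rng.normal(0.8, 0.3, 500)
        grid = np.linspace(0.0, 3.0, 31)
        _, curve = sweep_threshold(pos, ctl, grid)
        for i, t in enumerate(grid):
            assert curve["frac_positive"][i] == sum(v >= t for v in pos) / 500
            assert curve["frac_control"][i] == sum(v >= t for v in ctl) / 500

    def test_curves_monotone_nonincreasing(self, rng):
        pos = rng.normal(1.0, 0.5, 200)
        ctl = rng.normal(0.5, 0.5, 200)
        _, curve = sweep_threshold(pos, ctl, np.linspace(-1, 3, 50))
        assert (np.diff(curve["frac_positive"]) <= 0).all()
        assert (np.diff(curve["frac_control"]) <= 0).all()

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            sweep_threshold(np.array([]), np.array([1.0]), np.array([0.5, 1.0]))


class TestPopulationSummaries:
    def make_tables(self, n_agg_per_cell, rich_flags=()):
        cells = pd.DataFrame({
            "cell_id": range(1, len(n_agg_per_cell) + 1),
            "n_aggregates": n_agg_per_cell,
        })
        aggs = []
        aid = 1
        for cid, n in enumerate(n_agg_per_cell, start=1):
            for _ in range(n):
                aggs.append({"aggregate_id": aid, "cell_id": cid, "area_px": 9,
                             "mean_limonene": 1.0,
                             "limonene_rich": aid in rich_flags})
                aid += 1
        return cells, pd.DataFrame(aggs)

    def test_fraction_with_aggregates(self):
        cells, aggs = self.make_tables([0] * 8 + [1, 2])
        s = population_summaries(cells, aggs)
        assert s["frac_cells_with_aggregates"] == pytest.approx(0.2)
        assert s["aggregate_count_histogram"] == {0: 8, 1: 1, 2: 1}

    def test_no_rich_flags(self):
        cells, aggs = self.make_tables([1, 1, 0])
        s = population_summaries(cells, aggs)
        assert s["frac_cells_limonene_rich"] == 0.0

    def test_label_permutation_invariance(self, rng):
        counts = list(rng.integers(0, 3, 30))
        cells, aggs = self.make_tables(counts)
        perm = rng.permutation(len(cells))
        s1 = population_summaries(cells, aggs)
        s2 = population_summaries(cells.iloc[perm].reset_index(drop=True), aggs)
        assert s1["frac_cells_with_aggregates"] == s2["frac_cells_with_aggregates"]
        assert s1["aggregate_count_histogram"] == s2["aggregate_count_histogram"]

    def test_empty_cell_table_rejected(self):
        with pytest.raises(ValueError):
            population_summaries(pd.DataFrame(), pd.DataFrame())


class TestCalibration:
    def test_noiseless_line_exact(self):
        df = pd.DataFrame({"conc_mm": [0.0, 0.0, 50.0, 100.0],
                           "intensity": [0.0, 0.0, 100.0, 200.0]})
        fit = fit_calibration(df)
        assert fit.slope == pytest.approx(2.0, rel=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.lod_mm == 0.0
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_lod_is_three_sigma_over_slope(self):
        # blanks {-14, 0, 14} have sd exactly 14; the line keeps slope 2
        df = pd.DataFrame({"conc_mm": [0.0, 0.0, 0.0, 50.0, 100.0],
                           "intensity": [-14.0, 0.0, 14.0, 100.0, 200.0]})
        fit = fit_calibration(df)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.blank_sigma == pytest.approx(14.0, rel=1e-12)
        assert fit.lod_mm == pytest.approx(21.0, rel=1e-12)

    def test_recovers_generator_slope_within_2se(self):
        df = generate_calibration_series(n_replicates=1000, seed=4)
        fit = fit_calibration(df)
        assert abs(fit.slope - 2.0) <= 2 * fit.slope_stderr

    def test_negative_slope_invalid(self):
        df = pd.DataFrame({"conc_mm": [0.0, 0.0, 50.0, 100.0],
                           "intensity": [100.0, 100.0, 50.0, 0.0]})
        with pytest.raises(ValueError, match="slope"):
            fit_calibration(df)

    def test_requires_blanks_and_three_levels(self):
        with pytest.raises(ValueError):
            fit_calibration(pd.DataFrame({"conc_mm": [0.0, 1.0],
                                          "intensity": [0.0, 2.0]}))
        with pytest.raises(ValueError):
            fit_calibration(pd.DataFrame({"conc_mm": [1.0, 2.0, 3.0],
                                          "intensity": [2.0, 4.0, 6.0]}))


class TestEstimateConcentration:
    fit = CalibrationFit(slope=2.0, intercept=0.0, blank_sigma=14.0,
                         lod_mm=21.0, r2=0.99)

    @pytest.mark.parametrize("intensity, expected", [
        (10.0, 0.0),          # equal to blank
        (10.0 + 2.0 * 50, 50.0),
        (0.0, 0.0),           # below blank floors at zero
    ])
    def test_inverse_line(self, intensity, expected):
        assert estimate_concentration(intensity, 10.0, self.fit) == pytest.approx(expected)

    def test_invalid_fit_rejected(self):
        bad = CalibrationFit(slope=0.0, intercept=0.0, blank_sigma=1.0,
                             lod_mm=0.0, r2=0.0)
        with pytest.raises(ValueError):
            estimate_concentration(1.0, 0.0, bad)


def test_benjamini_hochberg_adjustment():
    from hsrskit import adjust_pvalues

    raw = np.array([0.04, 0.005, 0.03, 0.01])
    adjusted = adjust_pvalues(raw)
    # BH by hand: sorted [0.005, 0.01, 0.03, 0.04] -> [0.02, 0.02, 0.04, 0.04]
    np.testing.assert_allclose(adjusted, [0.04, 0.02, 0.04, 0.02])
    assert (adjusted >= raw - 1e-15).all()


class TestComparePopulations:
    def test_identical_samples_p_near_one(self):
        stat, p = compare_populations([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_fully_separated_u_is_zero(self):
        stat, p = compare_populations([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert stat == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_populations([], [1.0])
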