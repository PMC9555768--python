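"""Grid binning, density arithmetic and the genotype-comparison statistics."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from rescuekit.spatial import (
    BinCounts,
    DensityMatrix,
    GridSpec,
    SectionPattern,
    SpatialDensityModel,
    assign_bins,
    chi2_distribution_test,
    compute_density,
    heatmap_matrix,
    numerosity_tests,
    per_bin_tests,
    plot_heatmap,
    pool_segment,
)

from oracles import bh_stepup, mannwhitney_exact_greater


def section(points, embryo="e1", genotype="WT", segment="A", idx=1):
    return SectionPattern(points=np.asarray(points, float).reshape(-1, 2),
                         section_index=idx, embryo_id=embryo,
                         genotype=genotype, segment=segment)


GRID = GridSpec()  # 5 rows x 4 cols over 200 x 160 um


class TestAssignBins:
    def test_single_point_at_anchor_bin_centroid(self):
        counts = assign_bins(section([(25.0, 16.0)]), GRID)  # centroid of bin 1
        assert counts.counts[0] == 1 and counts.total == 1

    def test_interior_boundary_goes_to_higher_index_bin(self):
        # x = 50 is the boundary between columns 1 and 2 (half-open bins)
        counts = assign_bins(section([(50.0, 10.0)]), GRID)
        assert counts.counts[1] == 1
        assert counts.total == 1  # never double-counted

    def test_outer_edge_point_belongs_to_last_bin(self):
        counts = assign_bins(section([(200.0, 160.0)]), GRID)
        assert counts.counts[-1] == 1 and counts.overflow == 0

    def test_outside_points_tallied_not_dropped(self):
        counts = assign_bins(section([(-1.0, 5.0), (10.0, 10.0)]), GRID)
        assert counts.overflow == 1 and counts.total == 1

    def test_uniform_pattern_fills_bins_binomially(self, rng):
        n = 10_000
        pts = rng.uniform([0, 0], [GRID.width, GRID.height], size=(n, 2))
        counts = assign_bins(section(pts), GRID)
        assert counts.total == n
        expected = n / GRID.n_bins
        sd = math.sqrt(n * (1 / 20) * (19 / 20))
        assert all(abs(c - expected) < 5 * sd for c in counts.counts)

    def test_count_conservation_on_random_sections(self, rng):
        for _ in range(200):
            n = rng.integers(0, 400)
            pts = rng.uniform([-20, -20], [GRID.width + 20, GRID.height + 20],
                              size=(n, 2))
            counts = assign_bins(section(pts), GRID)
            assert counts.total + counts.overflow == n


class TestComputeDensity:
    def test_five_cells_in_250_um2_is_two_per_100um2(self):
        grid = GridSpec(n_rows=5, n_cols=4, width=50, height=100)  # 250 um2 bins
        counts = BinCounts(counts=(5,) + (0,) * 19)
        dens = compute_density(counts, grid)
        assert dens.densities[0] == pytest.approx(2.0)

    def test_zero_counts_give_zero_densities(self):
        dens = compute_density(BinCounts(counts=(0,) * 20), GRID)
        assert all(d == 0.0 for d in dens.densities)

    def test_doubling_areas_halves_densities(self):
        counts = BinCounts(counts=tuple(range(20)))
        base = compute_density(counts, GRID).as_array()
        doubled_grid = GridSpec(bin_areas=tuple(GRID.areas * 2))
        doubled = compute_density(counts, doubled_grid).as_array()
        np.testing.assert_allclose(doubled, base / 2)

    def test_counts_recoverable_from_densities(self, rng):
        counts = BinCounts(counts=tuple(rng.integers(0, 50, size=20)))
        dens = compute_density(counts, GRID)
        back = dens.as_array() * GRID.areas / 100.0
        np.testing.assert_allclose(back, counts.counts, atol=1e-9)


class TestPoolSegment:
    def test_pooling_is_additive_and_order_invariant(self, rng):
        s1 = section(rng.uniform(0, 150, size=(30, 2)), idx=1)
        s2 = section(rng.uniform(0, 150, size=(40, 2)), idx=2)
        c1, c2 = assign_bins(s1, GRID), assign_bins(s2, GRID)
        pooled_ab, _, _ = pool_segment([s1, s2], "A", GRID)
        pooled_ba, _, _ = pool_segment([s2, s1], "A", GRID)
        assert pooled_ab.counts == tuple(a + b for a, b in zip(c1.counts, c2.counts))
        assert pooled_ab == pooled_ba

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            pool_segment([section([(1, 1)], segment="A")], "P", GRID)

    def test_mixed_genotype_embryo_rejected(self):
        s1 = section([(1, 1)], embryo="e1", genotype="WT")
        s2 = section([(2, 2)], embryo="e1", genotype="null", idx=2)
        with pytest.raises(ValueError, match="mixed"):
            pool_segment([s1, s2], "A", GRID)

    def test_per_unit_density_is_mean_per_section_density(self):
        pts = [(25.0, 16.0)]
        s1, s2 = section(pts, idx=1), section(pts, idx=2)
        _, _, dens = pool_segment([s1, s2], "A", GRID)
        # 2 cells over 2 sections of a 1600 um2 bin -> 1 cell/section/bin
        assert dens["e1"].densities[0] == pytest.approx(100.0 / 1600.0)


class TestChi2DistributionTest:
    def test_identical_compositions_give_zero_statistic(self):
        a = BinCounts(counts=tuple(range(1, 21)))
        stat, p = chi2_distribution_test(a, a)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_disjoint_concentrations_match_closed_form(self):
        a = BinCounts(counts=(100,) + (0,) * 19)
        b = BinCounts(counts=(0, 100) + (0,) * 18)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = chi2_distribution_test(a, b)
        # empty bins drop, leaving the 2x2 table [[100,0],[0,100]]: X2 = 200, df 1
        assert stat == pytest.approx(200.0)
        assert p == pytest.approx(float(chi2_dist.sf(200.0, 1)), rel=1e-10)
        assert p < 1e-10

    def test_statistic_invariant_under_joint_bin_permutation(self, rng):
        av = rng.integers(1, 60, size=20)
        bv = rng.integers(1, 60, size=20)
        perm = rng.permutation(20)
        s1, _ = chi2_distribution_test(BinCounts(counts=tuple(av)),
                                       BinCounts(counts=tuple(bv)))
        s2, _ = chi2_distribution_test(BinCounts(counts=tuple(av[perm])),
                                       BinCounts(counts=tuple(bv[perm])))
        assert s1 == pytest.approx(s2)

    def test_all_zero_group_rejected(self):
        with pytest.raises(ValueError):
            chi2_distribution_test(BinCounts(counts=(0,) * 20),
                                   BinCounts(counts=(1,) * 20))

    def test_low_expected_counts_warn(self):
        a = BinCounts(counts=(1, 1) + (0,) * 18)
        b = BinCounts(counts=(1, 0) + (0,) * 18)
        with pytest.warns(UserWarning, match="expected"):
            chi2_distribution_test(a, b)


class TestPerBinTests:
    def test_identical_groups_are_never_significant(self, rng):
        group = [DensityMatrix(densities=tuple(rng.uniform(1, 5, 20)))
                 for _ in range(4)]
        results = per_bin_tests(group, group)
        assert all(r.p_raw >= 0.5 for r in results)
        assert all(r.p_bh >= r.p_raw for r in results)

    def test_single_bin_family_leaves_p_unchanged(self, rng):
        a = [DensityMatrix(densities=(v,)) for v in rng.uniform(1, 2, 3)]
        b = [DensityMatrix(densities=(v,)) for v in rng.uniform(2, 3, 3)]
        (res,) = per_bin_tests(a, b)
        assert res.p_bh == pytest.approx(res.p_raw)

    def test_bh_adjustment_matches_reference_stepup(self, rng):
        a = [DensityMatrix(densities=tuple(rng.uniform(1, 5, 20))) for _ in range(5)]
        b = [DensityMatrix(densities=tuple(rng.uniform(1, 6, 20))) for _ in range(5)]
        results = per_bin_tests(a, b)
        expected = bh_stepup([r.p_raw for r in results])
        np.testing.assert_allclose([r.p_bh for r in results], expected, rtol=1e-10)
        order = np.argsort([r.p_raw for r in results])
        adj_sorted = np.asarray([results[i].p_bh for i in order])
        assert (np.diff(adj_sorted) >= -1e-12).all()
        assert all(r.p_bh <= 1.0 for r in results)

    def test_planted_shift_detected_with_power(self, rng):
        """+5 sd shift in bin 7 of group B, n=5/group: minimum adjusted p in
        bin 7 and significance in >= 95% of 500 simulations."""
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            A = rng.normal(10, 1, size=(5, 20))
            B = rng.normal(10, 1, size=(5, 20))
            B[:, 6] += 5.0
            res = per_bin_tests(
                [DensityMatrix(densities=tuple(r)) for r in A],
                [DensityMatrix(densities=tuple(r)) for r in B],
            )
            p_bh = np.array([r.p_bh for r in res])
            if p_bh.argmin() == 6 and p_bh[6] < 0.05:
                hits += 1
        assert hits / n_sims >= 0.95

    def test_undersized_group_rejected_by_name(self):
        d = DensityMatrix(densities=(1.0,) * 20)
        with pytest.raises(ValueError, match="group A"):
            per_bin_tests([d], [d, d])
        with pytest.raises(ValueError, match="group B"):
            per_bin_tests([d, d], [d])


class TestNumerosityTests:
    def test_clearly_separated_groups_have_exact_p_one_twentieth(self):
        res = numerosity_tests({"WT": [10, 11, 12], "null": [40, 41, 42]})
        pair = dict((a, p) for a, _, p in res.pairwise)
        assert pair["null_vs_WT"] == pytest.approx(1 / math.comb(6, 3))
        assert pair["null_vs_WT"] == pytest.approx(
            mannwhitney_exact_greater([40, 41, 42], [10, 11, 12])
        )

    def test_identical_totals_report_unit_p_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            res = numerosity_tests({"WT": [5, 5, 5], "null": [5, 5, 5]})
        assert res.kw_p == 1.0

    def test_embryo_order_does_not_change_statistics(self):
        a = numerosity_tests({"WT": [10, 14, 12], "null": [22, 18, 30]})
        b = numerosity_tests({"WT": [12, 10, 14], "null": [30, 22, 18]})
        assert a.kw_statistic == pytest.approx(b.kw_statistic)
        assert a.pairwise == b.pairwise

    def test_single_embryo_genotype_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            numerosity_tests({"WT": [10, 11, 12], "null": [40]})


class TestHeatmapMatrix:
    def test_all_below_first_break_is_class_zero(self):
        d = [DensityMatrix(densities=(0.1,) * 20)]
        _, classes = heatmap_matrix(d, breaks=[1.0, 2.0, 3.0])
        assert (classes == 0).all()

    def test_class_index_nondecreasing_in_density(self, rng):
        means = np.sort(rng.uniform(0, 10, 20))
        d = [DensityMatrix(densities=tuple(means))]
        _, classes = heatmap_matrix(d, breaks=[2.5, 5.0, 7.5])
        assert (np.diff(classes) >= 0).all()

    def test_default_quartile_breaks_balance_classes(self, rng):
        # distinct uniform bin means -> quartile breaks split 20 bins 5/5/5/5
        d = [DensityMatrix(densities=tuple(rng.permutation(np.arange(1.0, 21.0))))]
        _, classes = heatmap_matrix(d)
        assert sorted(np.bincount(classes, minlength=4)) == [5, 5, 5, 5]

    def test_nonmonotone_breaks_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            heatmap_matrix([DensityMatrix(densities=(1.0,) * 20)], breaks=[2.0, 1.0])

    def test_plot_written_to_disk(self, tmp_path, rng):
        means = rng.uniform(0, 3, size=(5, 4))
        out = tmp_path / "map.png"
        plot_heatmap(means, str(out), title="demo")
        assert out.stat().st_size > 0


class TestSpatialDensityModel:
    def test_unknown_genotype_label_lists_found_labels(self):
        import pandas as pd

        df = pd.DataFrame({
            "x_um": [1.0], "y_um": [1.0], "section": [1],
            "embryo": ["e1"], "genotype": ["mystery"], "segment": ["A"],
        })
        with pytest.raises(ValueError, match="mystery"):
            SpatialDensityModel.from_dataframe(df)

    def test_single_embryo_genotype_degrades_gracefully(self, rng):
        pats = []
        for emb in ("WT_e1", "WT_e2"):
            pats.append(section(rng.uniform(0, 150, (30, 2)), embryo=emb,
                                genotype="WT"))
        pats.append(section(rng.uniform(0, 150, (30, 2)), embryo="null_e1",
                            genotype="null"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = SpatialDensityModel(pats).fit()
        # numerosity errored but densities and chi-square are still reported
        assert "A" in res.numerosity_errors
        assert ("null", "A") in res.chi2_tests
        assert ("null", "A") in res.embryo_densities
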