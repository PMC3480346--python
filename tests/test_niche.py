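"""Exposure accounting, population binning, LOESS surfaces and peaks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import climniche as cn
from climniche import niche
from climniche.exceptions import DataError, DomainError


class TestMeans:
    def test_exposure_equal_weights_is_mean(self):
        v = np.array([3.0, 7.0, 11.0])
        assert cn.exposure_mean(v, np.ones(3)) == v.mean()

    def test_exposure_point_mass(self):
        assert cn.exposure_mean([10.0, 20.0], [0.0, 5.0]) == 20.0

    def test_exposure_weighted(self):
        assert cn.exposure_mean([10.0, 20.0], [1.0, 3.0]) == 17.5

    def test_exposure_zero_weight_errors(self):
        with pytest.raises(DomainError):
            cn.exposure_mean([1.0], [0.0])

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exposure_invariant_to_weight_scaling(self, scale):
        v = np.array([1.0, 4.0, 9.0])
        w = np.array([1.0, 2.0, 3.0])
        assert cn.exposure_mean(v, w * scale) == pytest.approx(
            cn.exposure_mean(v, w), rel=1e-12)

    @pytest.mark.parametrize("vals,expected", [
        ([10.0, 20.0], 15.0), ([4.0, 4.0, 4.0], 4.0), ([7.0], 7.0)])
    def test_area_mean(self, vals, expected):
        assert cn.area_mean(vals) == expected

    def test_uniform_population_identity_exact(self):
        rng = np.random.default_rng(1)
        v = rng.normal(10, 3, 101)
        assert cn.exposure_mean(v, np.full(101, 37.0)) == cn.area_mean(v)


class TestTrajectory:
    def test_matches_analytic_oracle(self, amplification_bundle):
        b = amplification_bundle
        years = list(b.config.census_years)
        pops = b.county_table[["county_id"] + [f"pop_{y}" for y in years]]
        traj = cn.exposure_trajectory(b.normals, pops, years)
        got = (traj.table[traj.table["variable"] == "annual_temp"]
               .set_index("year")["exposure_mean"])
        want = b.expected_exposure.set_index("year")["expected_exposure"]
        np.testing.assert_allclose(got, want, atol=1e-8)
        de, da = traj.deltas["annual_temp"]
        assert da == 0.0 and de > 0

    def test_area_mean_flagged_for_first_census(self, amplification_bundle):
        b = amplification_bundle
        years = list(b.config.census_years)
        pops = b.county_table[["county_id"] + [f"pop_{y}" for y in years]]
        traj = cn.exposure_trajectory(b.normals, pops, years)
        first = traj.table[traj.table["year"] == years[0]]
        assert (~first["area_valid"]).all()
        assert first["area_mean"].isna().all()

    def test_population_swap_flips_delta_sign(self, amplification_bundle):
        b = amplification_bundle
        years = list(b.config.census_years)
        pops = b.county_table[["county_id"] + [f"pop_{y}" for y in years]]
        cols = [f"pop_{y}" for y in years]
        flipped = pops.copy()
        flipped[cols] = pops[cols].to_numpy()[::-1]  # cold counties now grow
        t1 = cn.exposure_trajectory(b.normals, pops, years)
        t2 = cn.exposure_trajectory(b.normals, flipped, years)
        assert t1.deltas["annual_temp"][0] * t2.deltas["annual_temp"][0] < 0


class TestAmplificationRatio:
    def test_values(self):
        assert cn.amplification_ratio(1.5, 0.24) == pytest.approx(6.25)
        assert cn.amplification_ratio(0.3, 0.3) == 1.0

    def test_zero_area_change_is_undefined_not_fatal(self):
        assert math.isnan(cn.amplification_ratio(0.5, 0.0))


class TestBinPopulation:
    def _axes(self):
        return (cn.AxisSpec("a", 0, 10, 5), cn.AxisSpec("b", 0, 10, 5))

    def test_single_county(self):
        a1, a2 = self._axes()
        g = niche.bin_population([3.0], [7.0], [42.0], a1, a2)
        assert g.sum() == 42.0 and g[1, 3] == 42.0

    def test_same_cell_sums(self):
        a1, a2 = self._axes()
        g = niche.bin_population([1.0, 1.5], [1.0, 1.2], [10.0, 5.0], a1, a2)
        assert g[0, 0] == 15.0

    def test_interior_edge_goes_to_upper_cell(self):
        a1, a2 = self._axes()
        g = niche.bin_population([2.0], [0.0], [1.0], a1, a2)
        assert g[1, 0] == 1.0  # edge value 2.0 belongs to cell [2, 4)

    def test_top_edge_closed(self):
        a1, a2 = self._axes()
        g = niche.bin_population([10.0], [10.0], [1.0], a1, a2)
        assert g[4, 4] == 1.0

    def test_strict_policy_errors_out_of_range(self):
        a1, a2 = self._axes()
        with pytest.raises(DataError):
            niche.bin_population([11.0], [0.0], [1.0], a1, a2)
        g = niche.bin_population([11.0, 1.0], [0.0, 1.0], [1.0, 2.0],
                                 a1, a2, policy="drop")
        assert g.sum() == 2.0

    def test_conserves_integer_totals(self):
        a1, a2 = self._axes()
        rng = np.random.default_rng(0)
        c1 = rng.uniform(0, 10, 200)
        c2 = rng.uniform(0, 10, 200)
        pop = rng.integers(1, 1000, 200).astype(float)
        g = niche.bin_population(c1, c2, pop, a1, a2)
        assert g.sum() == pop.sum()


class TestLoess:
    def test_constant_grid_reproduced(self):
        a1 = cn.AxisSpec("a", 0, 10, 10)
        a2 = cn.AxisSpec("b", 0, 10, 10)
        raw = np.full((10, 10), 99.0)
        sm = cn.loess_surface(raw, a1, a2, alpha=0.3)
        np.testing.assert_allclose(sm, math.log10(100.0), atol=1e-8)

    def test_single_bump_argmax_within_one_cell(self):
        a1 = cn.AxisSpec("a", 0, 20, 20)
        a2 = cn.AxisSpec("b", 0, 20, 20)
        X, Y = np.meshgrid(a1.centers, a2.centers, indexing="ij")
        raw = 1e4 * np.exp(-((X - 10.5) ** 2 + (Y - 8.5) ** 2) / 8.0)
        sm = cn.loess_surface(raw, a1, a2, alpha=0.3, degree=2)
        i, j = np.unravel_index(sm.argmax(), sm.shape)
        ti, tj = np.unravel_index(raw.argmax(), raw.shape)
        assert abs(i - ti) <= 1 and abs(j - tj) <= 1

    def test_alpha_one_oversmooths_bimodal(self, bimodal_fixture):
        f = bimodal_fixture
        raw = niche.bin_population(f["c1"], f["c2"], f["pop"],
                                   f["axis1"], f["axis2"])
        tight = cn.loess_surface(raw, f["axis1"], f["axis2"], alpha=0.3)
        wide = cn.loess_surface(raw, f["axis1"], f["axis2"], alpha=1.0)
        assert wide.max() < tight.max()


class TestFindPeaks:
    def test_monotone_plane_has_no_peaks(self):
        X, Y = np.meshgrid(np.arange(10.0), np.arange(10.0), indexing="ij")
        assert len(cn.find_peaks(X + 0.5 * Y)) == 0

    def test_two_bumps_found_at_centers(self):
        X, Y = np.meshgrid(np.arange(20.0), np.arange(20.0), indexing="ij")
        s = (np.exp(-((X - 5) ** 2 + (Y - 5) ** 2) / 4.0)
             + 2 * np.exp(-((X - 14) ** 2 + (Y - 15) ** 2) / 4.0))
        pk = cn.find_peaks(s, min_separation=3)
        assert len(pk) == 2
        assert (pk.loc[0, "row"], pk.loc[0, "col"]) == (14, 15)
        assert (pk.loc[1, "row"], pk.loc[1, "col"]) == (5, 5)

    def test_close_bumps_thinned_to_higher(self):
        X, Y = np.meshgrid(np.arange(20.0), np.arange(20.0), indexing="ij")
        s = (np.exp(-((X - 8) ** 2 + (Y - 8) ** 2) / 2.0)
             + 2 * np.exp(-((X - 10) ** 2 + (Y - 8) ** 2) / 2.0))
        pk = cn.find_peaks(s, min_separation=4)
        assert len(pk) == 1
        assert pk.loc[0, "row"] == 10

    def test_min_height_filters(self):
        X, Y = np.meshgrid(np.arange(10.0), np.arange(10.0), indexing="ij")
        s = np.exp(-((X - 5) ** 2 + (Y - 5) ** 2) / 4.0)
        assert len(cn.find_peaks(s, min_height=2.0)) == 0


class TestPeakTracking:
    def _surface(self, f, pop_scale=(1.0, 1.0)):
        c1, c2, pop = f["c1"], f["c2"], f["pop"].copy()
        left = c1 < 10
        pop[left] *= pop_scale[0]
        pop[~left] *= pop_scale[1]
        return cn.build_surface(c1, c2, pop, f["axis1"], f["axis2"],
                                alpha=0.3, min_separation=3)

    def test_identical_surfaces_constant_series(self, bimodal_fixture):
        surf = self._surface(bimodal_fixture)
        series = niche.peak_abundance_series({1900: surf, 1920: surf,
                                              1940: surf}, radius=0.25)
        for _, g in series.groupby("lineage"):
            assert g["abundance"].nunique() == 1
        assert series["lineage"].nunique() == 2

    def test_growing_peak_tracked_as_increasing(self, bimodal_fixture):
        f = bimodal_fixture
        surfaces = {1900: self._surface(f),
                    1920: self._surface(f, (1.0, 2.0)),
                    1940: self._surface(f, (1.0, 4.0))}
        series = niche.peak_abundance_series(surfaces, radius=0.25)
        # the warm (right) lineage grows; the other stays flat
        by_lineage = {li: g.sort_values("year")["abundance"].to_numpy()
                      for li, g in series.groupby("lineage")}
        grew = [li for li, a in by_lineage.items() if a[-1] > 2 * a[0]]
        flat = [li for li, a in by_lineage.items()
                if np.allclose(a, a[0], rtol=1e-6)]
        assert len(grew) == 1 and len(flat) == 1
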