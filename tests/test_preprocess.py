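"""Inclusion rules and transformations: the monitoring-protocol toy cases
plus idempotence/exactness properties."""
import numpy as np
import pandas as pd
import pytest

from traitflux import (
    CommunityTimeSeries,
    filter_cumulative_abundance,
    filter_rare_taxa,
    impute_missing_years,
    ln_transform,
    standardize_anomaly,
)


def community_from_presence(presence: dict, n_years: int = 40) -> CommunityTimeSeries:
    years = np.arange(1971, 1971 + n_years)
    dens = pd.DataFrame(0.0, index=pd.Index(years, name="year"), columns=list(presence))
    for taxon, occ in presence.items():
        for i in occ:
            dens.iloc[i, dens.columns.get_loc(taxon)] = 1.0
    return CommunityTimeSeries(density=dens)


class TestRareTaxonFilter:
    @pytest.mark.parametrize(
        "occ,kept",
        [
            ({5, 17}, False),          # twice, scattered: not established
            ({5, 6}, True),            # consecutive years: retained
            ({3, 11, 27}, True),       # 3/40 = 7.5%: above threshold
            ({8}, False),              # single occurrence
        ],
    )
    def test_establishment_rule(self, occ, kept):
        cts = community_from_presence({"x": occ, "anchor": set(range(40))})
        out = filter_rare_taxa(cts)
        assert ("x" in out.taxa) is kept

    def test_idempotent_and_densities_unchanged(self):
        cts = community_from_presence(
            {"a": {1, 2, 3}, "b": {5, 17}, "c": set(range(0, 40, 3))}
        )
        once = filter_rare_taxa(cts)
        twice = filter_rare_taxa(once)
        pd.testing.assert_frame_equal(once.density, twice.density)
        pd.testing.assert_frame_equal(once.density, cts.density[once.taxa])

    def test_all_removed_warns_not_raises(self):
        cts = community_from_presence({"a": {2}, "b": {30}})
        with pytest.warns(UserWarning):
            out = filter_rare_taxa(cts)
        assert out.taxa == []


class TestCumulativeAbundanceFilter:
    def test_96_percent_rule_keeps_top_three_of_five(self):
        years = pd.Index([2000, 2001], name="year")
        dens = pd.DataFrame(
            {"a": [30, 30], "b": [15, 15], "c": [3, 3], "d": [1.5, 1.5], "e": [0.5, 0.5]},
            index=years,
        )  # totals 60, 30, 6, 3, 1
        out = filter_cumulative_abundance(CommunityTimeSeries(density=dens), 0.96)
        assert out.taxa == ["a", "b", "c"]

    def test_threshold_one_keeps_everything(self):
        years = pd.Index([2000], name="year")
        dens = pd.DataFrame({"a": [5.0], "b": [1.0]}, index=years)
        out = filter_cumulative_abundance(CommunityTimeSeries(density=dens), 1.0)
        assert out.taxa == ["a", "b"]

    def test_single_taxon_retained(self):
        dens = pd.DataFrame({"only": [2.0, 3.0]}, index=pd.Index([2000, 2001], name="year"))
        out = filter_cumulative_abundance(CommunityTimeSeries(density=dens))
        assert out.taxa == ["only"]

    def test_all_zero_rejected(self):
        dens = pd.DataFrame({"a": [0.0]}, index=pd.Index([2000], name="year"))
        with pytest.raises(ValueError):
            filter_cumulative_abundance(CommunityTimeSeries(density=dens))


class TestLnTransform:
    def test_ln_plus_one(self, small_community):
        out = ln_transform(small_community)
        np.testing.assert_allclose(
            out.density.to_numpy(), np.log1p(small_community.density.to_numpy())
        )

    def test_zero_maps_to_zero_and_e_minus_one_to_one(self):
        dens = pd.DataFrame(
            {"a": [0.0, np.e - 1.0]}, index=pd.Index([2000, 2001], name="year")
        )
        out = ln_transform(CommunityTimeSeries(density=dens))
        np.testing.assert_allclose(out.density["a"].to_numpy(), [0.0, 1.0])


class TestImputation:
    def test_interior_gap_is_neighbour_average(self):
        s = pd.Series([1.0, np.nan, 3.0], index=[2000, 2001, 2002])
        np.testing.assert_allclose(impute_missing_years(s).to_numpy(), [1, 2, 3])

    def test_gap_free_series_unchanged(self):
        s = pd.Series([4.0, 5.0, 6.0], index=[2000, 2001, 2002])
        np.testing.assert_allclose(impute_missing_years(s).to_numpy(), s.to_numpy())

    def test_boundary_gap_copies_nearest(self):
        s = pd.Series([np.nan, 4.0, 6.0], index=[2000, 2001, 2002])
        np.testing.assert_allclose(impute_missing_years(s).to_numpy(), [4, 4, 6])

    def test_absent_index_years_are_filled(self):
        s = pd.Series([1.0, 3.0], index=[2000, 2002])
        out = impute_missing_years(s)
        assert list(out.index) == [2000, 2001, 2002]
        np.testing.assert_allclose(out.to_numpy(), [1, 2, 3])

    def test_observed_values_preserved_exactly(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        s = pd.Series(vals, index=np.arange(1990, 2010))
        s.iloc[[3, 4, 11]] = np.nan
        out = impute_missing_years(s)
        obs = s.notna()
        np.testing.assert_array_equal(out[obs.index[obs]].to_numpy(), vals[obs.to_numpy()])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_missing_years(pd.Series([np.nan, np.nan], index=[2000, 2001]))


class TestAnomalyStandardisation:
    def test_unit_spacing_case(self):
        np.testing.assert_allclose(standardize_anomaly([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_zero_mean_unit_sample_sd(self):
        rng = np.random.default_rng(1)
        out = standardize_anomaly(rng.normal(3.0, 2.5, size=37))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1.0) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        once = standardize_anomaly(rng.normal(size=25))
        np.testing.assert_allclose(standardize_anomaly(once), once, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            standardize_anomaly([2.0, 2.0, 2.0])
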