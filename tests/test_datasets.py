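"""Three-file schema contracts: validation, zero-filling, summaries, round trips."""

import numpy as np
import pandas as pd
import pytest

from mudflat.datasets import (
    CampaignSummary,
    per_year_from_samples,
    read_table,
    reference_campaign_table,
    round_half_up,
    summarize_campaign,
    summarize_community,
    validate,
    write_table,
    zero_fill,
)
from mudflat.errors import SchemaError


@pytest.fixture()
def tiny_tables():
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "sampling_station_id": ["G1", "G2", "R1"],
            "sampling_type": ["grid", "grid", "random"],
            "date": ["2015-06-01", "2015-06-02", "2015-06-03"],
            "platform": ["boat", "walk", "boat"],
            "tidal_basin_name": ["b1", "b1", "b2"],
            "tidal_flat_name": ["f1", "f1", "f2"],
            "x": [5.1, 5.2, 5.3],
            "y": [53.1, 53.2, 53.3],
            "median_grain_size": [150.0, np.nan, 210.0],
            "percentage_mud": [12.0, 55.0, np.nan],
        }
    )
    species = pd.DataFrame(
        {
            "sibes_id": [1, 2],
            "name": ["Clam", "Snail"],
            "aphia_id": [100, 101],
            "occupancy": [50.0, 10.0],
        }
    )
    biota = pd.DataFrame(
        {
            "sample_id": ["s1", "s3"],
            "sibes_id": [1, 2],
            "abundance_m2": [57.8, 115.6],
            "afdm_m2": [1.2, np.nan],
        }
    )
    return samples, species, biota


class TestValidate:
    def test_clean_tables_pass(self, tiny_tables):
        assert validate(*tiny_tables).ok

    def test_duplicate_sample_id_flagged(self, tiny_tables):
        samples, species, biota = tiny_tables
        dup = pd.concat([samples, samples.iloc[[0]]], ignore_index=True)
        report = validate(dup, species, biota)
        assert not report.ok
        assert any(v.rule == "duplicate key" for v in report.violations)

    def test_orphan_biota_row_flagged(self, tiny_tables):
        samples, species, biota = tiny_tables
        biota = pd.concat(
            [biota, pd.DataFrame([{"sample_id": "ghost", "sibes_id": 1, "abundance_m2": 5.0, "afdm_m2": 0.1}])],
            ignore_index=True,
        )
        report = validate(samples, species, biota)
        assert sum(v.rule == "referential" for v in report.violations) == 1

    def test_mud_percentage_range_flagged(self, tiny_tables):
        samples, species, biota = tiny_tables
        samples.loc[0, "percentage_mud"] = 101.0
        report = validate(samples, species, biota)
        assert any("percentage_mud" in v.detail for v in report.violations)

    def test_unknown_platform_flagged(self, tiny_tables):
        samples, species, biota = tiny_tables
        samples.loc[1, "platform"] = "hovercraft"
        assert not validate(samples, species, biota).ok

    def test_stored_zero_abundance_flagged(self, tiny_tables):
        samples, species, biota = tiny_tables
        biota.loc[0, "abundance_m2"] = 0.0
        report = validate(samples, species, biota)
        assert any("absences" in v.detail for v in report.violations)

    def test_report_serializes_to_json_lines(self, tiny_tables):
        samples, species, biota = tiny_tables
        samples.loc[0, "percentage_mud"] = -3.0
        report = validate(samples, species, biota)
        assert report.exit_status == 1
        lines = report.to_json_lines().splitlines()
        assert len(lines) == len(report.violations)


class TestZeroFill:
    def test_dense_row_count_and_zero_count(self, tiny_tables):
        dense = zero_fill(*tiny_tables)
        assert len(dense) == 3 * 2
        assert int((dense["abundance_m2"] == 0).sum()) == 4

    def test_total_abundance_conserved(self, tiny_tables):
        samples, species, biota = tiny_tables
        dense = zero_fill(samples, species, biota)
        assert dense["abundance_m2"].sum() == pytest.approx(biota["abundance_m2"].sum())

    def test_empty_biota_gives_all_zeros(self, tiny_tables):
        samples, species, biota = tiny_tables
        dense = zero_fill(samples, species, biota.iloc[0:0])
        assert (dense["abundance_m2"] == 0).all() and len(dense) == 6

    def test_unknown_taxa_rejected(self, tiny_tables):
        with pytest.raises(KeyError):
            zero_fill(*tiny_tables, taxa=[99])


class TestRoundTrip:
    def test_write_read_value_identical(self, tiny_tables, tmp_path):
        for name, df in zip(("samples", "species", "biota"), tiny_tables):
            p = tmp_path / f"{name}.csv"
            write_table(df, p)
            back = read_table(p)
            pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_missing_values_written_as_empty_fields(self, tiny_tables, tmp_path):
        samples = tiny_tables[0]
        p = tmp_path / "samples.csv"
        write_table(samples, p)
        row = p.read_text().splitlines()[2]  # s2 has a missing grain size
        assert ",," in row


class TestCampaignSummary:
    def test_reference_table_averages_row(self):
        s = summarize_campaign(reference_campaign_table(), averages_range=(2008, 2019))
        assert s.averages["total"] == 4109
        assert s.averages["grid"] == 3565
        assert s.averages["random"] == 544

    def test_reference_table_min_max_totals(self):
        s = summarize_campaign(reference_campaign_table())
        assert (s.min_total, s.max_total) == (2399, 4471)

    def test_every_printed_percent_random_cell_reproduced(self):
        ref = reference_campaign_table()
        s = summarize_campaign(ref)
        assert s.per_year["pct_random"].tolist() == ref["pct_random"].astype(float).tolist()

    def test_exclude_years_convention(self):
        # the alternative reading: all years except the disrupted one
        s = summarize_campaign(
            reference_campaign_table(), averages_range=None, exclude_years=(2020,)
        )
        assert s.averages["total"] == round_half_up(
            reference_campaign_table().query("year != 2020")["total"].mean()
        )

    def test_single_year_averages_equal_that_year(self):
        one = reference_campaign_table().iloc[[0]]
        s = summarize_campaign(one, averages_range=None)
        assert s.averages["total"] == one["total"].iloc[0]

    def test_empty_input_gives_empty_summary(self):
        s = summarize_campaign(pd.DataFrame(columns=["year", "total", "grid", "random"]))
        assert isinstance(s, CampaignSummary) and s.per_year.empty

    def test_per_year_from_samples(self, tiny_tables):
        per_year = per_year_from_samples(tiny_tables[0])
        assert per_year.loc[0, "total"] == 3
        assert per_year.loc[0, "random"] == 1
        assert per_year.loc[0, "pct_random"] == round_half_up(100 / 3)
        assert per_year.loc[0, "pct_boating"] == round_half_up(200 / 3)


class TestCommunitySummary:
    def test_richness_and_biomass_per_station(self, tiny_tables):
        dense = zero_fill(*tiny_tables)
        per_sample, _, _ = summarize_community(dense, tiny_tables[0])
        by_id = per_sample.set_index("sample_id")
        assert by_id.loc["s1", "richness"] == 1
        assert by_id.loc["s2", "richness"] == 0
        assert by_id.loc["s2", "total_afdm_m2"] == 0.0

    def test_sparse_input_rejected(self, tiny_tables):
        samples, species, biota = tiny_tables
        with pytest.raises(SchemaError):
            summarize_community(biota, samples)

    def test_yearly_species_mean_matches_generator(self, small_world, small_tables):
        """Observed mean density within 3 SE of the latent field's spatial mean."""
        samples, species, biota = small_tables
        dense = zero_fill(samples, species, biota)
        _, yearly, _ = summarize_community(dense, samples)
        for sp in small_world.config.species_params:
            row = yearly[yearly["sibes_id"] == sp.sibes_id]
            obs = float(row["mean_abundance_m2"].iloc[0])
            truth = float(small_world.density[sp.sibes_id].data.mean())
            per_sample = dense[dense["sibes_id"] == sp.sibes_id]["abundance_m2"]
            se = per_sample.std(ddof=1) / np.sqrt(len(per_sample))
            assert abs(obs - truth) < 3 * se


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(0.5, 0, 1.0), (1.5, 0, 2.0), (2.5, 0, 3.0), (0.949, 1, 0.9), (0.95, 1, 1.0)],
    )
    def test_half_up_not_bankers(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected
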