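import io

import numpy as np
import pandas as pd
import pytest

import pyroseasons as ps
from pyroseasons.fire_analysis import FireRecordError, round_half_away


class TestPackagedTables:
    def test_top_fires_table_has_twenty_records(self):
        df = ps.load_top_fires()
        assert len(df) == 20
        assert set(df["source"]) == {"lightning", "military"}

    def test_totals_table_covers_all_source_season_cells(self):
        df = ps.load_season_source_totals()
        assert len(df) == 9
        assert df["n_fires"].sum() == 59 + 112 + 664


class TestReadFireRecords:
    def _read(self, text):
        return ps.read_fire_records(io.StringIO(text))

    def test_valid_records_parse(self):
        df = self._read("date,area_ha,source\n2001-05-01,12.5,lightning\n")
        assert df.loc[0, "area_ha"] == 12.5

    @pytest.mark.parametrize("row, match", [
        ("2001-05-01,12.5,arson", "unknown ignition source"),
        ("2001-05-01,-1,lightning", "must be > 0"),
        ("2001-05-01,0,lightning", "must be > 0"),
        ("bad-date,5,military", "bad date"),
    ])
    def test_invalid_rows_rejected_with_row_number(self, row, match):
        with pytest.raises(FireRecordError, match=match):
            self._read(f"date,area_ha,source\n{row}\n")


class TestAttachSeason:
    @pytest.fixture
    def labeled_days(self):
        dates = pd.date_range("2000-01-01", periods=10, freq="D")
        labels = pd.Series([1] * 5 + [2] * 5, index=dates)
        roles = {1: "dry", 2: "fire"}
        return dates, labels, roles

    def test_join_carries_cluster_role_and_weather(self, labeled_days):
        dates, labels, roles = labeled_days
        frame = pd.DataFrame(
            {"temp": np.arange(10.0), "rh": np.arange(10.0) + 50},
            index=dates,
        )
        fires = pd.DataFrame({
            "date": [dates[1], dates[7]],
            "area_ha": [5.0, 7.0],
            "source": ["lightning", "military"],
        })
        joined = ps.attach_season(fires, labels, roles,
                                  series=ps.WeatherSeries(frame))
        assert list(joined["season"]) == ["dry", "fire"]
        assert joined.loc[1, "temp"] == frame.iloc[7]["temp"]

    def test_fire_outside_weather_range_rejected(self, labeled_days):
        _, labels, roles = labeled_days
        fires = pd.DataFrame({
            "date": [pd.Timestamp("1999-12-31")],
            "area_ha": [5.0], "source": ["lightning"],
        })
        with pytest.raises(FireRecordError, match="1999-12-31"):
            ps.attach_season(fires, labels, roles)

    def test_unassigned_day_warns_and_gets_role_none(self, labeled_days):
        dates, labels, roles = labeled_days
        labels.iloc[3] = 0
        fires = pd.DataFrame({
            "date": [dates[3]], "area_ha": [5.0], "source": ["prescribed"],
        })
        with pytest.warns(UserWarning, match="unassigned"):
            joined = ps.attach_season(fires, labels, roles)
        assert joined.loc[0, "season"] == "none"


class TestShares:
    def test_rounding_is_half_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away([45.5, 44.5, -0.5, 2.4]), [46, 45, -1, 2]
        )

    def test_printed_share_reproduction_from_aggregates(self):
        shares = ps.shares_from_totals(ps.load_season_source_totals())
        idx = shares.set_index(["source", "season"])
        assert idx.loc[("lightning", "fire"), "count_share_pct"] == 73
        assert idx.loc[("lightning", "fire"), "area_share_pct"] == 90
        assert idx.loc[("military", "fire"), "count_share_pct"] == 46
        assert idx.loc[("military", "fire"), "area_share_pct"] == 61
        assert idx.loc[("military", "wet"), "count_share_pct"] == 15
        assert idx.loc[("prescribed", "dry"), "count_share_pct"] == 51
        assert idx.loc[("prescribed", "dry"), "area_share_pct"] == 55

    def test_single_fire_takes_full_share(self):
        fires = pd.DataFrame({
            "date": [pd.Timestamp("2000-06-01")],
            "area_ha": [3.0], "source": ["lightning"], "season": ["fire"],
        })
        out = ps.season_source_summary(fires)
        assert out.loc[0, "count_share_pct"] == 100

    def test_summary_totals_are_exact(self, rng):
        n = 60
        fires = pd.DataFrame({
            "date": pd.date_range("2000-01-01", periods=n, freq="3D"),
            "area_ha": rng.lognormal(2, 1, n),
            "source": rng.choice(["lightning", "military"], n),
            "season": rng.choice(["wet", "dry", "fire"], n),
        })
        out = ps.season_source_summary(fires)
        for source, sub in fires.groupby("source"):
            rows = out[out["source"] == source]
            assert rows["n_fires"].sum() == len(sub)
            assert rows["total_area_ha"].sum() == pytest.approx(
                sub["area_ha"].sum()
            )
            assert abs(rows["count_share_pct"].sum() - 100) <= 1
            assert abs(rows["area_share_pct"].sum() - 100) <= 1


class TestTopN:
    def test_printed_lightning_ranking(self):
        top3 = ps.top_n_fires(ps.load_top_fires(), "lightning", 3)
        assert list(top3["area_ha"]) == [1914, 1652, 549]

    def test_printed_military_largest(self):
        top1 = ps.top_n_fires(ps.load_top_fires(), "military", 1)
        assert top1.loc[0, "area_ha"] == 2128
        assert top1.loc[0, "date"] == pd.Timestamp("2006-05-04")

    def test_ties_broken_by_earlier_date(self):
        fires = pd.DataFrame({
            "date": pd.to_datetime(["2001-06-01", "2000-06-01"]),
            "area_ha": [5.0, 5.0], "source": ["lightning"] * 2,
        })
        top = ps.top_n_fires(fires, "lightning", 2)
        assert top.loc[0, "date"] == pd.Timestamp("2000-06-01")

    def test_requesting_more_than_available_warns(self):
        fires = ps.load_top_fires()
        with pytest.warns(UserWarning, match="available"):
            out = ps.top_n_fires(fires, "lightning", 99)
        assert len(out) == 10

    def test_empty_source_yields_empty_table(self):
        with pytest.warns(UserWarning):
            out = ps.top_n_fires(ps.load_top_fires(), "prescribed", 3)
        assert out.empty


class TestPeakModeOverlay:
    def test_cluster_seven_holds_five_of_top_ten_lightning_fires(self):
        overlay = ps.peak_mode_overlay(ps.load_top_fires())
        row = overlay[(overlay["source"] == "lightning")
                      & (overlay["cluster"] == 7)]
        assert int(row["n_fires"].iloc[0]) == 5
        assert bool(row["peak_mode"].iloc[0])

    def test_printed_aggregate_area_share_is_69_pct(self):
        agg = ps.load_lightning_cluster_areas().assign(
            source="lightning",
            date=pd.Timestamp("2000-01-01"),
        )
        overlay = ps.peak_mode_overlay(agg)
        share = overlay.set_index("cluster").loc["7", "area_share_pct"]
        assert round_half_away(share) == 69

    def test_no_lightning_fires_warns(self):
        fires = pd.DataFrame({
            "date": [pd.Timestamp("2000-01-01")], "area_ha": [5.0],
            "source": ["military"], "cluster": [2],
        })
        with pytest.warns(UserWarning, match="peak mode undefined"):
            overlay = ps.peak_mode_overlay(fires)
        assert not overlay["peak_mode"].any()


class TestBubbleExport:
    def _joined(self):
        return pd.DataFrame({
            "f1": [0.0, 1.0], "f2": [0.5, -0.5],
            "area_ha": [4.0, 1.0],
            "source": ["lightning", "military"],
            "season": ["fire", "dry"],
        })

    def test_radius_scales_with_sqrt_area(self):
        out = ps.bubble_plot_export(self._joined())
        assert out.loc[0, "radius"] / out.loc[1, "radius"] == pytest.approx(2.0)

    def test_tiny_fire_gets_floor_radius(self):
        df = self._joined()
        df.loc[0, "area_ha"] = 1e-4
        out = ps.bubble_plot_export(df)
        assert out.loc[0, "radius"] == 0.05

    def test_row_count_preserved(self):
        assert len(ps.bubble_plot_export(self._joined())) == 2
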