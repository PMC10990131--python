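"""CVG construction, the 40 degC scenario filter, backcast/forecast
identities, and the single-variable response sweep."""

import numpy as np
import pandas as pd
import pytest

from ricegxw import (
    backcast_forecast,
    classify_cvgs,
    response_sweep,
    scenario_filter,
    sliding_window_cvgs,
)
from ricegxw.config import WEATHER_VARS
from ricegxw.forecast import ForecastResult, forecast_results_frame, trait_frequency_table


class TestSlidingWindows:
    def test_window_count(self, tiny_system):
        g = tiny_system["observed"]  # 25 - drops at 10% -> check against actual
        n = len(g.variety_ids)
        cvgs = sliding_window_cvgs(g, window=20, step=1)
        assert len(cvgs) == n - 20 + 1
        assert all(len(c.members) == 20 for c in cvgs)

    def test_exact_window_single_cvg(self, tiny_system):
        g = tiny_system["observed"]
        n = len(g.variety_ids)
        cvgs = sliding_window_cvgs(g, window=n, step=1)
        assert len(cvgs) == 1 and set(cvgs[0].members) == set(g.variety_ids)

    def test_first_window_is_earliest_released(self, tiny_system):
        g = tiny_system["observed"]
        cvgs = sliding_window_cvgs(g, window=5, step=1)
        by_release = g.meta.assign(_id=g.meta.index).sort_values(
            ["release_year", "_id"], kind="stable"
        )
        assert cvgs[0].members == by_release.index[:5].to_list()
        assert cvgs[0].metadata["release_min"] == by_release["release_year"].iloc[0]

    def test_too_few_varieties_raise(self, tiny_system):
        with pytest.raises(ValueError, match="at least"):
            sliding_window_cvgs(tiny_system["observed"], window=10_000)


class TestClassification:
    def test_membership_matches_metadata_filter(self, tiny_system):
        g = tiny_system["observed"]
        for scheme, column in [("semidwarf", "sd1"), ("ca_ancestry", "ca_ancestry")]:
            groups = {c.name: set(c.members) for c in classify_cvgs(g, scheme)}
            positive, negative = groups.keys()
            assert groups[positive] == set(g.meta.index[g.meta[column]])
            assert groups[negative] == set(g.meta.index[~g.meta[column]])

    def test_program_partition_sums_to_total(self, tiny_system):
        g = tiny_system["observed"]
        groups = classify_cvgs(g, "program")
        assert sum(len(c.members) for c in groups) == len(g.variety_ids)

    def test_all_flagged_gives_empty_complement(self, tiny_system):
        g = tiny_system["observed"]
        forced = g.meta.copy()
        forced["sd1"] = True
        from ricegxw.alleles import GenotypeMatrix

        g_all = GenotypeMatrix(calls=g.calls, meta=forced)
        groups = {c.name: c.members for c in classify_cvgs(g_all, "semidwarf")}
        assert len(groups["sd"]) == len(g.variety_ids) and groups["wild"] == []

    def test_unknown_scheme_rejected(self, tiny_system):
        with pytest.raises(ValueError, match="scheme"):
            classify_cvgs(tiny_system["observed"], "height")


class TestScenarioFilter:
    def _table(self, tmaxes):
        return pd.DataFrame(
            {
                "county": "C1",
                "year": range(2016, 2016 + len(tmaxes)),
                "april_tavg": 18.0,
                "april_prcp": 100.0,
                "july_tmax": tmaxes,
                "july_prcp": 100.0,
            }
        )

    def test_boundary_inclusive_above_strictly_dropped(self):
        kept, report = scenario_filter(self._table([39.0, 40.0, 40.0001, 41.0]))
        assert kept["july_tmax"].to_list() == [39.0, 40.0]
        assert report["n_dropped"] == 2

    def test_drop_fraction(self):
        kept, report = scenario_filter(self._table([41.0] * 3 + [35.0] * 7))
        assert len(kept) == 7 and report["drop_fraction"] == pytest.approx(0.3)

    def test_no_exceedance_identity(self):
        table = self._table([33.0, 34.0])
        kept, report = scenario_filter(table)
        pd.testing.assert_frame_equal(kept, table)
        assert report["n_dropped"] == 0

    def test_lower_limit_never_keeps_more_rows(self):
        table = self._table(list(np.linspace(30, 45, 40)))
        kept_counts = [
            scenario_filter(table, tmax_limit=t)[1]["n_kept"] for t in np.arange(30, 46)
        ]
        assert all(a <= b for a, b in zip(kept_counts, kept_counts[1:]))


class TestBackcastForecast:
    def test_relative_change_identity(self):
        r = ForecastResult("x", backcast_mean=6000.0, forecast_mean=6120.0,
                           n_backcast=10, n_forecast=10)
        assert r.relative_change == pytest.approx(2.0)

    def test_future_equal_to_history_gives_zero_change(
        self, tiny_system, linear_stub_factory
    ):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvg = sliding_window_cvgs(g, window=5)[0]
        stub = linear_stub_factory(columns=[], coefs={"july_tmax": -50.0})
        res = backcast_forecast(stub, cvg, g, wx, wx.copy())
        assert res.relative_change == pytest.approx(0.0)
        assert res.valid

    def test_empty_future_flagged_invalid(self, tiny_system, linear_stub_factory):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvg = sliding_window_cvgs(g, window=5)[0]
        stub = linear_stub_factory(columns=[])
        res = backcast_forecast(stub, cvg, g, wx, wx.iloc[:0], {"n_dropped": 99})
        assert not res.valid and np.isnan(res.relative_change)
        assert res.n_rows_dropped == 99

    def test_results_frame_columns(self, tiny_system, linear_stub_factory):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvgs = sliding_window_cvgs(g, window=5)[:3]
        stub = linear_stub_factory(columns=[], coefs={"july_tmax": -10.0})
        frame = forecast_results_frame(
            [backcast_forecast(stub, c, g, wx, wx) for c in cvgs]
        )
        assert {"cvg", "relative_change_pct", "rows_kept", "rows_dropped"} <= set(frame)
        assert len(frame) == 3


def test_trait_frequency_table_fractions(tiny_system):
    g = tiny_system["observed"]
    cvgs = sliding_window_cvgs(g, window=5)
    table = trait_frequency_table(cvgs, g)
    assert table["sd1"].between(0, 1).all()
    assert table["ca_ancestry"].between(0, 1).all()
    # modern windows should be at least as semidwarf-rich as the oldest
    assert table["sd1"].iloc[-1] >= table["sd1"].iloc[0]


class TestResponseSweep:
    def test_curve_length_and_extrapolation_flags(self, tiny_system, linear_stub_factory):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvg = sliding_window_cvgs(g, window=5)[0]
        stub = linear_stub_factory(columns=[], coefs={"july_tmax": -80.0})
        lo = wx["july_tmax"].min()
        grid = [lo - 5.0, lo + 0.1, wx["july_tmax"].max() + 3.0]
        curve = response_sweep(stub, cvg, g, "july_tmax", grid, wx)
        assert len(curve) == 3
        assert curve["extrapolated"].to_list() == [True, False, True]

    def test_negative_linear_truth_gives_monotone_decreasing_curve(
        self, tiny_system, linear_stub_factory
    ):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvg = sliding_window_cvgs(g, window=5)[0]
        stub = linear_stub_factory(columns=[], coefs={"july_tmax": -80.0})
        curve = response_sweep(stub, cvg, g, "july_tmax", np.linspace(31, 38, 8), wx)
        assert (np.diff(curve["predicted_mean"]) < 0).all()

    def test_single_point_at_means_equals_direct_prediction(
        self, tiny_system, linear_stub_factory
    ):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvg = sliding_window_cvgs(g, window=5)[0]
        stub = linear_stub_factory(columns=[], coefs={"july_tmax": -80.0})
        mean_tmax = wx.groupby("county")["july_tmax"].mean().mean()
        curve = response_sweep(stub, cvg, g, "july_tmax", [mean_tmax], wx)
        # linear stub: mean over counties at county means == prediction at grand mean
        expected = 6000.0 - 80.0 * mean_tmax
        assert curve["predicted_mean"].iloc[0] == pytest.approx(expected)

    def test_validation(self, tiny_system, linear_stub_factory):
        g = tiny_system["observed"]
        wx = tiny_system["weather"]
        cvg = sliding_window_cvgs(g, window=5)[0]
        stub = linear_stub_factory(columns=[])
        with pytest.raises(ValueError, match="weather variable"):
            response_sweep(stub, cvg, g, "august_tmax", [1.0], wx)
        with pytest.raises(ValueError, match="empty"):
            response_sweep(stub, cvg, g, "july_tmax", [], wx)
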