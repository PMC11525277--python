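"""Yield standardization, correlation selection and confusion-matrix metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import regcdi
from regcdi.core import classify
from regcdi.grid import GridError
from regcdi.validation import (ConfusionMatrix, accuracy, binarize_classes,
                               binarize_threshold, binarize_z, confusion,
                               confusion_multiclass, early_warning, mcc,
                               pearson_correlation, seasonal_severity,
                               select_indicators, standardize_yield)

from conftest import make_series


def table_of(**districts):
    rows = [{"district": d, "year": 2000 + i, "yield": v}
            for d, vals in districts.items() for i, v in enumerate(vals)]
    df = pd.DataFrame(rows)
    df["district"] = df["district"].astype(str).str.replace("d", "").astype(int)
    return regcdi.YieldTable(df)


class TestStandardizeYield:
    def test_hand_values_sample_sigma(self):
        out = standardize_yield(table_of(d1=[2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out.data["z"].values, [-1.0, 0.0, 1.0])

    def test_population_sigma_option(self):
        out = standardize_yield(table_of(d1=[2.0, 4.0, 6.0]), ddof=0)
        np.testing.assert_allclose(out.data["z"].values,
                                   np.array([-2.0, 0.0, 2.0]) / np.sqrt(8 / 3))

    def test_z_has_zero_mean_per_district(self):
        rng = np.random.default_rng(4)
        out = standardize_yield(table_of(d1=list(rng.uniform(1, 3, 8)),
                                         d2=list(rng.uniform(2, 5, 8))))
        for _, sub in out.data.groupby("district"):
            assert sub["z"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            out = standardize_yield(table_of(d1=[2.0, 2.0, 2.0]))
        assert out.data["z"].isna().all()
        assert any("variance" in r.message for r in caplog.records)

    def test_too_few_years_flagged(self):
        out = standardize_yield(table_of(d1=[2.0, 3.0]))
        assert out.data["z"].isna().all()


class TestSeasonalSeverity:
    def test_constant_season(self):
        vals = np.full(24, 0.4)
        sev = seasonal_severity(make_series(vals), regcdi.KHARIF)
        np.testing.assert_allclose(sev.values[:, 0, 0], 0.4)

    def test_season_min_is_worst_month(self):
        vals = np.full(12, 0.9)
        vals[5:9] = [0.5, 0.2, 0.6, 0.3]  # Jun..Sep
        sev = seasonal_severity(make_series(vals), regcdi.KHARIF)
        assert sev.values[0, 0, 0] == pytest.approx(0.2)

    def test_critical_month_mode(self):
        vals = np.arange(12.0) / 12
        sev = seasonal_severity(make_series(vals), regcdi.KHARIF,
                                mode="critical-month", critical_month=8)
        assert sev.values[0, 0, 0] == pytest.approx(7 / 12)  # August value

    def test_critical_month_must_be_in_season(self):
        with pytest.raises(GridError):
            seasonal_severity(make_series(np.zeros(12)), regcdi.KHARIF,
                              mode="critical-month", critical_month=12)


class TestPearson:
    def test_perfect_and_inverse(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(a, a) == pytest.approx(1.0)
        assert pearson_correlation(a, -a) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_correlation([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_degenerate_inputs(self):
        with pytest.raises(GridError):
            pearson_correlation([1, 2], [3, 4])
        with pytest.raises(GridError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCorrelationMap:
    def test_severity_equal_to_z_gives_unit_correlation(self):
        zones = regcdi.ZoneMap(labels=np.ones((2, 2), dtype=int))
        table = standardize_yield(table_of(d1=[2.0, 4.0, 6.0, 3.0]))
        z = table.data["z"].values
        sev = regcdi.validation.SeasonalSeverity(
            values=np.repeat(z[:, None, None], 4, axis=1).reshape(4, 2, 2),
            years=table.data["year"].values, season="kharif", mode="season-min")
        pcc = regcdi.correlation_map(sev, table, zones, target="z")
        np.testing.assert_allclose(pcc, 1.0)

    def test_short_district_masked(self):
        zones = regcdi.ZoneMap(labels=np.ones((1, 1), dtype=int))
        table = standardize_yield(table_of(d1=[2.0, 4.0]))
        sev = regcdi.validation.SeasonalSeverity(
            values=np.zeros((2, 1, 1)), years=np.array([2000, 2001]),
            season="kharif", mode="season-min")
        pcc = regcdi.correlation_map(sev, table, zones, target="yield")
        assert np.isnan(pcc).all()

    def test_synthetic_coupling_recovers_positive_mean(self, scene, index_result):
        """Yield was generated to drop with Kharif drought stress, so the
        district-yield vs seasonal-minimum-index correlation is positive."""
        table = standardize_yield(scene.yields)
        sev = seasonal_severity(index_result.index, regcdi.KHARIF)
        pcc = regcdi.correlation_map(sev, table, scene.zones, target="z")
        assert np.nanmean(pcc) > 0.05


class TestSelectIndicators:
    # region-mean correlations with (yield, standardized yield) in the
    # style of a published indicator-screening table
    SUMMARIES = {
        "VCI": (0.01, 0.02), "TCI": (0.49, 0.54), "NDWI": (0.20, 0.20),
        "SMCI": (0.33, 0.30), "SMDI": (0.13, 0.08), "SWDI": (0.21, 0.19),
        "SIWSI-1": (0.15, 0.15), "SIWSI-2": (0.02, 0.02),
    }
    TYPES = {
        "VCI": "vegetation", "TCI": "vegetation", "NDWI": "vegetation",
        "SMCI": "soil moisture", "SMDI": "soil moisture", "SWDI": "soil moisture",
        "SIWSI-1": "crop stress", "SIWSI-2": "crop stress",
    }

    def test_recovers_leading_triple(self):
        chosen = select_indicators(self.SUMMARIES, self.TYPES)
        assert chosen == {"vegetation": "TCI", "soil moisture": "SMCI",
                          "crop stress": "SIWSI-1"}

    def test_tie_breaks_lexicographically(self, caplog):
        with caplog.at_level("WARNING"):
            chosen = select_indicators({"A": (0.3, 0.3), "B": (0.3, 0.3)},
                                       {"A": "t", "B": "t"})
        assert chosen == {"t": "A"}
        assert any("tie" in r.message for r in caplog.records)

    def test_missing_type_rejected(self):
        with pytest.raises(GridError):
            select_indicators({"A": (0.3, 0.3)}, {})


class TestBinarize:
    def test_z_negative_rule(self):
        np.testing.assert_array_equal(binarize_z([-0.5, 0.2]), [True, False])

    def test_threshold_is_strict(self):
        assert not binarize_threshold(np.array([0.12]), 0.12)[0]
        assert binarize_threshold(np.array([0.119]), 0.12)[0]

    def test_d0_is_non_drought(self):
        cls = classify(regcdi.CombinedIndexSeries(series=make_series([0.25])))
        assert not binarize_classes(cls)[0, 0, 0]


class TestConfusionMetrics:
    def test_identical_series(self):
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        cm = confusion(a, a)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (4, 6, 0, 0)
        assert accuracy(cm) == 100.0
        assert mcc(cm) == pytest.approx(1.0)

    def test_complement_series(self):
        a = np.array([1, 0, 1, 0], dtype=bool)
        cm = confusion(a, ~a)
        assert cm.tp == 0 and cm.tn == 0
        assert mcc(cm) == pytest.approx(-1.0)

    def test_hand_tallied_mixed_case(self):
        actual = np.array([1, 1, 1, 0, 0, 0, 1, 0], dtype=bool)
        predicted = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
        cm = confusion(actual, predicted)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 3, 1, 1)

    @pytest.mark.parametrize("counts,expected", [
        ((3, 5, 1, 1), 80.0),        # (tp, tn, fp, fn)
        ((2, 2, 2, 2), 50.0),
    ])
    def test_accuracy_values(self, counts, expected):
        tp, tn, fp, fn = counts
        cm = ConfusionMatrix.from_counts(tp=tp, tn=tn, fp=fp, fn=fn)
        assert accuracy(cm) == pytest.approx(expected)

    def test_mcc_hand_value(self):
        cm = ConfusionMatrix.from_counts(tp=6, tn=3, fp=1, fn=2)
        assert mcc(cm) == pytest.approx(16 / np.sqrt(7 * 8 * 4 * 5))
        assert mcc(cm) == pytest.approx(0.48, abs=0.01)

    def test_balanced_is_zero(self):
        cm = ConfusionMatrix.from_counts(tp=5, tn=5, fp=5, fn=5)
        assert mcc(cm) == 0.0

    def test_zero_denominator_convention(self, caplog):
        cm = ConfusionMatrix.from_counts(tp=0, tn=5, fp=0, fn=3)
        with caplog.at_level("WARNING"):
            assert mcc(cm) == 0.0
        assert any("denominator" in r.message for r in caplog.records)

    def test_accuracy_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(0)
        a = rng.random(200) < 0.4
        p = rng.random(200) < 0.4
        assert accuracy(confusion(a, p)) == accuracy(confusion(~a, ~p))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_mcc_equals_binary_pearson(self, seed):
        """Oracle: MCC is the Pearson correlation of the 0/1 vectors."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        a = rng.random(n) < rng.uniform(0.2, 0.8)
        p = rng.random(n) < rng.uniform(0.2, 0.8)
        cm = confusion(a, p)
        if min(a.sum(), (~a).sum(), p.sum(), (~p).sum()) == 0:
            assert mcc(cm) == 0.0
        else:
            oracle = np.corrcoef(a.astype(float), p.astype(float))[0, 1]
            assert mcc(cm) == pytest.approx(oracle, abs=1e-12)

    def test_multiclass_accuracy_below_merged_binary(self):
        """Coarsening classes can only convert errors into agreements."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            actual = rng.integers(0, 6, 300)
            predicted = rng.integers(0, 6, 300)
            multi = accuracy(confusion_multiclass(actual, predicted))
            binary = accuracy(confusion(actual >= 2, predicted >= 2))
            assert multi <= binary + 1e-12


class TestEarlyWarning:
    def test_perfect_lead(self):
        rng = np.random.default_rng(21)
        vals = rng.uniform(0, 0.4, size=(40, 2, 2))
        idx = regcdi.CombinedIndexSeries(series=make_series(vals))
        lag = 2
        shifted = np.empty_like(vals)
        shifted[:-lag] = vals[lag:]   # predictor knows the future exactly
        shifted[-lag:] = 0.5
        predictor = make_series(shifted, variable="oracle")
        res = early_warning(idx, predictor, lag, threshold=0.12,
                            predictor_rule="threshold")
        assert res["accuracy"] == 100.0
        assert res["mcc"] == pytest.approx(1.0)

    def test_independent_predictor_has_no_skill(self):
        rng = np.random.default_rng(22)
        n = 10_000
        vals = rng.uniform(0, 0.24, size=(n, 1, 1))  # balanced around 0.12
        pred = rng.uniform(0, 0.24, size=(n, 1, 1))
        idx = regcdi.CombinedIndexSeries(series=make_series(vals))
        res = early_warning(idx, make_series(pred, variable="noise"), 1,
                            threshold=0.12, predictor_rule="threshold")
        assert abs(res["mcc"]) < 0.05

    def test_lead_lag_structure_recovered(self, scene, index_result):
        """Soil moisture deficit precedes the index response by one month,
        so lag-1 skill must beat lag-3 skill."""
        a1 = early_warning(index_result.index, scene.ssm, 1, threshold=0.12)
        a3 = early_warning(index_result.index, scene.ssm, 3, threshold=0.12)
        assert a1["accuracy"] > a3["accuracy"]

    def test_lag_bounds(self):
        idx = regcdi.CombinedIndexSeries(series=make_series(np.zeros(5)))
        with pytest.raises(GridError):
            early_warning(idx, make_series(np.zeros(5)), 5)
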