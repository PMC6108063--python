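import numpy as np
import pandas as pd
import pytest

from lvikit.aggregate import AESIndicatorTable
from lvikit.engine import (
    DEFAULT_THRESHOLDS,
    area_share_by_class,
    classify_vulnerability,
    composite_lvi,
    contributing_factors,
    evaluate,
    lvi_ipcc,
    profile_scores,
    standardize,
)
from lvikit.framework import load_framework

UNITS = ["U1", "U2", "U3", "U4", "U5"]


def _table(values: pd.DataFrame) -> AESIndicatorTable:
    n = pd.Series(10, index=values.index)
    prov = pd.DataFrame("survey", index=values.index, columns=values.columns)
    return AESIndicatorTable(values=values, n=n, provenance=prov)


def _mini_fw(orientations):
    """One indicator per entry; profile 'p' (exposure), 'q' (sensitivity), 'r' (AC)."""
    return load_framework(
        {
            "profiles": [
                {"id": "p", "factor": "exposure"},
                {"id": "q", "factor": "sensitivity"},
                {"id": "r", "factor": "adaptive_capacity"},
            ],
            "indicators": [
                {
                    "id": iid,
                    "profile": prof,
                    "orientation": orient,
                    "aggregator": "mean",
                    "source_fields": ["f"],
                }
                for iid, prof, orient in orientations
            ],
        }
    )


def _random_table(rng, fw, units=UNITS):
    cols = fw.indicator_ids
    vals = pd.DataFrame(
        rng.uniform(0, 10, size=(len(units), len(cols))), index=units, columns=cols
    )
    return _table(vals)


class TestStandardize:
    def test_hand_column(self):
        fw = _mini_fw(
            [("a", "p", "factor_increasing"), ("b", "q", "factor_increasing"),
             ("c", "r", "factor_increasing")]
        )
        vals = pd.DataFrame(
            {
                "a": [0.78, 0.30, 0.30, 0.60, 0.76],
                "b": [1, 2, 3, 4, 5],
                "c": [5, 4, 3, 2, 1],
            },
            index=UNITS,
        )
        st = standardize(_table(vals), fw)
        assert st.values["a"].tolist() == pytest.approx(
            [1.0, 0.0, 0.0, 0.625, 0.9583], abs=1e-4
        )

    def test_endpoints(self):
        fw = _mini_fw(
            [("a", "p", "factor_increasing"), ("b", "q", "factor_increasing"),
             ("c", "r", "factor_increasing")]
        )
        vals = pd.DataFrame({"a": [3.0, 9.0], "b": [0.0, 1.0], "c": [1.0, 2.0]},
                            index=["U1", "U2"])
        st = standardize(_table(vals), fw)
        assert st.values.loc["U1", "a"] == 0.0
        assert st.values.loc["U2", "a"] == 1.0

    def test_decreasing_flip(self):
        fw = _mini_fw(
            [("a", "p", "factor_decreasing"), ("b", "q", "factor_increasing"),
             ("c", "r", "factor_increasing")]
        )
        vals = pd.DataFrame({"a": [0.2, 0.8], "b": [0.0, 1.0], "c": [1.0, 2.0]},
                            index=["U1", "U2"])
        st = standardize(_table(vals), fw)
        assert st.values["a"].tolist() == pytest.approx([1.0, 0.0])

    def test_constant_column_warns_to_zero(self, caplog):
        fw = _mini_fw(
            [("a", "p", "factor_increasing"), ("b", "q", "factor_increasing"),
             ("c", "r", "factor_increasing")]
        )
        vals = pd.DataFrame({"a": [2.0, 2.0], "b": [0.0, 1.0], "c": [1.0, 2.0]},
                            index=["U1", "U2"])
        with caplog.at_level("WARNING"):
            st = standardize(_table(vals), fw)
        assert (st.values["a"] == 0.0).all()
        assert "constant" in caplog.text

    def test_single_unit_errors(self):
        fw = _mini_fw([("a", "p", "factor_increasing"), ("b", "q", "factor_increasing"),
                       ("c", "r", "factor_increasing")])
        vals = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}, index=["U1"])
        with pytest.raises(ValueError, match="bounds"):
            standardize(_table(vals), fw)

    def test_range_and_attainment(self, fw, indicator_table):
        st = standardize(indicator_table, fw)
        assert ((st.values >= -1e-12) & (st.values <= 1 + 1e-12)).all().all()
        for col in st.values.columns:
            if st.values[col].nunique() > 1:
                assert st.values[col].min() == pytest.approx(0.0, abs=1e-12)
                assert st.values[col].max() == pytest.approx(1.0, abs=1e-12)


class TestProfileScores:
    def test_mean(self):
        fw = _mini_fw(
            [("a", "p", "factor_increasing"), ("b", "p", "factor_increasing"),
             ("c", "p", "factor_increasing"), ("d", "q", "factor_increasing"),
             ("e", "r", "factor_increasing")]
        )
        vals = pd.DataFrame(
            {"a": [0.2, 0.0], "b": [0.4, 0.0], "c": [0.9, 0.0],
             "d": [0.5, 0.5], "e": [0.5, 0.5]},
            index=["U1", "U2"],
        )
        st = standardize(_table(vals), fw)
        st.values = vals  # bypass min-max: feed already-standardized values
        ps = profile_scores(st, fw)
        assert ps.values.loc["U1", "p"] == pytest.approx(0.5)
        assert ps.profile_sizes["p"] == 3

    def test_single_indicator_profile(self, fw, indicator_table):
        st = standardize(indicator_table, fw)
        ps = profile_scores(st, fw)
        assert ps.values.shape == (5, 8)
        assert ((ps.values >= 0) & (ps.values <= 1)).all().all()

    def test_missing_cell_reduces_n(self):
        fw = _mini_fw(
            [("a", "p", "factor_increasing"), ("b", "p", "factor_increasing"),
             ("d", "q", "factor_increasing"), ("e", "r", "factor_increasing")]
        )
        vals = pd.DataFrame(
            {"a": [0.2, 0.4], "b": [np.nan, 0.8], "d": [0.1, 0.2], "e": [0.3, 0.4]},
            index=["U1", "U2"],
        )
        st = standardize(_table(vals), fw)
        st.values = vals
        ps = profile_scores(st, fw)
        assert ps.n_used.loc["U1", "p"] == 1
        assert ps.values.loc["U1", "p"] == pytest.approx(0.2)

    def test_all_missing_errors(self):
        fw = _mini_fw(
            [("a", "p", "factor_increasing"), ("d", "q", "factor_increasing"),
             ("e", "r", "factor_increasing")]
        )
        vals = pd.DataFrame(
            {"a": [np.nan, 0.4], "d": [0.1, 0.2], "e": [0.3, 0.4]}, index=["U1", "U2"]
        )
        st = standardize(_table(vals), fw)
        st.values = vals
        with pytest.raises(ValueError, match="U1"):
            profile_scores(st, fw)


class TestCompositeAndFactors:
    def test_two_profile_weighted_mean(self):
        fw = _mini_fw(
            [("a", "q", "factor_increasing")] * 0
            + [(f"q{i}", "q", "factor_increasing") for i in range(3)]
            + [(f"r{i}", "r", "factor_increasing") for i in range(5)]
            + [("e0", "p", "factor_increasing")]
        )
        # build profile scores directly
        st = standardize(_random_table(np.random.default_rng(0), fw), fw)
        ps = profile_scores(st, fw)
        ps.values.loc["U1", "q"] = 0.2
        ps.values.loc["U1", "r"] = 0.6
        # restrict to the two profiles of interest
        from lvikit.engine import _weighted_over

        assert _weighted_over(ps, ["q", "r"])["U1"] == pytest.approx(0.45)

    def test_constant_profiles(self, fw):
        rng = np.random.default_rng(1)
        st = standardize(_random_table(rng, fw), fw)
        ps = profile_scores(st, fw)
        ps.values.loc[:, :] = 0.7
        st_const = ps
        assert composite_lvi(st_const).tolist() == pytest.approx([0.7] * 5)

    def test_flat_mean_identity(self, fw):
        rng = np.random.default_rng(2)
        st = standardize(_random_table(rng, fw), fw)
        ps = profile_scores(st, fw)
        lvi = composite_lvi(ps)
        flat = st.values.mean(axis=1)
        assert np.allclose(lvi, flat, atol=1e-12)

    def test_exposure_equals_climate_profile(self, fw, indicator_table):
        st = standardize(indicator_table, fw)
        ps = profile_scores(st, fw)
        fs = contributing_factors(ps, fw)
        assert np.allclose(fs.exposure, ps.values["climate"], atol=1e-15)

    def test_sensitivity_weighting(self, fw):
        rng = np.random.default_rng(3)
        st = standardize(_random_table(rng, fw), fw)
        ps = profile_scores(st, fw)
        ps.values.loc["U1", "ecosystem"] = 0.4
        ps.values.loc["U1", "agriculture"] = 0.8
        fs = contributing_factors(ps, fw)
        assert fs.sensitivity["U1"] == pytest.approx((5 * 0.4 + 3 * 0.8) / 8)

    def test_factor_flat_mean_identity(self, fw):
        rng = np.random.default_rng(4)
        st = standardize(_random_table(rng, fw), fw)
        ps = profile_scores(st, fw)
        fs = contributing_factors(ps, fw)
        for factor in ("exposure", "sensitivity", "adaptive_capacity"):
            cols = [
                i.id
                for p in fw.profiles_for(factor)
                for i in fw.indicators_for(p.id)
            ]
            assert np.allclose(
                fs.values[factor], st.values[cols].mean(axis=1), atol=1e-12
            )


class TestLviIpcc:
    def test_symmetry_zero(self):
        from lvikit.engine import FactorScores

        vals = pd.DataFrame(
            {"exposure": [0.4], "sensitivity": [0.9], "adaptive_capacity": [0.4]},
            index=["U1"],
        )
        fs = FactorScores(values=vals, indicator_totals=pd.Series(dtype=int))
        assert lvi_ipcc(fs)["U1"] == 0.0

    @pytest.mark.parametrize(
        "e,a,s,expected",
        [(0.78, 0.21, 0.30, 0.171), (0.30, 0.73, 1.26, -0.5418)],
    )
    def test_published_inputs(self, e, a, s, expected):
        from lvikit.engine import FactorScores

        vals = pd.DataFrame(
            {"exposure": [e], "sensitivity": [s], "adaptive_capacity": [a]},
            index=["U1"],
        )
        fs = FactorScores(values=vals, indicator_totals=pd.Series(dtype=int))
        assert lvi_ipcc(fs)["U1"] == pytest.approx(expected, abs=1e-12)

    def test_range(self):
        from lvikit.engine import FactorScores

        rng = np.random.default_rng(5)
        vals = pd.DataFrame(
            rng.uniform(0, 1, size=(100, 3)),
            columns=["exposure", "sensitivity", "adaptive_capacity"],
        )
        fs = FactorScores(values=vals, indicator_totals=pd.Series(dtype=int))
        scores = lvi_ipcc(fs)
        assert ((scores >= -1) & (scores <= 1)).all()


class TestClassify:
    def test_published_scores(self):
        scores = pd.Series([0.72, -0.62, -0.72, 0.18, 0.71], index=UNITS)
        classes = classify_vulnerability(scores)
        assert classes.tolist() == ["high", "low", "low", "moderate", "high"]

    def test_boundary_zero_is_moderate(self):
        assert classify_vulnerability(pd.Series({"u": 0.0}))["u"] == "moderate"

    def test_all_negative(self):
        classes = classify_vulnerability(pd.Series([-0.1, -0.9]))
        assert (classes == "low").all()

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_vulnerability(pd.Series([0.0]), thresholds=(0.5, 0.5))


class TestAreaShares:
    AREAS = {
        "AES1": 7200, "AES2": 3200, "AES3": 1600,
        "AES4": 1300, "AES5": 2400, "AES6": 250,
    }

    def test_low_share(self):
        classes = {"AES2": "low", "AES3": "low"}
        shares = area_share_by_class(self.AREAS, classes)
        assert shares["low"] == pytest.approx(30.09, abs=0.01)

    def test_moderate_share(self):
        shares = area_share_by_class(self.AREAS, {"AES4": "moderate"})
        assert shares["moderate"] == pytest.approx(8.15, abs=0.01)

    def test_single_unit(self):
        assert area_share_by_class({"U": 10.0}, {"U": "high"}) == {"high": 100.0}

    def test_full_classification_sums_to_100(self):
        classes = {u: "high" for u in self.AREAS}
        shares = area_share_by_class(self.AREAS, classes)
        assert shares["high"] == pytest.approx(100.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            area_share_by_class({}, {})


class TestSystemProperties:
    def test_monotonicity_exposure_and_capacity(self, fw):
        rng = np.random.default_rng(6)
        bounds = pd.DataFrame(
            {"min": 0.0, "max": 10.0}, index=fw.indicator_ids
        )
        base = _random_table(rng, fw)
        st, ps, fs, res = evaluate(base, fw, bounds=bounds)
        exp_ind = fw.indicators_for("climate")[0]
        cap_ind = next(
            i
            for i in fw.indicators_for("wealth")
            if i.orientation.value == "factor_increasing"
        )
        for unit in UNITS:
            bumped = base.values.copy()
            bumped.loc[unit, exp_ind.id] = min(10.0, bumped.loc[unit, exp_ind.id] + 2)
            t2 = _table(bumped)
            _, _, _, res2 = evaluate(t2, fw, bounds=bounds)
            assert res2.lvi_ipcc[unit] >= res.lvi_ipcc[unit] - 1e-12

            bumped = base.values.copy()
            bumped.loc[unit, cap_ind.id] = min(10.0, bumped.loc[unit, cap_ind.id] + 2)
            _, _, _, res3 = evaluate(_table(bumped), fw, bounds=bounds)
            assert res3.lvi_ipcc[unit] <= res.lvi_ipcc[unit] + 1e-12

    def test_unit_permutation_equivariance(self, fw):
        rng = np.random.default_rng(7)
        base = _random_table(rng, fw)
        perm = ["U3", "U1", "U5", "U2", "U4"]
        permuted = _table(base.values.loc[perm])
        _, _, _, res_a = evaluate(base, fw)
        _, _, _, res_b = evaluate(permuted, fw)
        assert np.allclose(res_a.lvi_ipcc[perm], res_b.lvi_ipcc, atol=1e-14)
        assert (res_a.classes[perm].values == res_b.classes.values).all()

    def test_lvi_in_unit_interval(self, fw, indicator_table):
        _, _, _, res = evaluate(indicator_table, fw)
        assert ((res.lvi >= 0) & (res.lvi <= 1)).all()
        assert ((res.lvi_ipcc >= -1) & (res.lvi_ipcc <= 1)).all()
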