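"""Outcome classification and descriptive prevalence (crude and weighted)."""

import numpy as np
import pandas as pd
import pytest

from stuntmap.survey_core import (
    SurveyDesign,
    classify_stunting,
    crude_prevalence,
    prevalence_from_counts,
    read_child_table,
    weighted_prevalence,
)


class TestClassifyStunting:
    @pytest.mark.parametrize(
        "haz,expected",
        [(-2.01, 1), (-2.0, 0), (1.3, 0), (-5.9, 1), (0.0, 0)],
    )
    def test_threshold_is_strict(self, haz, expected):
        assert classify_stunting(haz) == expected

    def test_implausible_and_missing_are_nan(self):
        out = classify_stunting([-6.5, 7.0, np.nan, -3.0])
        assert np.isnan(out[:3]).all()
        assert out[3] == 1

    def test_flag_limit_configurable(self):
        assert classify_stunting(-6.5, flag_limit=8.0) == 1


def _table_from_counts(level_counts):
    """Expand {level: (stunted_n, not_n)} into a child table."""
    rows = []
    for lvl, (s, ns) in level_counts.items():
        rows += [{"cov": lvl, "stunted": 1}] * s + [{"cov": lvl, "stunted": 0}] * ns
    return pd.DataFrame(rows)


class TestCrudePrevalence:
    def test_reported_cross_tabulations(self):
        """Category percentages from published survey cross-tab counts."""
        table = _table_from_counts({"yes": (270, 420), "no": (4333, 7479)})
        res = crude_prevalence(table, "cov").set_index("category")
        assert res.loc["yes", "stunted_pct"] == 39.1
        assert res.loc["no", "stunted_pct"] == 36.7
        assert res.loc["yes", "stunted_pct"] + res.loc["yes", "not_stunted_pct"] == 100.0

    def test_all_stunted_is_100(self):
        table = _table_from_counts({"a": (5, 0)})
        assert crude_prevalence(table, "cov").loc[0, "stunted_pct"] == 100.0

    def test_category_counts_partition_total(self, survey):
        res = crude_prevalence(survey.children, "wealth")
        nonmiss = survey.children.dropna(subset=["wealth", "stunted"])
        assert res["stunted_n"].sum() == (nonmiss["stunted"] == 1).sum()
        assert res["n"].sum() == len(nonmiss)

    def test_unrounded_proportions_sum_to_one(self, survey):
        res = crude_prevalence(survey.children, "maternal_education")
        assert ((res["stunted_n"] + res["not_stunted_n"]) == res["n"]).all()

    def test_empty_category_flagged_not_crash(self):
        table = _table_from_counts({"a": (3, 7)})
        table["maternal_nutrition"] = "normal"
        res = crude_prevalence(table, "maternal_nutrition").set_index("category")
        assert res.loc["obese", "n"] == 0
        assert np.isnan(res.loc["obese", "stunted_pct"])

    def test_missing_covariate_column_raises(self, survey):
        with pytest.raises(KeyError):
            crude_prevalence(survey.children, "nonexistent")


def test_prevalence_from_counts_half_up_rounding():
    assert prevalence_from_counts(1233, 4003) == 23.5
    assert prevalence_from_counts(1, 3) == 25.0
    assert np.isnan(prevalence_from_counts(0, 0))


class TestWeightedPrevalence:
    def _design(self):
        return SurveyDesign(stratum="stratum", cluster="psu", weight="w")

    def test_collapses_to_crude_under_trivial_design(self):
        rng = np.random.default_rng(0)
        n = 200
        table = pd.DataFrame(
            {
                "cov": rng.choice(["a", "b"], n),
                "stunted": rng.integers(0, 2, n),
                "stratum": "s1",
                "psu": np.arange(n),
                "w": 1.0,
            }
        )
        wt = weighted_prevalence(table, self._design(), "cov").set_index("category")
        cr = crude_prevalence(table, "cov").set_index("category")
        for lvl in ("a", "b"):
            assert wt.loc[lvl, "stunted_prop"] == pytest.approx(cr.loc[lvl, "stunted_prop"], abs=1e-12)

    def test_invariant_to_weight_rescaling_by_duplication(self):
        table = pd.DataFrame(
            {
                "cov": ["a"] * 6,
                "stunted": [1, 0, 0, 1, 1, 0],
                "stratum": ["s1", "s1", "s1", "s2", "s2", "s2"],
                "psu": ["p1", "p2", "p3", "p4", "p5", "p6"],
                "w": [2.0, 1.0, 3.0, 1.5, 2.5, 1.0],
            }
        )
        doubled = pd.concat([table, table], ignore_index=True)
        doubled["w"] /= 2.0
        a = weighted_prevalence(table, self._design(), "cov")
        b = weighted_prevalence(doubled, self._design(), "cov")
        assert a.loc[0, "stunted_prop"] == pytest.approx(b.loc[0, "stunted_prop"], abs=1e-12)

    def test_hand_computed_ht_ratio_and_linearized_se(self):
        """12-record two-stratum fixture vs a directly coded oracle."""
        table = pd.DataFrame(
            {
                "cov": ["a"] * 12,
                "stunted": [1, 0, 1, 1, 0, 0, 1, 0, 0, 1, 1, 0],
                "stratum": ["s1"] * 6 + ["s2"] * 6,
                "psu": ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4", "p5", "p5", "p6", "p6"],
                "w": [1.0, 2.0, 1.5, 0.5, 2.0, 1.0, 3.0, 1.0, 2.0, 2.0, 1.0, 1.0],
            }
        )
        w = table["w"].to_numpy()
        y = table["stunted"].to_numpy(float)
        W = w.sum()
        p = float((w * y).sum() / W)
        u = w * (y - p) / W
        var = 0.0
        for s in ("s1", "s2"):
            m = table["stratum"] == s
            z = pd.Series(u[m.to_numpy()]).groupby(table.loc[m, "psu"].to_numpy()).sum()
            var += len(z) / (len(z) - 1) * ((z - z.mean()) ** 2).sum()
        res = weighted_prevalence(table, self._design(), "cov")
        assert res.loc[0, "stunted_prop"] == pytest.approx(p, abs=1e-14)
        assert res.loc[0, "se_pct"] == pytest.approx(100 * np.sqrt(var), abs=1e-10)

    def test_single_psu_stratum_warns_and_contributes_zero(self):
        table = pd.DataFrame(
            {
                "cov": ["a"] * 4,
                "stunted": [1, 0, 1, 0],
                "stratum": ["s1", "s1", "s2", "s2"],
                "psu": ["p1", "p2", "p3", "p3"],
                "w": 1.0,
            }
        )
        with pytest.warns(UserWarning, match="single PSU"):
            res = weighted_prevalence(table, self._design(), "cov")
        assert np.isfinite(res.loc[0, "se_pct"])

    def test_nonpositive_weight_rejected(self):
        table = pd.DataFrame(
            {"cov": ["a"], "stunted": [1], "stratum": ["s"], "psu": ["p"], "w": [0.0]}
        )
        with pytest.raises(ValueError):
            weighted_prevalence(table, self._design(), "cov")


class TestReadChildTable:
    def test_roundtrip_from_generator(self, survey, tmp_path):
        path = tmp_path / "children.csv"
        survey.children.drop(columns=["true_p"]).to_csv(path, index=False)
        back = read_child_table(path)
        assert len(back) == len(survey.children)
        assert (back["stunted"] == survey.children["stunted"].to_numpy()).all()

    def test_stunted_derived_from_haz(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {"child_id": ["k1", "k2"], "cluster_id": ["c1", "c1"], "weight": [1.0, 1.0], "haz": [-2.5, 0.0]}
        ).to_csv(path, index=False)
        back = read_child_table(path)
        assert back["stunted"].tolist() == [1, 0]

    def test_bad_weight_rejected_with_row(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {"child_id": ["k1"], "cluster_id": ["c1"], "weight": [-1.0], "haz": [0.0]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="rows"):
            read_child_table(path)

    def test_unknown_category_label_named(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "child_id": ["k1"],
                "cluster_id": ["c1"],
                "weight": [1.0],
                "haz": [0.0],
                "wealth": ["plutocrat"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="wealth"):
            read_child_table(path)
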