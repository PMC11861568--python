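import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumiscreen import phospho
from lumiscreen.errors import SchemaError, ValidationError
from lumiscreen.simulate import PhosphoSimConfig, generate_phospho


def t6_two_tailed(t: float) -> float:
    """Closed-form two-tailed tail probability of Student's t with 6 df.

    Derived symbolically from the density; used as an independent oracle
    for the two-sample pooled test with n=4 per group.
    """
    t = abs(t)
    s = math.sqrt(t * t + 6.0)
    upper = (
        -2 * t**5 + 2 * t**4 * s - 30 * t**3 + 24 * t**2 * s - 135 * t + 72 * s
    ) / (4 * s * (t**4 + 12 * t**2 + 36))
    return 2.0 * upper


def pooled_t(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))


def site_table(rows):
    defaults = dict(
        gene="G", protein_id="P", position=1, residue="S",
        localization_prob=0.99, score_diff=50.0, reverse=False, contaminant=False,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFilterSites:
    def test_localization_prob_boundary_strict(self):
        kept, report = phospho.filter_sites(site_table([{"localization_prob": 0.5}]))
        assert kept.empty
        assert report.set_index("reason").loc["localization_prob", "n_removed"] == 1
        kept, _ = phospho.filter_sites(site_table([{"localization_prob": 0.5000001}]))
        assert len(kept) == 1

    def test_score_diff_boundary_strict(self):
        kept, report = phospho.filter_sites(site_table([{"score_diff": 5.0}]))
        assert kept.empty
        assert report.set_index("reason").loc["score_diff", "n_removed"] == 1
        kept, _ = phospho.filter_sites(site_table([{"score_diff": 5.0000001}]))
        assert len(kept) == 1

    def test_six_site_fixture(self):
        table = site_table(
            [
                {"gene": "A"},
                {"gene": "B", "reverse": True},
                {"gene": "C", "contaminant": True},
                {"gene": "D", "localization_prob": 0.3},
                {"gene": "E"},
                {"gene": "F"},
            ]
        )
        kept, report = phospho.filter_sites(table)
        assert sorted(kept["gene"]) == ["A", "E", "F"]
        assert report["n_removed"].sum() == 3

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            phospho.filter_sites(site_table([{}]).drop(columns=["score_diff"]))

    def test_conservation(self):
        table, _ = generate_phospho(
            PhosphoSimConfig(n_sites=200, n_regulated=0, frac_reverse=0.1,
                             frac_contaminant=0.1, seed=6)
        )
        kept, report = phospho.filter_sites(table)
        assert len(kept) + report["n_removed"].sum() == len(table)


class TestNormalizeLog:
    def test_hand_computed_column(self):
        table = pd.DataFrame({"x": [4.0, 8.0, 16.0]})
        out = phospho.normalize_log(table, ["x"])
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_on_centered_data(self):
        table = pd.DataFrame({"x": [4.0, 8.0, 16.0]})
        once = phospho.normalize_log(table, ["x"])
        again = phospho.normalize_log(np.exp2(once), ["x"])
        pd.testing.assert_frame_equal(once, again)

    def test_scale_invariance(self):
        table = pd.DataFrame({"x": [3.0, 7.0, 11.0, 20.0]})
        base = phospho.normalize_log(table, ["x"])
        scaled = phospho.normalize_log(table * 8.0, ["x"])
        assert base["x"].to_numpy() == pytest.approx(scaled["x"].to_numpy())

    def test_all_medians_zero_after(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.lognormal(10, 1, size=(21, 4)),
                             columns=list("abcd"))
        out = phospho.normalize_log(table, list("abcd"))
        assert out[list("abcd")].median().to_numpy() == pytest.approx([0.0] * 4)

    def test_center_then_log_order(self):
        table = pd.DataFrame({"x": [4.0, 8.0, 16.0]})
        out = phospho.normalize_log(table, ["x"], order="center-then-log")
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            phospho.normalize_log(pd.DataFrame({"x": [1.0, 0.0]}), ["x"])

    def test_unknown_order_rejected(self):
        with pytest.raises(ValidationError):
            phospho.normalize_log(pd.DataFrame({"x": [1.0]}), ["x"], order="sideways")


class TestSiteTtest:
    def test_identical_groups(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        difference, p = phospho.site_ttest(vals, vals)
        assert difference == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_oracle_df6(self):
        a = [0.0, 0.1, -0.1, 0.0]
        b = [0.5, 0.6, 0.4, 0.5]
        difference, p = phospho.site_ttest(a, b)
        assert difference == pytest.approx(-0.5)
        assert p == pytest.approx(t6_two_tailed(pooled_t(a, b)), abs=1e-10)

    @given(
        a=st.lists(st.floats(-2, 2), min_size=4, max_size=4),
        b=st.lists(st.floats(-2, 2), min_size=4, max_size=4),
    )
    @settings(max_examples=60)
    def test_closed_form_oracle_random(self, a, b):
        # near-zero spread triggers catastrophic cancellation in both the
        # implementation and the oracle; the degenerate path owns that case
        if np.var(a) + np.var(b) < 1e-12:
            return
        _, p = phospho.site_ttest(a, b)
        assert p == pytest.approx(t6_two_tailed(pooled_t(a, b)), abs=1e-10)

    def test_zero_variance_equal_means(self):
        difference, p = phospho.site_ttest([1.0, 1.0], [1.0, 1.0])
        assert (difference, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_floored(self, caplog):
        with caplog.at_level("WARNING"):
            difference, p = phospho.site_ttest([1.0, 1.0], [2.0, 2.0])
        assert difference == -1.0
        assert 0 < p <= np.finfo(float).tiny

    def test_welch_option_differs(self):
        a, b = [0.0, 0.1, 0.2, 0.9], [1.0, 1.1, 1.05, 1.08]
        _, p_student = phospho.site_ttest(a, b, test="student")
        _, p_welch = phospho.site_ttest(a, b, test="welch")
        assert p_student != p_welch

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            phospho.site_ttest([1.0], [1.0, 2.0])


class TestAnalyzeSites:
    def make_normalized(self, stim_vals, ctl_vals):
        row = dict(gene="MICAL3", protein_id="P1", position=120, residue="S")
        for i, v in enumerate(stim_vals, start=1):
            row[f"stimulated_{i}"] = v
        for i, v in enumerate(ctl_vals, start=1):
            row[f"control_{i}"] = v
        return pd.DataFrame([row])

    def test_site_id_format(self, phospho_intensity_cols):
        stim, ctl = phospho_intensity_cols
        res = phospho.analyze_sites(
            self.make_normalized([0.2, 0.3, 0.1, 0.2], [0.0, 0.1, -0.1, 0.0]), stim, ctl
        )
        assert res["site_id"].iloc[0] == "MICAL3(120)"

    def test_inclusive_difference_boundary(self, phospho_intensity_cols):
        # difference exactly 0.2 with small p: significant (inclusive >=)
        stim, ctl = phospho_intensity_cols
        res = phospho.analyze_sites(
            self.make_normalized([0.2, 0.3, 0.1, 0.2], [0.0, 0.1, -0.1, 0.0]), stim, ctl
        )
        assert res["difference"].iloc[0] == pytest.approx(0.2)
        assert res["p"].iloc[0] <= 0.05
        assert bool(res["significant"].iloc[0])
        assert res["direction"].iloc[0] == "up"

    def test_inclusive_p_boundary(self):
        # significance rule applied directly at p == 0.05, diff == 0.2
        df = pd.DataFrame({"p": [0.05], "difference": [0.2]})
        significant = (df["p"] <= 0.05) & (df["difference"].abs() >= 0.2)
        assert bool(significant.iloc[0])

    def test_below_min_diff_not_significant(self, phospho_intensity_cols):
        stim, ctl = phospho_intensity_cols
        res = phospho.analyze_sites(
            self.make_normalized([0.1, 0.1001, 0.0999, 0.1], [0.0, 0.0001, -0.0001, 0.0]),
            stim, ctl,
        )
        assert res["p"].iloc[0] < 0.05
        assert not bool(res["significant"].iloc[0])

    def test_missing_values_excluded_and_counted(self, phospho_intensity_cols):
        stim, ctl = phospho_intensity_cols
        table = self.make_normalized([0.1, np.nan, np.nan, np.nan], [0.0, 0.1, 0.0, 0.1])
        res = phospho.analyze_sites(table, stim, ctl)
        assert res.empty
        assert res.attrs["n_excluded_missing"] == 1


class TestAnnotateAndVolcano:
    def results(self):
        return pd.DataFrame(
            {
                "site_id": ["SHANK3(10)", "MICAL3(120)", "OTHER(5)"],
                "gene": ["SHANK3", "MICAL3", "OTHER"],
                "protein_id": ["P1", "P2", "P3"],
                "position": [10, 120, 5],
                "residue": ["S", "S", "T"],
                "difference": [-0.9, -0.4, 0.01],
                "p": [0.001, 0.02, 0.9],
                "significant": [True, True, False],
                "direction": ["down", "down", "up"],
            }
        )

    def test_empty_maps_all_false(self):
        out = phospho.annotate_sites(self.results())
        assert not out["known_regulatory_site"].any()

    def test_gobp_category_flags(self):
        gobp = pd.DataFrame(
            {"gene": ["SHANK3", "MICAL3"], "category": ["cell adhesion", "cytoskeleton organization"]}
        )
        out = phospho.annotate_sites(self.results(), gobp_map=gobp)
        assert out.loc[out["gene"] == "SHANK3", "gobp_cell_adhesion"].iloc[0]
        assert not out.loc[out["gene"] == "OTHER", "gobp_cell_adhesion"].iloc[0]
        assert out.loc[out["gene"] == "MICAL3", "gobp_cytoskeleton_organization"].iloc[0]

    def test_regulatory_site_flag(self):
        out = phospho.annotate_sites(self.results(), regulatory_sites={"SHANK3(10)"})
        assert out.set_index("site_id")["known_regulatory_site"].to_dict() == {
            "SHANK3(10)": True, "MICAL3(120)": False, "OTHER(5)": False,
        }

    def test_volcano_identity_on_fixture(self):
        vol = phospho.volcano_table(self.results())
        assert len(vol) == 3
        assert vol["neg_log10_p"].tolist() == pytest.approx(
            [-np.log10(p) for p in sorted_by_site(self.results())["p"]]
        )
        assert list(vol["site_id"]) == list(sorted_by_site(self.results())["site_id"])

    def test_volcano_empty(self):
        vol = phospho.volcano_table(pd.DataFrame())
        assert vol.empty

    def test_volcano_truth_sites_beyond_thresholds(self, phospho_intensity_cols):
        stim, ctl = phospho_intensity_cols
        table, truth = generate_phospho(
            PhosphoSimConfig(n_sites=400, n_regulated=40, group_difference=1.0,
                             within_group_sd=0.2, seed=13)
        )
        norm = phospho.normalize_log(table, stim + ctl)
        res = phospho.analyze_sites(norm, stim, ctl)
        vol = phospho.volcano_table(res).merge(truth, on="site_id")
        reg = vol[vol["regulated"]]
        assert (reg["difference"].abs() >= 0.2).mean() >= 0.95
        assert (reg["neg_log10_p"] >= -np.log10(0.05)).mean() >= 0.95


def sorted_by_site(df):
    return df.sort_values("site_id", kind="mergesort").reset_index(drop=True)
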