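"""Confounder screen, ANCOVA, exclusion filter, asymmetry statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import nucleoflow as nf
from nucleoflow.cohort import categorical_factor_tests


def _null_frame(rng, n_per=(12, 12), diagnoses=("control", "SCH"), cv=0.25):
    rows = []
    for diag, n in zip(diagnoses, n_per):
        hemi = (["L", "R"] * n)[:n]
        for i in range(n):
            rows.append(
                {
                    "diagnosis": diag,
                    "hemisphere": hemi[i],
                    "density": 1e5 * rng.lognormal(0.0, cv),
                }
            )
    return pd.DataFrame(rows)


class TestConfounderScreen:
    def test_perfectly_linked_covariate(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"density": rng.lognormal(11.5, 0.25, 24)})
        df["cov"] = df["density"]
        report = nf.confounder_screen(df, ["density"], ["cov"])
        row = report.screen.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-10
        assert report.flagged["density"] == ["cov"]

    def test_constant_covariate_reported_null_with_warning(self):
        df = pd.DataFrame({"density": [1.0, 2.0, 3.0], "cov": [5.0, 5.0, 5.0]})
        report = nf.confounder_screen(df, ["density"], ["cov"])
        assert np.isnan(report.screen.iloc[0]["r"])
        assert report.warnings

    def test_null_covariate_flagged_at_nominal_rate(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_reps = 400
        for _ in range(n_reps):
            df = pd.DataFrame(
                {
                    "density": rng.lognormal(11.5, 0.25, 24),
                    "cov": rng.normal(0, 1, 24),
                }
            )
            hits += nf.confounder_screen(df, ["density"], ["cov"]).screen.iloc[0][
                "flagged"
            ]
        assert 0.02 <= hits / n_reps <= 0.08

    def test_generator_injected_link_is_flagged(self):
        cfg = nf.GeneratorConfig(
            group_sizes={("FPC", "control"): 17, ("FPC", "BPD"): 17},
            covariate_links=[nf.CovariateLink("age", slope=-0.02)],
        )
        flagged = 0
        n_reps = 40
        for seed in range(n_reps):
            demo = nf.generate_cohort(cfg, seed, include_events=False).demographics
            rep = nf.confounder_screen(demo, ["true_density_total"], ["age"])
            flagged += rep.screen.iloc[0]["flagged"]
        assert flagged >= 0.9 * n_reps


class TestAncova:
    def test_orthogonal_covariate_matches_t_test(self):
        rng = np.random.default_rng(4)
        df = _null_frame(rng)
        df["cov"] = rng.normal(0, 1, len(df))
        raw = nf.density_group_test(
            {
                "SCH": df.loc[df["diagnosis"] == "SCH", "density"],
                "control": df.loc[df["diagnosis"] == "control", "density"],
            }
        )
        adj = nf.ancova_adjust(df, "density", "diagnosis", ["cov"])
        assert adj["adjusted"]
        assert abs(adj["p"] - raw["p"]) < 0.02

    def test_no_flagged_covariates_passes_through_t_test(self):
        rng = np.random.default_rng(5)
        df = _null_frame(rng)
        res = nf.ancova_adjust(df, "density", "diagnosis", [])
        raw = nf.density_group_test(
            {
                "SCH": df.loc[df["diagnosis"] == "SCH", "density"],
                "control": df.loc[df["diagnosis"] == "control", "density"],
            }
        )
        assert not res["adjusted"]
        assert res["p"] == pytest.approx(raw["p"])

    def test_confound_injected_via_covariate_removed(self):
        """A group difference carried entirely by a covariate vanishes."""
        rng = np.random.default_rng(6)
        ok = 0
        n_reps = 50
        for _ in range(n_reps):
            df = _null_frame(rng, cv=0.15)
            df["pmi"] = rng.normal(25, 8, len(df)) + np.where(
                df["diagnosis"] == "SCH", 15.0, 0.0
            )
            df["density"] *= 1.0 - 0.012 * (df["pmi"] - 25.0)
            adj = nf.ancova_adjust(df, "density", "diagnosis", ["pmi"])
            ok += adj["p"] >= 0.05
        assert ok >= 0.8 * n_reps

    def test_collinear_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        df = _null_frame(rng)
        df["a"] = rng.normal(0, 1, len(df))
        df["b"] = 2.0 * df["a"]
        with pytest.warns(UserWarning, match="collinear"):
            res = nf.ancova_adjust(df, "density", "diagnosis", ["a", "b"])
        assert res["covariates"] == ["a"]
        assert res["dropped"] == ["b"]


class TestExclusionFilter:
    def test_boundary_semantics(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "pmi_h": [40.0, 40.1, 10.0, 10.0],
                "refrigeration_h": [5.0, 5.0, 20.0, 20.1],
            }
        )
        kept = nf.exclusion_filter(df)
        assert list(kept["sample_id"]) == ["a", "c"]

    def test_compliant_cohort_unchanged(self):
        df = pd.DataFrame(
            {"sample_id": ["a", "b"], "pmi_h": [10.0, 20.0], "refrigeration_h": [1.0, 2.0]}
        )
        pd.testing.assert_frame_equal(nf.exclusion_filter(df), df)

    def test_empty_remainder_errors(self):
        df = pd.DataFrame({"pmi_h": [50.0], "refrigeration_h": [5.0]})
        with pytest.raises(nf.DataError):
            nf.exclusion_filter(df)

    def test_filter_reduces_pmi_density_correlation(self):
        cfg = nf.GeneratorConfig(
            group_sizes={("FPC", "control"): 17, ("FPC", "BPD"): 17},
            covariate_links=[nf.CovariateLink("pmi_h", slope=-0.008)],
        )
        full_r, filt_r = [], []
        for seed in range(20):
            demo = nf.generate_cohort(cfg, seed, include_events=False).demographics
            r_full = stats.pearsonr(demo["pmi_h"], demo["true_density_total"])[0]
            kept = nf.exclusion_filter(demo)
            r_filt = stats.pearsonr(kept["pmi_h"], kept["true_density_total"])[0]
            full_r.append(abs(r_full))
            filt_r.append(abs(r_filt))
        assert np.mean(filt_r) < np.mean(full_r)


class TestAsymmetry:
    @pytest.mark.parametrize(
        "left, right, expected",
        [([110.0], [100.0], 10.0), ([100.0], [100.0], 0.0), ([90.0], [100.0], -10.0)],
    )
    def test_rate_examples(self, left, right, expected):
        assert nf.asymmetry_rate(left, right) == pytest.approx(expected)

    @given(
        st.lists(st.floats(10.0, 1e4), min_size=1, max_size=8),
        st.lists(st.floats(10.0, 1e4), min_size=1, max_size=8),
    )
    def test_antisymmetry_under_hemisphere_swap(self, left, right):
        x = nf.asymmetry_rate(left, right)
        y = nf.asymmetry_rate(right, left)
        assert y == pytest.approx(10_000.0 / (100.0 + x) - 100.0, rel=1e-9)

    def test_empty_side_errors(self):
        with pytest.raises(nf.DataError):
            nf.asymmetry_rate([], [1.0])

    def test_factorial_anova_df2_is_n_minus_4(self):
        """12 + 10 subjects in a 2x2 design -> residual df 18."""
        rng = np.random.default_rng(8)
        df = _null_frame(rng, n_per=(12, 10))
        res = nf.asymmetry_anova(df, "density", ("control", "SCH"))
        assert res["df2"] == 18
        assert res["n"] == 22

    def test_empty_cell_errors(self):
        df = pd.DataFrame(
            {
                "diagnosis": ["control"] * 4 + ["SCH"] * 4,
                "hemisphere": ["L", "L", "R", "R", "L", "L", "L", "L"],
                "density": np.arange(8, dtype=float) + 1,
            }
        )
        with pytest.raises(nf.DataError):
            nf.asymmetry_anova(df, "density", ("control", "SCH"))

    def test_reversed_asymmetry_detected_by_interaction(self):
        """Reversed left-right pattern flags the group x hemisphere term."""
        cfg = nf.GeneratorConfig(
            group_sizes={("FPC", "control"): 12, ("FPC", "SCH"): 10},
            between_subject_cv=0.15,
            class_cv=0.0,
            asymmetry={("control", "all"): 1.35, ("SCH", "all"): 0.74},
        )
        hits = 0
        n_reps = 50
        for seed in range(n_reps):
            demo = nf.generate_cohort(cfg, seed, include_events=False).demographics
            res = nf.asymmetry_anova(
                demo, "true_density_total", ("control", "SCH")
            )
            hits += res["p_interaction"] < 0.05
        assert hits >= 0.8 * n_reps

    def test_null_interaction_rate_nominal(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_reps = 300
        for _ in range(n_reps):
            df = _null_frame(rng, n_per=(12, 10))
            hits += (
                nf.asymmetry_anova(df, "density", ("control", "SCH"))["p_interaction"]
                < 0.05
            )
        assert 0.02 <= hits / n_reps <= 0.08


class TestSubgroups:
    def test_control_samples_rejected(self):
        df = pd.DataFrame(
            {
                "diagnosis": ["control", "BPD", "SCH"],
                "density": [1.0, 2.0, 3.0],
                "disease_duration": [np.nan, 10.0, 20.0],
            }
        )
        with pytest.raises(nf.DataError):
            nf.subgroup_correlations(df, ["density"], ["disease_duration"])

    def test_duration_link_recovered_with_positive_sign(self):
        cfg = nf.GeneratorConfig(
            group_sizes={("FPC", "BPD"): 12, ("FPC", "SCH"): 10},
            covariate_links=[nf.CovariateLink("disease_duration", slope=0.03)],
        )
        flagged_positive = 0
        n_reps = 20
        for seed in range(n_reps):
            demo = nf.generate_cohort(cfg, seed, include_events=False).demographics
            table = nf.subgroup_correlations(
                demo, ["true_density_total"], ["disease_duration"]
            )
            row = table.iloc[0]
            flagged_positive += bool(row["flagged"] and row["r"] > 0)
        assert flagged_positive >= 0.7 * n_reps

    def test_categorical_factor_tests_shape(self):
        rng = np.random.default_rng(10)
        df = _null_frame(rng)
        df["gender"] = rng.choice(["M", "F"], len(df))
        df["abuse_severity"] = rng.integers(0, 6, len(df))
        table = categorical_factor_tests(
            df, ["density"], factors=("gender", "hemisphere", "abuse_severity")
        )
        assert set(table["factor"]) == {"gender", "hemisphere", "abuse_severity"}
        assert ((table["p"].dropna() >= 0) & (table["p"].dropna() <= 1)).all()
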