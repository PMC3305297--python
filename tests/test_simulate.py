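"""Generator: determinism, design structure, ground-truth construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nucleoflow as nf
from nucleoflow.config import CLASSES
from nucleoflow.simulate import SampleSpec


def test_same_seed_gives_identical_cohorts(small_config):
    a = nf.generate_cohort(small_config, seed=9)
    b = nf.generate_cohort(small_config, seed=9)
    pd.testing.assert_frame_equal(a.demographics, b.demographics)
    for sid in a.events:
        pd.testing.assert_frame_equal(a.events[sid], b.events[sid])


def test_distinct_seeds_differ(small_config):
    a = nf.generate_cohort(small_config, seed=1, include_events=False)
    b = nf.generate_cohort(small_config, seed=2, include_events=False)
    assert not np.allclose(
        a.demographics["true_density_total"], b.demographics["true_density_total"]
    )


def test_cohort_matches_configured_group_sizes():
    ds = nf.generate_cohort(nf.GeneratorConfig(), seed=0, include_events=False)
    counts = ds.demographics.groupby(["region", "diagnosis"], observed=True).size()
    assert counts[("FPC", "control")] == 12
    assert counts[("FPC", "BPD")] == 12
    assert counts[("FPC", "SCH")] == 10
    assert counts[("ITC", "control")] == 12
    assert counts[("ITC", "BPD")] == 11
    assert counts[("ITC", "SCH")] == 11
    # one hemisphere per subject, roughly balanced within each group
    hemi = ds.demographics.groupby(["region", "diagnosis"], observed=True)[
        "hemisphere"
    ].value_counts()
    for (region, diag), n in counts.items():
        left = hemi.get((region, diag, "L"), 0)
        assert abs(left - n / 2) <= 0.5


def test_null_config_has_no_group_effect():
    """With no effects configured, diagnosis group means agree within 2 s.e.m."""
    cfg = nf.GeneratorConfig()
    means = {d: [] for d in ("control", "BPD", "SCH")}
    for seed in range(200):
        ds = nf.generate_cohort(cfg, seed=seed, include_events=False)
        fpc = ds.demographics[ds.demographics["region"] == "FPC"]
        for d in means:
            means[d].append(
                fpc.loc[fpc["diagnosis"] == d, "true_density_total"].mean()
            )
    control = np.mean(means["control"])
    for d in ("BPD", "SCH"):
        diff = np.mean(means[d]) - control
        sem = np.sqrt(
            np.var(means[d], ddof=1) / 200 + np.var(means["control"], ddof=1) / 200
        )
        assert abs(diff) < 2 * sem


def test_effect_multiplier_is_exact_in_expectation():
    cfg = nf.GeneratorConfig(
        group_sizes={("FPC", "control"): 12, ("FPC", "BPD"): 12},
        effects={("BPD", "FPC", "olig2"): 0.6},
    )
    ratios = []
    for seed in range(50):
        demo = nf.generate_cohort(cfg, seed=seed, include_events=False).demographics
        olig2 = demo["true_density_olig2_weak"] + demo["true_density_olig2_strong"]
        by = olig2.groupby(demo["diagnosis"]).mean()
        ratios.append(by["BPD"] / by["control"])
    sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(np.mean(ratios) - 0.6) < 3 * sem


def _spec_for(cfg, density_total=100_000.0, pmi=0.0):
    return SampleSpec(
        sample_id="s",
        diagnosis="control",
        region="FPC",
        hemisphere="L",
        tissue_mass_mg=20.0,
        covariates={"pmi_h": pmi},
        true_densities={
            cls: density_total * cfg.class_fractions[cls] for cls in CLASSES
        },
        neun_small_weight=cfg.neun_size_mixture.small_weight,
        event_seed=0,
    )


def test_expected_event_count_is_density_mass_aliquot():
    """100k/mg x 20 mg x 1% aliquot -> ~20k nuclei events (Poisson)."""
    cfg = nf.GeneratorConfig()
    ev = nf.generate_sample_events(_spec_for(cfg), cfg, seed=3)
    n_nuclei = (~ev["truth_label"].isin(["bead", "debris"])).sum()
    assert abs(n_nuclei - 20_000) < 5 * np.sqrt(20_000)


def test_class_counts_match_configured_fractions():
    """Chi-square goodness of fit of truth-label counts vs expectation."""
    cfg = nf.GeneratorConfig()
    spec = _spec_for(cfg)
    ev = nf.generate_sample_events(spec, cfg, seed=11)
    truth = ev["truth_label"].str.replace("g2m_", "", regex=False)
    observed = np.array([(truth == cls).sum() for cls in CLASSES])
    expected = np.array(
        [spec.true_densities[cls] * 20.0 * cfg.aliquot_fraction for cls in CLASSES]
    )
    expected = expected / expected.sum() * observed.sum()
    _, p = stats.chisquare(observed, expected)
    assert p > 0.01


def test_zero_drift_leaves_fs_independent_of_pmi():
    cfg = nf.GeneratorConfig(pmi_drift_per_hour=0.0, fs_scale_jitter_cv=0.0)
    nonsig = 0
    for seed in range(20):
        a = nf.generate_sample_events(_spec_for(cfg, pmi=0.0), cfg, seed=seed)
        b = nf.generate_sample_events(_spec_for(cfg, pmi=48.0), cfg, 1000 + seed)
        fs_a = a.loc[a["truth_label"].str.contains("neun"), "fs"]
        fs_b = b.loc[b["truth_label"].str.contains("neun"), "fs"]
        _, p = stats.ks_2samp(fs_a, fs_b)
        nonsig += p >= 0.01
    assert nonsig >= 18


def test_pmi_drift_shifts_fs_upward():
    cfg = nf.GeneratorConfig(fs_scale_jitter_cv=0.0)
    a = nf.generate_sample_events(_spec_for(cfg, pmi=0.0), cfg, seed=5)
    b = nf.generate_sample_events(_spec_for(cfg, pmi=48.0), cfg, seed=5)
    fs_a = a.loc[a["truth_label"].str.contains("neun"), "fs"].mean()
    fs_b = b.loc[b["truth_label"].str.contains("neun"), "fs"].mean()
    assert fs_b > fs_a * 1.05


class TestMicroscopyPairs:
    def test_row_count(self):
        pairs = nf.generate_microscopy_pairs(nf.GeneratorConfig(), 200, seed=1)
        assert len(pairs) == 200
        assert (pairs > 0).all().all()

    def test_identity_when_no_inflation_or_noise(self):
        cfg = nf.GeneratorConfig(area_inflation_slope=0.0, area_noise_sd_um2=0.0)
        pairs = nf.generate_microscopy_pairs(cfg, 100, seed=2)
        res = nf.fs_area_compare(pairs)
        np.testing.assert_allclose(pairs["area_neun"], pairs["area_7aad"])
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_default_calibration_r_in_band(self):
        rs = [
            nf.fs_area_compare(
                nf.generate_microscopy_pairs(nf.GeneratorConfig(), 200, seed=s)
            )["pearson_r"]
            for s in range(20)
        ]
        assert 0.85 <= np.mean(rs) <= 0.97

    def test_rejects_nonpositive_n(self):
        with pytest.raises(nf.ConfigError):
            nf.generate_microscopy_pairs(nf.GeneratorConfig(), 0, seed=1)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        cfg = nf.GeneratorConfig(
            class_fractions={
                "neun": 0.5,
                "olig2_weak": 0.2,
                "olig2_strong": 0.2,
                "double_negative": 0.2,
            }
        )
        with pytest.raises(nf.ConfigError):
            cfg.validate()

    def test_negative_parameters_rejected(self):
        with pytest.raises(nf.ConfigError):
            nf.GeneratorConfig(baseline_density_total=-1.0).validate()
        with pytest.raises(nf.ConfigError):
            nf.GeneratorConfig(debris_fraction=-0.1).validate()

    def test_bad_effect_key_rejected(self):
        with pytest.raises(nf.ConfigError):
            nf.GeneratorConfig(effects={("BPD", "FPC", "nope"): 0.5}).validate()
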