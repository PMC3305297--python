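"""Synthetic cohort generator.

Produces per-sample cytometry event tables (forward scatter + 7-AAD DNA line
+ NeuN and olig2 channels, with counting-bead spike-ins and ground-truth
labels) and a demographics table with the covariates needed for confounder
analysis.  The event model:

* nuclei event counts are Poisson with mean
  ``true_density × tissue_mass × aliquot_fraction`` per class;
* 7-AAD intensities sit on two lines — G0/G1 at I0 and G2/M at 2·I0 — with a
  small CV, emulating intact nuclei with fully preserved DNA;
* forward scatter is drawn from per-class distributions (a two-component
  mixture for NeuN), inflated multiplicatively with postmortem interval so
  that larger nuclei drift more in absolute FS units;
* counting beads appear as a Poisson number of very bright, uniform events.

Ground truth (per-class densities, labels) is recorded so every downstream
stage can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    CLASSES,
    DIAGNOSES,
    CovariateLink,
    GeneratorConfig,
    NeunSizeMixture,
    lognormal_params,
)
from .errors import ConfigError

EVENT_COLUMNS = ("fs", "ch_7aad", "ch_neun", "ch_olig2", "truth_label")

#: continuous covariates screened against density in the full cohort
SCREEN_COVARIATES = (
    "age",
    "refrigeration_h",
    "pmi_h",
    "ph",
    "brain_weight_g",
    "storage_days",
)

#: covariates defined only for diseased subjects
DISEASE_COVARIATES = ("onset_age", "disease_duration", "fluphenazine_mg")


@dataclass
class SampleSpec:
    """Ground-truth description of one tissue sample."""

    sample_id: str
    diagnosis: str
    region: str
    hemisphere: str
    tissue_mass_mg: float
    covariates: dict
    true_densities: dict  # nuclei per mg, keyed by CLASSES
    neun_small_weight: float
    event_seed: int

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ConfigError("hemisphere must be 'L' or 'R'")
        if self.tissue_mass_mg <= 0:
            raise ConfigError("tissue_mass_mg must be positive")

    @property
    def true_density_total(self) -> float:
        return float(sum(self.true_densities.values()))


@dataclass
class CohortDataset:
    """Demographics table plus one event table per sample."""

    demographics: pd.DataFrame
    events: dict  # sample_id -> event DataFrame
    specs: dict = field(default_factory=dict)  # sample_id -> SampleSpec
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.demographics)


def _child_seed(seed: int, index: int) -> int:
    """Deterministic per-sample integer seed below 2**31."""
    state = np.random.SeedSequence([int(seed), int(index)]).generate_state(1)
    return int(state[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GeneratorConfig, seed: int, include_events: bool = True
) -> CohortDataset:
    """Generate a full synthetic cohort.

    Fully reproducible given ``seed``.  With ``include_events=False`` only the
    demographics/ground-truth table is produced (cheap, e.g. for design
    checks).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    cm = config.covariate_model

    specs: list[SampleSpec] = []
    index = 0
    for (region, diagnosis), n in sorted(config.group_sizes.items()):
        # balanced hemisphere assignment, random order within the group
        hemis = ["L", "R"] * (n // 2)
        if n % 2:
            hemis.append(rng.choice(["L", "R"]))
        rng.shuffle(hemis)
        for k in range(n):
            index += 1
            sid = f"{region}-{diagnosis}-{k + 1:02d}"
            cov = _draw_covariates(rng, cm, diagnosis)
            mass = float(
                np.clip(
                    rng.normal(config.tissue_mass_mean_mg, config.tissue_mass_sd_mg),
                    config.tissue_mass_mean_mg * 0.5,
                    config.tissue_mass_mean_mg * 1.5,
                )
            )
            dens = _draw_true_densities(
                rng, config, diagnosis, region, hemis[k], cov
            )
            w_small = config.neun_size_mixture.small_weight
            w_small *= config.small_weight_effects.get((diagnosis, region), 1.0)
            specs.append(
                SampleSpec(
                    sample_id=sid,
                    diagnosis=diagnosis,
                    region=region,
                    hemisphere=hemis[k],
                    tissue_mass_mg=mass,
                    covariates=cov,
                    true_densities=dens,
                    neun_small_weight=float(np.clip(w_small, 0.0, 1.0)),
                    event_seed=_child_seed(seed, index),
                )
            )

    demo = _demographics_frame(specs)
    events = {}
    if include_events:
        for spec in specs:
            events[spec.sample_id] = generate_sample_events(
                spec, config, spec.event_seed
            )
    return CohortDataset(
        demographics=demo,
        events=events,
        specs={s.sample_id: s for s in specs},
        seed=int(seed),
    )


def _draw_covariates(rng, cm, diagnosis: str) -> dict:
    age = float(np.clip(rng.normal(cm.age_mean, cm.age_sd), 18.0, 80.0))
    cov = {
        "age": age,
        "pmi_h": float(
            np.clip(
                rng.normal(cm.pmi_mean, cm.pmi_sd)
                + cm.pmi_shift.get(diagnosis, 0.0),
                2.0,
                90.0,
            )
        ),
        "refrigeration_h": float(
            np.clip(
                rng.normal(cm.refrigeration_mean, cm.refrigeration_sd)
                + cm.refrigeration_shift.get(diagnosis, 0.0),
                0.0,
                48.0,
            )
        ),
        "ph": float(np.clip(rng.normal(cm.ph_mean, cm.ph_sd), 5.8, 7.2)),
        "brain_weight_g": float(
            np.clip(rng.normal(cm.brain_weight_mean, cm.brain_weight_sd), 900, 2000)
        ),
        "storage_days": float(
            np.clip(rng.normal(cm.storage_days_mean, cm.storage_days_sd), 30, 1500)
        ),
        "gender": str(rng.choice(["M", "F"])),
        "abuse_severity": int(rng.integers(0, 6)),
    }
    if diagnosis == "control":
        cov.update({k: np.nan for k in DISEASE_COVARIATES})
    else:
        onset = float(np.clip(rng.normal(cm.onset_age_mean, cm.onset_age_sd), 12, 45))
        onset = min(onset, age - 1.0)
        cov["onset_age"] = onset
        cov["disease_duration"] = age - onset
        cov["fluphenazine_mg"] = float(
            rng.lognormal(cm.fluphenazine_logmean, cm.fluphenazine_logsd)
        )
    return cov


def _covariate_reference(cm, name: str) -> float:
    return {
        "age": cm.age_mean,
        "pmi_h": cm.pmi_mean,
        "refrigeration_h": cm.refrigeration_mean,
        "ph": cm.ph_mean,
        "brain_weight_g": cm.brain_weight_mean,
        "storage_days": cm.storage_days_mean,
        "onset_age": cm.onset_age_mean,
        "disease_duration": cm.age_mean - cm.onset_age_mean,
        "fluphenazine_mg": float(np.exp(cm.fluphenazine_logmean)),
    }[name]


def _draw_true_densities(rng, config, diagnosis, region, hemisphere, cov) -> dict:
    mu_s, sd_s = lognormal_params(config.between_subject_cv)
    subject_factor = float(rng.lognormal(mu_s, sd_s)) if sd_s > 0 else 1.0
    mu_c, sd_c = lognormal_params(config.class_cv)
    dens = {}
    for cls in CLASSES:
        d = config.baseline_density_total * config.class_fractions[cls]
        d *= config.density_multiplier(diagnosis, region, cls)
        if hemisphere == "L":
            d *= config.asymmetry_multiplier(diagnosis, cls)
        d *= subject_factor
        if sd_c > 0:
            d *= float(rng.lognormal(mu_c, sd_c))
        for link in config.covariate_links:
            if link.nucleus_class not in (
                cls,
                "all",
            ) and not (
                link.nucleus_class == "olig2"
                and cls in ("olig2_weak", "olig2_strong")
            ):
                continue
            x = cov.get(link.covariate, np.nan)
            if np.isfinite(x):
                ref = _covariate_reference(config.covariate_model, link.covariate)
                d *= max(0.0, 1.0 + link.slope * (x - ref))
        dens[cls] = max(0.0, d)
    return dens


def _demographics_frame(specs) -> pd.DataFrame:
    rows = []
    for s in specs:
        row = {
            "sample_id": s.sample_id,
            "diagnosis": s.diagnosis,
            "region": s.region,
            "hemisphere": s.hemisphere,
            "tissue_mass_mg": s.tissue_mass_mg,
        }
        row.update(s.covariates)
        row["neun_small_weight"] = s.neun_small_weight
        for cls in CLASSES:
            row[f"true_density_{cls}"] = s.true_densities[cls]
        row["true_density_total"] = s.true_density_total
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# event-level generation
# ---------------------------------------------------------------------------

def generate_sample_events(
    spec: SampleSpec, config: GeneratorConfig, seed: int
) -> pd.DataFrame:
    """Generate the cytometry event table for one sample.

    Returns a DataFrame with columns ``fs`` (int, 0-1023), ``ch_7aad``,
    ``ch_neun``, ``ch_olig2`` (arbitrary units, >= 0) and ``truth_label``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    af = config.aliquot_fraction
    mass = spec.tissue_mass_mg
    i0 = config.dna_intensity_i0
    pmi = float(spec.covariates.get("pmi_h", 0.0))
    drift = 1.0 + config.pmi_drift_per_hour * pmi
    mu_j, sd_j = lognormal_params(config.fs_scale_jitter_cv)
    fs_scale = float(rng.lognormal(mu_j, sd_j)) if sd_j > 0 else 1.0

    parts = []
    expected_nuclei = 0.0
    for cls in CLASSES:
        lam = spec.true_densities[cls] * mass * af
        expected_nuclei += lam
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        fs = _draw_fs(rng, config, spec, cls, n) * drift * fs_scale
        g2m = rng.random(n) < config.g2m_fraction
        line = np.where(g2m, 2.0 * i0, i0)
        ch_dna = np.abs(rng.normal(line, config.dna_cv * line))
        ch_neun, ch_olig2 = _draw_markers(rng, config, cls, n)
        labels = np.where(g2m, f"g2m_{cls}", cls)
        parts.append((fs, ch_dna, ch_neun, ch_olig2, labels))

    # debris: dim sub-line 7-AAD signal, small FS, marker-negative
    n_debris = int(rng.poisson(config.debris_fraction * expected_nuclei))
    if n_debris:
        fs = np.abs(rng.normal(80.0, 30.0, n_debris)) * fs_scale
        ch_dna = i0 * rng.uniform(0.05, 0.5, n_debris)
        ch_neun = rng.lognormal(config.neun_neg_logmean, config.neun_logsd, n_debris)
        ch_olig2 = rng.lognormal(
            config.olig2_neg_logmean, config.olig2_logsd, n_debris
        )
        parts.append((fs, ch_dna, ch_neun, ch_olig2, np.full(n_debris, "debris")))

    # counting beads: bright, uniform, co-measured with the same aliquot
    n_beads = int(rng.poisson(config.bead_count_added * af))
    if n_beads:
        fs = rng.normal(config.bead_fs_loc, config.bead_fs_scale, n_beads)
        ch_dna = np.abs(
            rng.normal(config.bead_intensity, config.bead_cv * config.bead_intensity, n_beads)
        )
        bright = 0.2 * config.bead_intensity
        ch_neun = np.abs(rng.normal(bright, 0.02 * bright, n_beads))
        ch_olig2 = np.abs(rng.normal(bright, 0.02 * bright, n_beads))
        parts.append((fs, ch_dna, ch_neun, ch_olig2, np.full(n_beads, "bead")))

    if not parts:
        return pd.DataFrame(
            {
                "fs": np.array([], dtype=np.int64),
                "ch_7aad": [],
                "ch_neun": [],
                "ch_olig2": [],
                "truth_label": [],
            }
        )

    fs = np.concatenate([p[0] for p in parts])
    table = pd.DataFrame(
        {
            "fs": np.clip(np.rint(fs), 0, 1023).astype(np.int64),
            "ch_7aad": np.concatenate([p[1] for p in parts]),
            "ch_neun": np.concatenate([p[2] for p in parts]),
            "ch_olig2": np.concatenate([p[3] for p in parts]),
            "truth_label": np.concatenate([p[4] for p in parts]),
        }
    )
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


def _draw_fs(rng, config, spec, cls: str, n: int) -> np.ndarray:
    if cls == "neun":
        mix = config.neun_size_mixture
        small = rng.random(n) < spec.neun_small_weight
        fs = np.where(
            small,
            rng.normal(mix.small_loc, mix.small_scale, n),
            rng.normal(mix.large_loc, mix.large_scale, n),
        )
    elif cls in ("olig2_weak", "olig2_strong"):
        fs = rng.normal(config.olig2_fs_loc, config.olig2_fs_scale, n)
    else:
        fs = rng.normal(config.dneg_fs_loc, config.dneg_fs_scale, n)
    return np.clip(fs, 0.0, 1023.0)


def _draw_markers(rng, config, cls: str, n: int):
    if cls == "neun":
        ch_neun = rng.lognormal(config.neun_pos_logmean, config.neun_logsd, n)
    else:
        ch_neun = rng.lognormal(config.neun_neg_logmean, config.neun_logsd, n)
    if cls == "olig2_weak":
        ch_olig2 = rng.lognormal(config.olig2_weak_logmean, config.olig2_logsd, n)
    elif cls == "olig2_strong":
        ch_olig2 = rng.lognormal(config.olig2_strong_logmean, config.olig2_logsd, n)
    else:
        ch_olig2 = rng.lognormal(config.olig2_neg_logmean, config.olig2_logsd, n)
    return ch_neun, ch_olig2


# ---------------------------------------------------------------------------
# microscopy cross-validation pairs
# ---------------------------------------------------------------------------

def generate_microscopy_pairs(
    config: GeneratorConfig, n: int, seed: int
) -> pd.DataFrame:
    """Paired 7-AAD / NeuN traced nuclear areas (µm²) for FS validation.

    The 7-AAD area is the FS mixture mapped linearly to area; the NeuN area
    adds a perinuclear inflation term active above the configured onset area
    (the microscopy equivalent of the FS 400 exclusion point) plus tracing
    noise.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    rng = np.random.default_rng(seed)
    mix = config.neun_size_mixture
    small = rng.random(n) < mix.small_weight
    fs = np.where(
        small,
        rng.normal(mix.small_loc, mix.small_scale, n),
        rng.normal(mix.large_loc, mix.large_scale, n),
    )
    fs = np.clip(fs, 1.0, 1023.0)
    area_7aad = fs * config.area_per_fs
    inflation = config.area_inflation_slope * np.maximum(
        0.0, area_7aad - config.area_inflation_onset_um2
    )
    noise = rng.normal(0.0, config.area_noise_sd_um2, n)
    area_neun = np.maximum(1.0, area_7aad + inflation + noise)
    return pd.DataFrame({"area_7aad": area_7aad, "area_neun": area_neun})


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def build_disease_scenario(**overrides) -> GeneratorConfig:
    """Cohort configuration with the disease pattern switched on.

    Encodes the qualitative case-control pattern the analysis is designed to
    detect: an oligodendrocyte-lineage deficit confined to the frontopolar
    cortex of bipolar-disorder samples (stronger in the weak/mature peak), a
    reduced small-NeuN component weight in schizophrenia FPC and in both
    diagnoses' inferior temporal cortex (with compensating large weight, so
    total neuronal density is preserved), and a left-greater-than-right
    density asymmetry in controls that is reversed in schizophrenia.
    """
    effects = {
        ("BPD", "FPC", "olig2_weak"): 0.47,
        ("BPD", "FPC", "olig2_strong"): 0.72,
        ("BPD", "FPC", "neun"): 0.88,
        ("BPD", "FPC", "double_negative"): 0.88,
    }
    small_weight_effects = {
        ("SCH", "FPC"): 0.80,
        ("SCH", "ITC"): 0.80,
        ("BPD", "ITC"): 0.80,
    }
    asymmetry = {
        ("control", "all"): 1.10,
        ("SCH", "all"): 0.90,
        ("BPD", "all"): 1.02,
    }
    kwargs = dict(
        effects=effects,
        small_weight_effects=small_weight_effects,
        asymmetry=asymmetry,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def build_rat_pmi_config(**overrides) -> GeneratorConfig:
    """Configuration for the rat postmortem-interval drift scenario.

    Rat cortical NeuN nuclei are modelled with a dominant small component at
    FS ~128 and a minor large component at FS ~600.  With the multiplicative
    PMI drift (calibrated to ~10% peak shift at 48 h), the count in the fixed
    range FS 101-199 — which straddles the dominant peak — is nearly invariant
    to the shift, while the tail range FS 251-349 responds strongly: the
    qualitative behaviour seen when postmortem delay inflates apparent
    nuclear size without changing nuclei numbers.
    """
    kwargs = dict(
        neun_size_mixture=NeunSizeMixture(
            small_loc=128.0,
            small_scale=45.0,
            large_loc=600.0,
            large_scale=100.0,
            small_weight=0.85,
        ),
        class_fractions={
            "neun": 0.60,
            "olig2_weak": 0.06,
            "olig2_strong": 0.04,
            "double_negative": 0.30,
        },
        baseline_density_total=60_000.0,
        between_subject_cv=0.05,
        class_cv=0.02,
        fs_scale_jitter_cv=0.03,
        group_sizes={("FPC", "control"): 4},
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def generate_rat_pmi_groups(
    config: GeneratorConfig,
    pmi_hours: Mapping[str, float],
    n_per_group: int,
    seed: int,
) -> dict:
    """Generate rat samples at fixed postmortem intervals.

    Returns ``{group_name: [event DataFrame, ...]}`` where every sample in a
    group shares the given PMI (all other covariates at their reference).
    """
    out = {}
    idx = 0
    for name, pmi in pmi_hours.items():
        tables = []
        for _ in range(n_per_group):
            idx += 1
            sub_seed = _child_seed(seed, idx)
            rng = np.random.default_rng(np.random.SeedSequence([seed, idx, 7]))
            mu_s, sd_s = lognormal_params(config.between_subject_cv)
            factor = float(rng.lognormal(mu_s, sd_s)) if sd_s > 0 else 1.0
            dens = {
                cls: config.baseline_density_total
                * config.class_fractions[cls]
                * factor
                for cls in CLASSES
            }
            spec = SampleSpec(
                sample_id=f"rat-{name}-{idx}",
                diagnosis="control",
                region="FPC",
                hemisphere="L",
                tissue_mass_mg=config.tissue_mass_mean_mg,
                covariates={"pmi_h": float(pmi)},
                true_densities=dens,
                neun_small_weight=config.neun_size_mixture.small_weight,
                event_seed=sub_seed,
            )
            tables.append(generate_sample_events(spec, config, sub_seed))
        out[name] = tables
    return out
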