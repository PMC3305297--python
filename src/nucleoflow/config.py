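"""Configuration objects for the synthetic cohort generator.

The generator emulates a flow-cytometric nuclei-counting study of postmortem
cortical gray matter: per-sample event lists (forward scatter + 7-AAD DNA
channel + NeuN and olig2 immunofluorescence channels) with counting-bead
spike-ins, plus a demographics table with the covariates used for confounder
screening.  Baseline densities and class fractions are explicit configuration
defaults — the source study reports group contrasts graphically, not absolute
control levels — and are documented as arbitrary but realistic choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError

#: Nuclear classes forming a partition of all 7-AAD(+) nuclei.
CLASSES = ("neun", "olig2_weak", "olig2_strong", "double_negative")

#: Diagnostic groups.
DIAGNOSES = ("control", "BPD", "SCH")

#: Sampled cortical regions: frontopolar (BA10) and inferior temporal (BA20).
REGIONS = ("FPC", "ITC")

#: Group sizes of the emulated cohort (samples per region × diagnosis).
DEFAULT_GROUP_SIZES = {
    ("FPC", "control"): 12,
    ("FPC", "BPD"): 12,
    ("FPC", "SCH"): 10,
    ("ITC", "control"): 12,
    ("ITC", "BPD"): 11,
    ("ITC", "SCH"): 11,
}


@dataclass
class NeunSizeMixture:
    """Two-component normal mixture for NeuN(+) forward scatter (FS 0-1023).

    The small component stands for small (mostly non-pyramidal) neuronal
    nuclei, the large one for large pyramidal nuclei whose apparent FS is
    unreliable above the FS 400 exclusion point.
    """

    small_loc: float = 240.0
    small_scale: float = 45.0
    large_loc: float = 470.0
    large_scale: float = 80.0
    small_weight: float = 0.55

    def validate(self) -> None:
        if not 0.0 <= self.small_weight <= 1.0:
            raise ConfigError("small_weight must be in [0, 1]")
        if min(self.small_scale, self.large_scale) <= 0:
            raise ConfigError("mixture scales must be positive")


@dataclass
class CovariateModel:
    """Distributions of the demographic covariates.

    Units: age (years), PMI and refrigeration interval (hours), pH, brain
    weight (grams), frozen storage (days); disease-only covariates: age at
    onset (years), duration of disease (years), lifetime fluphenazine
    equivalent (mg).  Values are drawn from clipped normals (lognormal for
    fluphenazine) and are realistic for a brain-bank cohort.
    """

    age_mean: float = 45.0
    age_sd: float = 10.0
    pmi_mean: float = 30.0
    pmi_sd: float = 15.0
    #: optional per-diagnosis additive PMI shift in hours (the source cohorts
    #: had longer PMIs in the SCH group; default is the null model)
    pmi_shift: dict = field(default_factory=dict)
    refrigeration_mean: float = 10.0
    refrigeration_sd: float = 7.0
    refrigeration_shift: dict = field(default_factory=dict)
    ph_mean: float = 6.4
    ph_sd: float = 0.25
    brain_weight_mean: float = 1450.0
    brain_weight_sd: float = 130.0
    storage_days_mean: float = 400.0
    storage_days_sd: float = 200.0
    onset_age_mean: float = 24.0
    onset_age_sd: float = 6.0
    fluphenazine_logmean: float = 9.9  # ~e^9.9 = 20 g lifetime equivalent
    fluphenazine_logsd: float = 1.0


@dataclass
class CovariateLink:
    """Multiplicative linear link from a covariate to class densities.

    density *= max(0, 1 + slope * (covariate - covariate mean)).
    ``nucleus_class`` may be one of CLASSES, "olig2" (both olig2 classes) or
    "all".
    """

    covariate: str
    slope: float
    nucleus_class: str = "all"


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Absolute levels (baseline density, class fractions, channel intensities)
    are configuration defaults, not published values.  Effects, asymmetry
    multipliers and covariate links default to the null model.
    """

    # --- densities -------------------------------------------------------
    #: nuclei per mg of gray matter (all classes combined)
    baseline_density_total: float = 100_000.0
    #: partition of nuclei into classes; must sum to 1
    class_fractions: dict = field(
        default_factory=lambda: {
            "neun": 0.45,
            "olig2_weak": 0.07,
            "olig2_strong": 0.05,
            "double_negative": 0.43,
        }
    )
    #: shared between-subject lognormal CV applied to all classes of a sample
    between_subject_cv: float = 0.25
    #: additional independent per-class lognormal CV
    class_cv: float = 0.10

    # --- forward scatter -------------------------------------------------
    neun_size_mixture: NeunSizeMixture = field(default_factory=NeunSizeMixture)
    olig2_fs_loc: float = 200.0
    olig2_fs_scale: float = 40.0
    dneg_fs_loc: float = 170.0
    dneg_fs_scale: float = 45.0
    #: per-sample lognormal CV of a common FS scale factor (instrument drift)
    fs_scale_jitter_cv: float = 0.03
    #: FS inflation per hour of PMI: FS <- FS * (1 + drift * PMI).
    #: Default calibrated so a 48 h PMI shifts FS peaks by ~10%.
    pmi_drift_per_hour: float = 0.1 / 48.0

    # --- fluorescence channels ------------------------------------------
    #: location of the G0/G1 7-AAD DNA line (arbitrary units); the G2/M line
    #: sits at exactly twice this intensity
    dna_intensity_i0: float = 10_000.0
    dna_cv: float = 0.03
    g2m_fraction: float = 0.02
    #: log-intensity (natural log) locations/scales of the marker channels
    neun_neg_logmean: float = math.log(5.0)
    neun_pos_logmean: float = math.log(200.0)
    neun_logsd: float = 0.45
    olig2_neg_logmean: float = math.log(5.0)
    olig2_weak_logmean: float = math.log(60.0)
    olig2_strong_logmean: float = math.log(600.0)
    olig2_logsd: float = 0.35

    # --- debris and beads ------------------------------------------------
    #: debris events as a fraction of expected nuclei events
    debris_fraction: float = 0.05
    #: counting beads added per measured aliquot
    bead_count_added: float = 10_000.0
    bead_intensity: float = 500_000.0
    bead_cv: float = 0.01
    bead_fs_loc: float = 900.0
    bead_fs_scale: float = 10.0

    # --- microscopy cross-validation ------------------------------------
    #: linear FS -> nuclear area map, µm² per FS unit (FS 400 <-> 200 µm²)
    area_per_fs: float = 0.5
    #: perinuclear inflation of the NeuN-traced area above the onset area:
    #: area_neun = area_7aad + slope * max(0, area_7aad - onset) + noise
    area_inflation_slope: float = 0.15
    area_inflation_onset_um2: float = 200.0
    area_noise_sd_um2: float = 25.0

    # --- sampling --------------------------------------------------------
    #: fraction of the homogenate measured by the cytometer
    aliquot_fraction: float = 0.01
    #: dissected gray-matter mass, mg ("about 20 mg" design)
    tissue_mass_mean_mg: float = 20.0
    tissue_mass_sd_mg: float = 1.5

    # --- study design ----------------------------------------------------
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    #: multiplicative density effects keyed (diagnosis, region, class);
    #: class may be one of CLASSES, "olig2", or "all"; effects compose
    effects: dict = field(default_factory=dict)
    #: multiplier on the NeuN small-component weight keyed (diagnosis, region);
    #: the large weight compensates so total NeuN density is unchanged
    small_weight_effects: dict = field(default_factory=dict)
    #: left/right density multiplier keyed (diagnosis, class or "all");
    #: applied to left-hemisphere samples only
    asymmetry: dict = field(default_factory=dict)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    covariate_links: Sequence[CovariateLink] = field(default_factory=list)

    # ---------------------------------------------------------------------
    def validate(self) -> None:
        if set(self.class_fractions) != set(CLASSES):
            raise ConfigError(f"class_fractions must have keys {CLASSES}")
        fracs = [self.class_fractions[c] for c in CLASSES]
        if any(f < 0 for f in fracs):
            raise ConfigError("class fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("class fractions must sum to 1")
        for name in (
            "baseline_density_total",
            "dna_intensity_i0",
            "bead_count_added",
            "aliquot_fraction",
            "tissue_mass_mean_mg",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "between_subject_cv",
            "class_cv",
            "fs_scale_jitter_cv",
            "debris_fraction",
            "dna_cv",
            "bead_cv",
            "pmi_drift_per_hour",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.g2m_fraction < 1.0:
            raise ConfigError("g2m_fraction must be in [0, 1)")
        self.neun_size_mixture.validate()
        for (region, diagnosis), n in self.group_sizes.items():
            if diagnosis not in DIAGNOSES:
                raise ConfigError(f"unknown diagnosis {diagnosis!r}")
            if n < 1:
                raise ConfigError("group sizes must be >= 1")
        for key, mult in self.effects.items():
            if len(key) != 3 or key[2] not in CLASSES + ("olig2", "all"):
                raise ConfigError(f"bad effect key {key!r}")
            if mult < 0:
                raise ConfigError("effect multipliers must be non-negative")

    # ---------------------------------------------------------------------
    def density_multiplier(self, diagnosis: str, region: str, cls: str) -> float:
        """Compose the configured effects for one (diagnosis, region, class)."""
        mult = self.effects.get((diagnosis, region, cls), 1.0)
        if cls in ("olig2_weak", "olig2_strong"):
            mult *= self.effects.get((diagnosis, region, "olig2"), 1.0)
        mult *= self.effects.get((diagnosis, region, "all"), 1.0)
        return mult

    def asymmetry_multiplier(self, diagnosis: str, cls: str) -> float:
        return self.asymmetry.get((diagnosis, cls), 1.0) * self.asymmetry.get(
            (diagnosis, "all"), 1.0
        )

    def regions(self) -> tuple:
        seen = []
        for region, _ in self.group_sizes:
            if region not in seen:
                seen.append(region)
        return tuple(seen)


def lognormal_params(cv: float) -> tuple:
    """(mu, sigma) of a lognormal with mean exactly 1 and the given CV."""
    sigma2 = math.log(1.0 + cv * cv)
    return -sigma2 / 2.0, math.sqrt(sigma2)
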