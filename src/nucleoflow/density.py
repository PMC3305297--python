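"""Bead-calibrated absolute nuclei densities and group comparisons.

The counting beads are spiked into the measured aliquot at a known quantity,
so the ratio of nuclei events to bead events converts directly into the
absolute number of nuclei in the homogenate:

    total nuclei = (nuclei events / bead events) × beads added
    density      = total nuclei / tissue mass (per mg)

Class densities are the total density multiplied by each gated class
proportion, which makes class-density conservation exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, DataError
from .gating import GatingResult

DENSITY_CLASSES = ("total", "neun", "olig2", "olig2_weak", "olig2_strong",
                   "double_negative")


@dataclass
class DensityRecord:
    """Absolute nuclei densities (per mg) for one sample."""

    sample_id: str
    densities: dict  # keyed by DENSITY_CLASSES; weak/strong None when unsplit
    two_peaks_detected: bool = False

    def __getitem__(self, cls: str) -> float:
        return self.densities[cls]


def compute_densities(
    gating: GatingResult,
    tissue_mass_mg: float,
    beads_added: float,
    sample_id: str = "",
) -> DensityRecord:
    """Convert a gating result into absolute densities per mg."""
    if tissue_mass_mg <= 0:
        raise DataError("tissue_mass_mg must be positive")
    if beads_added <= 0:
        raise DataError("beads_added must be positive")
    n_beads = gating.counts["beads"]
    if n_beads == 0:
        raise CalibrationError("no bead events: cannot calibrate absolute counts")

    total_nuclei = gating.counts["total_nuclei"] / n_beads * beads_added
    density_total = total_nuclei / tissue_mass_mg
    densities = {"total": density_total}
    for cls in ("neun", "olig2", "double_negative"):
        densities[cls] = density_total * gating.proportions.get(cls, 0.0)
    if gating.two_peaks_detected:
        densities["olig2_weak"] = density_total * gating.proportions["olig2_weak"]
        densities["olig2_strong"] = density_total * gating.proportions["olig2_strong"]
    else:
        densities["olig2_weak"] = None
        densities["olig2_strong"] = None
    return DensityRecord(
        sample_id=sample_id,
        densities=densities,
        two_peaks_detected=gating.two_peaks_detected,
    )


def percent_difference(case_values, control_values) -> float:
    """Percent difference of group means: (case − control) / control × 100.

    Negative values mean a deficit in the case group relative to controls.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise DataError("both groups must be non-empty")
    control_mean = control.mean()
    if control_mean <= 0:
        raise DataError("control mean must be positive")
    return float((case.mean() - control_mean) / control_mean * 100.0)


def density_group_test(
    groups: dict,
    control: str = "control",
    mode: str = "auto",
    equal_var: bool = True,
) -> dict:
    """Between-group test of densities.

    Two groups: two-sided unpaired t-test (Student by default, Welch with
    ``equal_var=False``).  Three or more: one-way ANOVA.  For two groups the
    percent difference of means (case relative to ``control``) is reported.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise DataError(f"group {name!r} has fewer than 2 samples")
    if mode == "auto":
        mode = "t_test" if len(names) == 2 else "one_way_anova"

    if mode == "t_test":
        if len(names) != 2:
            raise DataError("t_test mode requires exactly two groups")
        if control in names:
            case_name = names[0] if names[1] == control else names[1]
        else:
            case_name, control = names[0], names[1]
        case, ctrl = arrays[case_name], arrays[control]
        t, p = stats.ttest_ind(case, ctrl, equal_var=equal_var)
        if equal_var:
            df = case.size + ctrl.size - 2
        else:
            v1, v2 = case.var(ddof=1) / case.size, ctrl.var(ddof=1) / ctrl.size
            df = (v1 + v2) ** 2 / (
                v1**2 / (case.size - 1) + v2**2 / (ctrl.size - 1)
            )
        return {
            "mode": "t_test",
            "statistic": float(t),
            "df": float(df),
            "p": float(p),
            "percent_difference": percent_difference(case, ctrl),
            "case": case_name,
            "control": control,
        }

    if mode == "one_way_anova":
        f, p = stats.f_oneway(*arrays.values())
        k = len(names)
        n = sum(a.size for a in arrays.values())
        return {
            "mode": "one_way_anova",
            "statistic": float(f),
            "df": (k - 1, n - k),
            "p": float(p),
            "percent_difference": None,
        }
    raise DataError(f"unknown mode {mode!r}")
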