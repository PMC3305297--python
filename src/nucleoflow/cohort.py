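"""Cohort-level inference: confounders, ANCOVA, exclusion, asymmetry.

The confounder battery follows the screening-then-adjustment design common
in postmortem studies: Pearson correlations between each class density and
each continuous covariate flag candidates at p < 0.05 (uncorrected, by
design); flagged covariates enter an ANCOVA (OLS of density on diagnostic
group plus covariates) whose group term is the adjusted test.  Hemispheric
asymmetry uses the index mean(left)/mean(right) × 100 − 100 and a two-factor
factorial ANOVA (group × hemisphere); the interaction term is designated the
asymmetry-difference statistic, since "the asymmetry differs between groups"
is an interaction claim, and the group main effect is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DataError

SCREEN_ALPHA = 0.05


@dataclass
class ConfounderReport:
    """Correlation screen plus (optionally) ANCOVA-adjusted group tests."""

    screen: pd.DataFrame  # columns: class, covariate, r, p, n, flagged
    flagged: dict  # class -> list of covariates with p < alpha
    ancova: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)


@dataclass
class AsymmetryResult:
    nucleus_class: str
    region: str
    rates: dict  # diagnosis -> asymmetry rate (%)
    anova: dict  # comparison -> {F_group, p_group, F_interaction, ...}


# ---------------------------------------------------------------------------
# confounder screen and ANCOVA
# ---------------------------------------------------------------------------

def confounder_screen(
    data: pd.DataFrame,
    density_cols,
    covariates,
    alpha: float = SCREEN_ALPHA,
) -> ConfounderReport:
    """Pearson screen of each density column against each covariate.

    Rows with missing values are dropped pairwise.  A constant covariate
    yields a null (NaN) correlation and a warning rather than an error.
    """
    rows = []
    notes = []
    flagged: dict = {c: [] for c in density_cols}
    for cls in density_cols:
        if cls not in data.columns:
            raise DataError(f"density column {cls!r} missing")
        for cov in covariates:
            if cov not in data.columns:
                raise DataError(f"covariate {cov!r} missing from demographics")
            sub = data[[cls, cov]].dropna()
            y = sub[cls].to_numpy(dtype=float)
            x = sub[cov].to_numpy(dtype=float)
            if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((cls, cov, np.nan, np.nan, len(sub), False))
                notes.append(f"{cls} ~ {cov}: correlation undefined (constant input)")
                continue
            r, p = stats.pearsonr(x, y)
            sig = bool(p < alpha)
            rows.append((cls, cov, float(r), float(p), len(sub), sig))
            if sig:
                flagged[cls].append(cov)
    screen = pd.DataFrame(
        rows, columns=["class", "covariate", "r", "p", "n", "flagged"]
    )
    return ConfounderReport(screen=screen, flagged=flagged, warnings=notes)


def ancova_adjust(
    data: pd.DataFrame,
    value_col: str,
    group_col: str,
    covariates,
    groups=None,
) -> dict:
    """Group effect on a density adjusted for covariates (OLS ANCOVA).

    Returns the group-term F and p from a type-II ANOVA of
    ``value ~ C(group) + covariates``.  With no covariates, falls back to
    the plain unpaired t-test (pass-through contract).  Collinear covariates
    are dropped with a warning.
    """
    sub = data.copy()
    if groups is not None:
        sub = sub[sub[group_col].isin(groups)]
    sub = sub.dropna(subset=[value_col, group_col])
    if sub[group_col].nunique() < 2:
        raise DataError("ANCOVA requires at least two groups")
    for g, cnt in sub[group_col].value_counts().items():
        if cnt < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")

    covariates = [c for c in covariates if c in sub.columns]
    if not covariates:
        levels = list(sub[group_col].unique())
        arrays = {g: sub.loc[sub[group_col] == g, value_col].to_numpy() for g in levels}
        from .density import density_group_test

        res = density_group_test(arrays)
        return {
            "adjusted": False,
            "covariates": [],
            "F": None,
            "p": res["p"],
            "df": res["df"],
            "n": len(sub),
            "dropped": [],
        }

    sub = sub.dropna(subset=covariates)
    kept, dropped = [], []
    for cov in covariates:
        x = sub[cov].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            dropped.append(cov)
            continue
        trial = kept + [cov]
        mat = np.column_stack([sub[c].to_numpy(dtype=float) for c in trial])
        mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        if np.linalg.matrix_rank(mat, tol=1e-8) < len(trial):
            dropped.append(cov)
            continue
        kept.append(cov)
    if dropped:
        warnings.warn(f"dropping collinear/constant covariates: {dropped}")

    rhs = " + ".join([f"C({group_col})"] + [f"Q('{c}')" for c in kept])
    model = smf.ols(f"Q('{value_col}') ~ {rhs}", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"C({group_col})"]
    return {
        "adjusted": True,
        "covariates": kept,
        "F": float(row["F"]),
        "p": float(row["PR(>F)"]),
        "df": (int(row["df"]), int(table.loc["Residual", "df"])),
        "n": len(sub),
        "dropped": dropped,
    }


# ---------------------------------------------------------------------------
# exclusion-matched reanalysis
# ---------------------------------------------------------------------------

def exclusion_filter(
    demographics: pd.DataFrame,
    pmi_max: float = 40.0,
    refrigeration_max: float = 20.0,
    pmi_col: str = "pmi_h",
    refrigeration_col: str = "refrigeration_h",
) -> pd.DataFrame:
    """Drop samples with PMI > ``pmi_max`` or refrigeration > ``refrigeration_max``.

    Strict-inequality exclusion: a sample exactly at the threshold is kept.
    """
    for col in (pmi_col, refrigeration_col):
        if col not in demographics.columns:
            raise DataError(f"demographics missing column {col!r}")
    keep = (demographics[pmi_col] <= pmi_max) & (
        demographics[refrigeration_col] <= refrigeration_max
    )
    out = demographics[keep]
    if len(out) == 0:
        raise DataError("exclusion filter removed every sample")
    return out


# ---------------------------------------------------------------------------
# hemispheric asymmetry
# ---------------------------------------------------------------------------

def asymmetry_rate(left_densities, right_densities) -> float:
    """mean(left)/mean(right) × 100 − 100; positive = left-greater-than-right."""
    left = np.asarray(left_densities, dtype=float)
    right = np.asarray(right_densities, dtype=float)
    if left.size == 0 or right.size == 0:
        raise DataError("both hemispheres must have samples")
    right_mean = right.mean()
    if right_mean <= 0:
        raise DataError("right-hemisphere mean must be positive")
    return float(left.mean() / right_mean * 100.0 - 100.0)


def asymmetry_anova(
    data: pd.DataFrame,
    value_col: str,
    diagnosis_pair,
    group_col: str = "diagnosis",
    hemisphere_col: str = "hemisphere",
) -> dict:
    """Two-factor factorial ANOVA (group × hemisphere) on one density.

    All four design cells must be non-empty.  Reports the group main effect
    and the group × hemisphere interaction (the designated asymmetry-
    difference statistic); residual df is N − 4 for the 2 × 2 design.
    """
    sub = data[data[group_col].isin(diagnosis_pair)].dropna(subset=[value_col])
    cells = sub.groupby([group_col, hemisphere_col], observed=True).size()
    for g in diagnosis_pair:
        for h in ("L", "R"):
            if cells.get((g, h), 0) == 0:
                raise DataError(f"empty design cell ({g}, {h})")
    model = smf.ols(
        f"Q('{value_col}') ~ C({group_col}) * C({hemisphere_col})", data=sub
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter_key = f"C({group_col}):C({hemisphere_col})"
    df2 = int(table.loc["Residual", "df"])
    return {
        "F_group": float(table.loc[f"C({group_col})", "F"]),
        "p_group": float(table.loc[f"C({group_col})", "PR(>F)"]),
        "F_interaction": float(table.loc[inter_key, "F"]),
        "p_interaction": float(table.loc[inter_key, "PR(>F)"]),
        "df1": 1,
        "df2": df2,
        "n": len(sub),
    }


def asymmetry_analysis(
    data: pd.DataFrame,
    value_col: str,
    nucleus_class: str,
    region: str,
    diagnoses=("control", "BPD", "SCH"),
    pairs=(("control", "SCH"), ("control", "BPD"), ("BPD", "SCH")),
) -> AsymmetryResult:
    """Asymmetry rates per diagnosis plus pairwise factorial ANOVAs."""
    rates = {}
    for diag in diagnoses:
        sub = data[data["diagnosis"] == diag]
        left = sub.loc[sub["hemisphere"] == "L", value_col].dropna()
        right = sub.loc[sub["hemisphere"] == "R", value_col].dropna()
        rates[diag] = (
            asymmetry_rate(left, right) if len(left) and len(right) else np.nan
        )
    anova = {}
    for pair in pairs:
        try:
            anova["_vs_".join(pair)] = asymmetry_anova(data, value_col, pair)
        except DataError:
            anova["_vs_".join(pair)] = None
    return AsymmetryResult(
        nucleus_class=nucleus_class, region=region, rates=rates, anova=anova
    )


# ---------------------------------------------------------------------------
# disease-only subgroup analyses
# ---------------------------------------------------------------------------

def subgroup_correlations(
    data: pd.DataFrame,
    density_cols,
    covariates=("onset_age", "disease_duration", "fluphenazine_mg"),
    alpha: float = SCREEN_ALPHA,
) -> pd.DataFrame:
    """Pearson r/p per class × disease-only covariate on diseased samples.

    Raises if any control sample is passed in (these covariates are defined
    only for diseased subjects) or if fewer than 3 samples remain.
    """
    if "diagnosis" in data.columns and (data["diagnosis"] == "control").any():
        raise DataError("subgroup correlations are defined for diseased samples only")
    if len(data) < 3:
        raise DataError("need at least 3 diseased samples")
    report = confounder_screen(data, density_cols, covariates, alpha)
    return report.screen


def categorical_factor_tests(
    data: pd.DataFrame,
    density_cols,
    factors=("gender", "hemisphere", "abuse_severity"),
) -> pd.DataFrame:
    """Unpaired t-tests of densities across binary/binarized factors.

    ``abuse_severity`` (an ordinal score) is binarized at its median; other
    factors must have exactly two observed levels.
    """
    rows = []
    for factor in factors:
        if factor not in data.columns:
            continue
        col = data[factor]
        if col.dtype.kind in "if":
            cut = col.median()
            groups = np.where(col <= cut, "low", "high")
        else:
            groups = col.astype(str).to_numpy()
        levels = sorted(pd.unique(groups))
        if len(levels) != 2:
            continue
        for cls in density_cols:
            a = data.loc[groups == levels[0], cls].dropna()
            b = data.loc[groups == levels[1], cls].dropna()
            if len(a) < 2 or len(b) < 2:
                rows.append((cls, factor, np.nan, np.nan, np.nan))
                continue
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append((cls, factor, float(t), len(a) + len(b) - 2, float(p)))
    return pd.DataFrame(rows, columns=["class", "factor", "t", "df", "p"])
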