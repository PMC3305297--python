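"""Forward-scatter (nuclear size) distribution analysis.

NeuN(+) nuclei with FS >= 400 are excluded (their apparent size is inflated
by incompletely removed perinuclear material), the remaining population is
adjusted to a fixed total of 10,000 so samples are comparable, and 21
overlapping 100-FS-unit windows (starts 100..300 at steps of 10) are each
compared between groups with an unpaired t-test.  Fixed-range count tests
and the FS <-> microscopic-area comparison live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .gating import GatingResult

FS_EXCLUSION = 400
ADJUSTED_TOTAL = 10_000.0


@dataclass
class WindowSpec:
    """Sliding-window layout: [start, start+width-1], start_min..start_max."""

    start_min: int = 100
    start_max: int = 300
    step: int = 10
    width: int = 100

    def __post_init__(self) -> None:
        if self.step <= 0 or self.width <= 0:
            raise DataError("window step and width must be positive")
        if self.start_max < self.start_min:
            raise DataError("start_max must be >= start_min")

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.start_min, self.start_max + 1, self.step)

    def windows(self) -> list:
        return [(int(s), int(s + self.width - 1)) for s in self.starts]

    def __len__(self) -> int:
        return len(self.starts)


def class_fs_values(
    events: pd.DataFrame, gating: GatingResult, nucleus_class: str = "neun"
) -> np.ndarray:
    """FS values of gated events of one nuclear class (G2/M included)."""
    labels = gating.labels
    if nucleus_class == "olig2":
        mask = np.isin(labels, ("olig2", "olig2_weak", "olig2_strong"))
    else:
        mask = labels == nucleus_class
    return events["fs"].to_numpy()[mask]


def adjusted_fs_counts(
    fs_values,
    adjusted_total: float = ADJUSTED_TOTAL,
    method: str = "scale",
    fs_exclusion: int = FS_EXCLUSION,
    seed: int | None = None,
) -> np.ndarray:
    """Per-FS-value counts below the exclusion point, adjusted to a fixed total.

    ``method="scale"`` (default) multiplies the raw integer counts by a
    common factor (fractional counts are kept so the total is exact);
    ``method="subsample"`` draws ``adjusted_total`` events without
    replacement using ``seed``.
    Returns an array of length ``fs_exclusion`` indexed by FS value.
    """
    fs = np.asarray(fs_values)
    fs = fs[(fs >= 0) & (fs < fs_exclusion)]
    if fs.size == 0:
        raise DataError(
            f"no events retained below the FS {fs_exclusion} exclusion point"
        )
    if method == "scale":
        counts = np.bincount(fs.astype(np.int64), minlength=fs_exclusion).astype(float)
        return counts * (adjusted_total / fs.size)
    if method == "subsample":
        total = int(adjusted_total)
        if fs.size < total:
            raise DataError(
                f"cannot subsample {total} events from {fs.size}; use method='scale'"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(fs, size=total, replace=False)
        return np.bincount(chosen.astype(np.int64), minlength=fs_exclusion).astype(
            float
        )
    raise DataError(f"unknown adjustment method {method!r}")


def neun_size_distribution(
    events: pd.DataFrame,
    gating: GatingResult,
    nucleus_class: str = "neun",
    adjusted_total: float = ADJUSTED_TOTAL,
    method: str = "scale",
    fs_exclusion: int = FS_EXCLUSION,
    seed: int | None = None,
) -> np.ndarray:
    """Adjusted FS count distribution of one gated class for one sample."""
    fs = class_fs_values(events, gating, nucleus_class)
    return adjusted_fs_counts(fs, adjusted_total, method, fs_exclusion, seed)


def window_counts(counts: np.ndarray, spec: WindowSpec | None = None) -> np.ndarray:
    """Sum the per-FS counts over each closed window [start, start+width-1]."""
    spec = spec or WindowSpec()
    counts = np.asarray(counts, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    out = []
    for lo, hi in spec.windows():
        hi = min(hi, len(counts) - 1)
        out.append(cum[hi + 1] - cum[lo])
    return np.asarray(out)


def window_group_tests(
    group_counts: dict,
    spec: WindowSpec | None = None,
    equal_var: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Unpaired t-test per FS window between two groups.

    ``group_counts`` maps group name -> 2-D array (samples × FS values) of
    adjusted counts.  No multiplicity correction is applied by default (the
    21 windows are reported as-is); ``holm=True`` adds a Holm-adjusted
    column.
    """
    spec = spec or WindowSpec()
    if len(group_counts) != 2:
        raise DataError("window_group_tests requires exactly two groups")
    (name_a, a), (name_b, b) = group_counts.items()
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("each group needs at least 2 samples")

    wa = np.stack([window_counts(row, spec) for row in a])
    wb = np.stack([window_counts(row, spec) for row in b])
    t, p = stats.ttest_ind(wa, wb, axis=0, equal_var=equal_var)
    df = a.shape[0] + b.shape[0] - 2
    out = pd.DataFrame(
        {
            "window_start": spec.starts,
            "window_end": spec.starts + spec.width - 1,
            f"mean_{name_a}": wa.mean(axis=0),
            f"sem_{name_a}": stats.sem(wa, axis=0),
            f"mean_{name_b}": wb.mean(axis=0),
            f"sem_{name_b}": stats.sem(wb, axis=0),
            "t": t,
            "df": df,
            "p": p,
        }
    )
    if holm:
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p"].to_numpy(), method="holm")[1]
    return out


def range_counts(fs_values, fs_range, normalize_to: float | None = None) -> float:
    """Events in the closed FS range [lo, hi], optionally per fixed total."""
    lo, hi = fs_range
    fs = np.asarray(fs_values)
    count = float(((fs >= lo) & (fs <= hi)).sum())
    if normalize_to is not None:
        if fs.size == 0:
            raise DataError("cannot normalize an empty FS list")
        count *= normalize_to / fs.size
    return count


def range_count_test(
    group_fs: dict,
    fs_range=(101, 199),
    normalize_to: float | None = None,
    equal_var: bool = True,
) -> dict:
    """Between-group test of per-sample event counts in a fixed FS range.

    ``group_fs`` maps group name -> list of per-sample FS arrays.  Two groups
    are compared by unpaired t-test, three or more by one-way ANOVA.
    """
    lo, hi = fs_range
    if not (0 <= lo <= hi <= 1023):
        raise DataError(f"invalid FS range {fs_range}")
    counts = {
        name: np.array([range_counts(fs, fs_range, normalize_to) for fs in samples])
        for name, samples in group_fs.items()
    }
    for name, arr in counts.items():
        if arr.size < 2:
            raise DataError(f"group {name!r} has fewer than 2 samples")
    names = list(counts)
    if len(names) == 2:
        a, b = counts[names[0]], counts[names[1]]
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        if np.isnan(t):  # identical degenerate groups
            t, p = 0.0, 1.0
        return {
            "mode": "t_test",
            "statistic": float(t),
            "df": a.size + b.size - 2,
            "p": float(p),
            "counts": counts,
        }
    f, p = stats.f_oneway(*counts.values())
    n = sum(arr.size for arr in counts.values())
    return {
        "mode": "one_way_anova",
        "statistic": float(f),
        "df": (len(names) - 1, n - len(names)),
        "p": float(p),
        "counts": counts,
    }


def fs_area_compare(
    pairs: pd.DataFrame,
    fs_values=None,
    bin_width_area: float = 50.0,
) -> dict:
    """Compare microscopic nuclear areas of the two markers, plus FS shape.

    Returns 50 µm²-binned histograms of the paired 7-AAD and NeuN traced
    areas, the Pearson correlation between the paired areas, and (when FS
    values are supplied) an FS histogram for visual shape comparison.
    """
    for col in ("area_7aad", "area_neun"):
        if col not in pairs.columns:
            raise DataError(f"pairs table missing column {col!r}")
    if len(pairs) < 3:
        raise DataError("need at least 3 area pairs")
    a7 = pairs["area_7aad"].to_numpy(dtype=float)
    an = pairs["area_neun"].to_numpy(dtype=float)
    if np.ptp(a7) == 0 or np.ptp(an) == 0:
        r, p = (1.0, 0.0) if np.allclose(a7, an) else (np.nan, np.nan)
    else:
        r, p = stats.pearsonr(a7, an)
    top = max(a7.max(), an.max())
    edges = np.arange(0.0, top + bin_width_area, bin_width_area)
    hist_7aad, _ = np.histogram(a7, bins=edges)
    hist_neun, _ = np.histogram(an, bins=edges)
    out = {
        "pearson_r": float(r),
        "p": float(p),
        "bin_edges": edges,
        "hist_7aad": hist_7aad,
        "hist_neun": hist_neun,
    }
    if fs_values is not None:
        fs = np.asarray(fs_values)
        fs_edges = np.arange(0, 1024 + 32, 32)
        out["fs_hist"], out["fs_bin_edges"] = np.histogram(fs, bins=fs_edges)
    return out
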