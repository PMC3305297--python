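"""Event gating: beads, DNA-line nuclei, marker classes, olig2 peak split.

The gating logic mirrors how intact-nuclei suspensions present on a
cytometer: counting beads form a very bright, uniform population; 7-AAD(+)
nuclei align on two horizontal intensity lines (G0/G1 at I0 and G2/M at
2·I0); debris sits below the lines.  Among nuclei, NeuN and olig2 positivity
is decided by thresholds that default to the valley between the negative and
positive log-intensity modes, so gating is invariant to a uniform rescaling
of the fluorescence axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import CalibrationError, DataError, GatingError

CLASS_LABELS = ("neun", "olig2", "double_negative")


@dataclass
class GatingConfig:
    """Tunable gating parameters.

    ``dna_line_tolerance`` is the half-width of the DNA-line gates in
    multiples of the estimated line CV.  Marker thresholds are either a
    fluorescence cutoff or ``"auto"`` (kernel-smoothed histogram valley).
    """

    dna_line_tolerance: float = 3.0
    neun_threshold: Union[float, str] = "auto"
    olig2_threshold: Union[float, str] = "auto"
    #: bead gate: events brighter than this multiple of the median 7-AAD
    bead_ratio_threshold: float = 5.0
    #: absolute 7-AAD intensity below which events are debris outright
    #: (0 disables the floor; line gating then decides)
    debris_cutoff: float = 0.0
    require_beads: bool = True
    #: two-peak detectability criteria for the olig2 split
    olig2_min_weight: float = 0.10
    olig2_min_separation: float = 2.0
    min_olig2_events: int = 20
    split_olig2: bool = True
    random_state: int = 0

    def validate(self) -> None:
        from .errors import ConfigError

        if self.dna_line_tolerance <= 0:
            raise ConfigError("dna_line_tolerance must be positive")
        for name in ("neun_threshold", "olig2_threshold"):
            v = getattr(self, name)
            if v != "auto" and (not np.isfinite(v) or v < 0):
                raise ConfigError(f"{name} must be 'auto' or a cutoff >= 0")


@dataclass
class OligoSplit:
    """Outcome of the two-component olig2 intensity decomposition."""

    two_peaks_detected: bool
    weak_count: int | None = None
    strong_count: int | None = None
    log_means: tuple | None = None
    weights: tuple | None = None
    boundary: float | None = None
    reason: str = ""


@dataclass
class GatingResult:
    """Per-sample gating outcome.

    ``labels`` assigns every event one of: ``bead``, ``debris``, ``neun``,
    ``olig2`` (refined to ``olig2_weak`` / ``olig2_strong`` when two peaks
    are detected), ``double_negative``.  ``g2m`` marks nuclei on the doubled
    DNA line; they count as nuclei of their marker class.
    """

    counts: dict
    proportions: dict
    two_peaks_detected: bool
    labels: np.ndarray
    g2m_mask: np.ndarray
    i0: float
    line_cv: float
    thresholds: dict
    split: OligoSplit | None = None
    warnings: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smoothed_log_hist(values: np.ndarray, bins: int = 128, sigma: float = 3.0):
    logs = np.log(values[values > 0])
    if logs.size == 0:
        return None, None
    lo, hi = logs.min(), logs.max()
    if hi - lo < 1e-9:
        hi = lo + 1e-9
    hist, edges = np.histogram(logs, bins=bins, range=(lo, hi))
    smooth = gaussian_filter1d(hist.astype(float), sigma)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return smooth, centers


def _mode_of(values: np.ndarray) -> float:
    smooth, centers = _smoothed_log_hist(values)
    if smooth is None or smooth.max() <= 0:
        raise GatingError("DNA intensity mode not identifiable")
    return float(np.exp(centers[int(np.argmax(smooth))]))


def _valley_threshold(values: np.ndarray) -> float:
    """Threshold separating the negative mode from the positive population.

    The negative (unstained) population is the lowest-intensity substantive
    mode; the threshold is placed at the first substantive valley between it
    and the nearest mode to its right.  A fluorescence distribution may be
    trimodal (negative / weak / strong), so the split must happen at the
    first valley, not the deepest one.  Falls back to +inf (everything
    negative) when no positive mode exists.
    """
    smooth, centers = _smoothed_log_hist(values)
    if smooth is None:
        return np.inf
    interior = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] > smooth[2:])
    peaks = np.flatnonzero(interior) + 1
    if smooth[0] > smooth[1]:
        peaks = np.r_[0, peaks]
    if smooth[-1] > smooth[-2]:
        peaks = np.r_[peaks, len(smooth) - 1]
    # prune tiny bumps
    peaks = peaks[smooth[peaks] > 0.02 * smooth.max()]
    if len(peaks) < 2:
        return np.inf
    negative = int(peaks.min())
    for cand in peaks[peaks > negative + 3]:
        valley = negative + int(np.argmin(smooth[negative : cand + 1]))
        depth = smooth[valley]
        if depth < 0.5 * min(smooth[negative], smooth[cand]):
            return float(np.exp(centers[valley]))
    return np.inf


# ---------------------------------------------------------------------------
# main gate
# ---------------------------------------------------------------------------

def gate_events(events: pd.DataFrame, config: GatingConfig | None = None) -> GatingResult:
    """Classify raw events into beads, nuclei classes, G2/M and debris."""
    config = config or GatingConfig()
    config.validate()
    if events is None or len(events) == 0:
        raise DataError("cannot gate an empty event table")
    for col in ("fs", "ch_7aad", "ch_neun", "ch_olig2"):
        if col not in events.columns:
            raise DataError(f"event table missing channel {col!r}")

    dna = events["ch_7aad"].to_numpy(dtype=float)
    n = len(events)
    labels = np.full(n, "excluded", dtype=object)

    # 1. beads: uniform, much brighter than the DNA lines
    median = float(np.median(dna))
    if median <= 0:
        raise GatingError("7-AAD channel is degenerate (median <= 0)")
    bead_mask = dna > config.bead_ratio_threshold * median
    labels[bead_mask] = "bead"
    n_beads = int(bead_mask.sum())
    if config.require_beads and n_beads == 0:
        raise CalibrationError(
            "no counting-bead events found; absolute densities cannot be calibrated"
        )

    rest = ~bead_mask
    if config.debris_cutoff > 0:
        floor = rest & (dna < config.debris_cutoff)
        labels[floor] = "debris"
        rest = rest & ~floor
        if not rest.any():
            return _empty_result(labels, n_beads, np.zeros(n, dtype=bool))

    # 2. DNA line position and width
    i0 = _mode_of(dna[rest])
    near = rest & (np.abs(dna - i0) < 0.2 * i0)
    if near.sum() >= 2:
        line_cv = float(np.std(dna[near]) / np.mean(dna[near]))
    else:
        line_cv = 0.05
    line_cv = float(np.clip(line_cv, 0.005, 0.2))

    tol = config.dna_line_tolerance * line_cv
    g01 = rest & (np.abs(dna - i0) <= tol * i0)
    g2m = rest & ~g01 & (np.abs(dna - 2.0 * i0) <= tol * 2.0 * i0)
    nuclei = g01 | g2m
    labels[rest & ~nuclei] = "debris"

    # 3. marker classes among nuclei
    ch_neun = events["ch_neun"].to_numpy(dtype=float)
    ch_olig2 = events["ch_olig2"].to_numpy(dtype=float)
    thr_neun = (
        _valley_threshold(ch_neun[nuclei])
        if config.neun_threshold == "auto"
        else float(config.neun_threshold)
    )
    thr_olig2 = (
        _valley_threshold(ch_olig2[nuclei])
        if config.olig2_threshold == "auto"
        else float(config.olig2_threshold)
    )
    neun_pos = nuclei & (ch_neun > thr_neun)
    olig2_pos = nuclei & (ch_olig2 > thr_olig2)
    double_pos = int((neun_pos & olig2_pos).sum())
    # disjointness: double-positive events are assigned to NeuN (fixed rule)
    olig2_only = olig2_pos & ~neun_pos
    dneg = nuclei & ~neun_pos & ~olig2_only
    labels[neun_pos] = "neun"
    labels[olig2_only] = "olig2"
    labels[dneg] = "double_negative"

    counts = {
        "total_nuclei": int(nuclei.sum()),
        "neun": int(neun_pos.sum()),
        "olig2": int(olig2_only.sum()),
        "double_negative": int(dneg.sum()),
        "beads": n_beads,
        "g2m": int(g2m.sum()),
        "debris": int((labels == "debris").sum()),
        "olig2_weak": None,
        "olig2_strong": None,
    }

    # 4. olig2 weak/strong decomposition
    split = None
    two_peaks = False
    if config.split_olig2 and counts["olig2"] >= max(2, config.min_olig2_events):
        split = split_olig2_peaks(ch_olig2[olig2_only], config)
        two_peaks = split.two_peaks_detected
        if two_peaks:
            counts["olig2_weak"] = split.weak_count
            counts["olig2_strong"] = split.strong_count
            weak = olig2_only & (ch_olig2 <= split.boundary)
            labels[weak] = "olig2_weak"
            labels[olig2_only & ~weak] = "olig2_strong"

    total = counts["total_nuclei"]
    if total > 0:
        proportions = {
            cls: counts[cls] / total for cls in ("neun", "olig2", "double_negative")
        }
        if two_peaks:
            proportions["olig2_weak"] = counts["olig2_weak"] / total
            proportions["olig2_strong"] = counts["olig2_strong"] / total
    else:
        proportions = {cls: 0.0 for cls in ("neun", "olig2", "double_negative")}

    return GatingResult(
        counts=counts,
        proportions=proportions,
        two_peaks_detected=two_peaks,
        labels=labels,
        g2m_mask=g2m,
        i0=i0,
        line_cv=line_cv,
        thresholds={"neun": thr_neun, "olig2": thr_olig2},
        split=split,
        warnings={"double_positive": double_pos},
    )


def _empty_result(labels, n_beads, g2m_mask) -> GatingResult:
    counts = {
        "total_nuclei": 0,
        "neun": 0,
        "olig2": 0,
        "double_negative": 0,
        "beads": n_beads,
        "g2m": 0,
        "debris": int((labels == "debris").sum()),
        "olig2_weak": None,
        "olig2_strong": None,
    }
    return GatingResult(
        counts=counts,
        proportions={c: 0.0 for c in ("neun", "olig2", "double_negative")},
        two_peaks_detected=False,
        labels=labels,
        g2m_mask=g2m_mask,
        i0=float("nan"),
        line_cv=float("nan"),
        thresholds={},
    )


# ---------------------------------------------------------------------------
# olig2 two-peak decomposition
# ---------------------------------------------------------------------------

def split_olig2_peaks(
    olig2_intensities, config: GatingConfig | None = None
) -> OligoSplit:
    """Two-component decomposition of olig2(+) log intensity.

    Fits a two-component Gaussian mixture on the natural log of the olig2
    intensities.  Two peaks are declared detectable when the lighter
    component holds at least ``olig2_min_weight`` of the mass and the means
    are separated by at least ``olig2_min_separation`` pooled within-
    component standard deviations.  The weak/strong boundary is the point of
    equal posterior responsibility (events are hard-assigned by posterior,
    which for a 1-D two-component mixture is a single intensity cut).
    """
    from sklearn.mixture import GaussianMixture

    config = config or GatingConfig()
    if hasattr(olig2_intensities, "to_numpy"):
        if "ch_olig2" in getattr(olig2_intensities, "columns", ()):
            olig2_intensities = olig2_intensities["ch_olig2"]
        olig2_intensities = olig2_intensities.to_numpy()
    x = np.asarray(olig2_intensities, dtype=float)
    x = x[x > 0]
    if x.size < 2:
        raise DataError("olig2 peak split requires at least 2 olig2(+) events")
    logs = np.log(x).reshape(-1, 1)
    if np.ptp(logs) < 1e-12:
        return OligoSplit(False, reason="degenerate (constant intensity)")
    try:
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            n_init=2,
            random_state=config.random_state,
            reg_covar=1e-6,
        ).fit(logs)
    except Exception as exc:  # non-convergence is a flag, not a crash
        return OligoSplit(False, reason=f"fit failed: {exc}")
    if not gm.converged_:
        return OligoSplit(False, reason="EM did not converge")

    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    separation = abs(means[1] - means[0]) / max(pooled_sd, 1e-12)
    if weights.min() < config.olig2_min_weight:
        return OligoSplit(
            False,
            log_means=tuple(means),
            weights=tuple(weights),
            reason=f"minor component weight {weights.min():.3f} below threshold",
        )
    if separation < config.olig2_min_separation:
        return OligoSplit(
            False,
            log_means=tuple(means),
            weights=tuple(weights),
            reason=f"separation {separation:.2f} sd below threshold",
        )

    post = gm.predict_proba(logs)[:, order]
    weak_mask = post[:, 0] >= post[:, 1]  # lower-intensity component = weak
    if weak_mask.any() and (~weak_mask).any():
        boundary = float(
            np.sqrt(x[weak_mask].max() * x[~weak_mask].min())
        )
    else:
        boundary = float(np.exp(np.mean(means)))
    return OligoSplit(
        True,
        weak_count=int(weak_mask.sum()),
        strong_count=int((~weak_mask).sum()),
        log_means=tuple(means),
        weights=tuple(weights),
        boundary=boundary,
    )
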