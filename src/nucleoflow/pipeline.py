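"""End-to-end pipeline: simulate/load -> gate -> quantify -> size -> stats.

A single :class:`RunConfig` drives a reproducible run that emits all the
figure/table analogs as TSV files plus a machine-readable manifest (config
hash, seed, package versions).  Every stage error is re-raised with the
stage name and sample id attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ancova_adjust,
    asymmetry_analysis,
    categorical_factor_tests,
    confounder_screen,
    exclusion_filter,
    subgroup_correlations,
)
from .config import GeneratorConfig
from .density import compute_densities, density_group_test
from .errors import DataError, NucleoflowError
from .gating import GatingConfig, gate_events
from .io import read_dataset
from .simulate import SCREEN_COVARIATES, CohortDataset, generate_cohort
from .size import WindowSpec, neun_size_distribution, window_group_tests

DENSITY_TEST_CLASSES = ("total", "neun", "olig2", "double_negative")
PAIRS = (("BPD", "control"), ("SCH", "control"))


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    gating: GatingConfig = field(default_factory=GatingConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    window_classes: tuple = ("neun",)
    adjusted_total: float = 10_000.0
    adjustment_method: str = "scale"
    pmi_max: float = 40.0
    refrigeration_max: float = 20.0
    #: beads added per aliquot when loading external data (synthetic runs
    #: take this from the generator config)
    beads_added: float = 10_000.0
    out_dir: str | None = None
    format: str = "tabular"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise DataError(
                "exactly one input source required: generator config or input_dir"
            )
        if self.adjustment_method not in ("scale", "subsample"):
            raise DataError(f"unknown adjustment method {self.adjustment_method!r}")


def _stage(stage: str, sample_id: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                where = f"stage {stage!r}" + (
                    f", sample {sample_id!r}" if sample_id else ""
                )
                raise NucleoflowError(f"{where}: {exc}") from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of result tables.

    When ``config.out_dir`` is set, every table is also written as TSV along
    with ``manifest.json``.
    """
    config.validate()

    with _stage("input"):
        if config.generator is not None:
            dataset = generate_cohort(config.generator, config.seed)
            beads_added = config.generator.bead_count_added
        else:
            dataset = read_dataset(config.input_dir, config.format)
            beads_added = config.beads_added

    demo = dataset.demographics
    gatings, records, fs_counts = {}, {}, {}
    for sample_id, events in dataset.events.items():
        with _stage("gating", sample_id):
            gatings[sample_id] = gate_events(events, config.gating)
        with _stage("density", sample_id):
            mass = float(demo.loc[sample_id, "tissue_mass_mg"])
            records[sample_id] = compute_densities(
                gatings[sample_id], mass, beads_added, sample_id
            )
        with _stage("size", sample_id):
            per_class = {}
            for cls in config.window_classes:
                try:
                    per_class[cls] = neun_size_distribution(
                        events,
                        gatings[sample_id],
                        nucleus_class=cls,
                        adjusted_total=config.adjusted_total,
                        method=config.adjustment_method,
                        seed=config.seed,
                    )
                except DataError:
                    per_class[cls] = None
            fs_counts[sample_id] = per_class

    densities = _density_frame(demo, records)
    results = {"densities": densities}
    results["density_tests"] = _density_tests(densities)
    results["window_stats"] = _window_stats(densities, fs_counts, config)
    results["asymmetry"] = _asymmetry_tables(densities)
    screen, ancova = _confounders(densities)
    results["confounder_screen"] = screen
    results["ancova"] = ancova
    results["exclusion_density_tests"], results["exclusion_window_stats"] = (
        _exclusion_reanalysis(densities, fs_counts, config)
    )
    results["subgroup_correlations"] = _subgroups(densities)
    results["categorical_tests"] = _categoricals(densities)

    if config.out_dir is not None:
        _write_results(results, config, dataset)
    return results


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def _density_frame(demo: pd.DataFrame, records: dict) -> pd.DataFrame:
    rows = []
    for sample_id, rec in records.items():
        row = {
            "sample_id": sample_id,
            "region": demo.loc[sample_id, "region"],
            "diagnosis": demo.loc[sample_id, "diagnosis"],
            "hemisphere": demo.loc[sample_id, "hemisphere"],
            "two_peaks_detected": rec.two_peaks_detected,
        }
        for cls, val in rec.densities.items():
            row[f"density_{cls}"] = val if val is not None else np.nan
        for col in demo.columns:
            if col not in row and col != "sample_id":
                row[col] = demo.loc[sample_id, col]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def _density_tests(densities: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for region in sorted(densities["region"].unique()):
        sub = densities[densities["region"] == region]
        for case, control in PAIRS:
            if not ((sub["diagnosis"] == case).sum() >= 2):
                continue
            for cls in DENSITY_TEST_CLASSES + ("olig2_weak", "olig2_strong"):
                col = f"density_{cls}"
                if cls in ("olig2_weak", "olig2_strong"):
                    pool = sub[sub["two_peaks_detected"]]
                else:
                    pool = sub
                a = pool.loc[pool["diagnosis"] == case, col].dropna()
                b = pool.loc[pool["diagnosis"] == control, col].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                res = density_group_test({case: a, control: b}, control=control)
                rows.append(
                    {
                        "region": region,
                        "class": cls,
                        "comparison": f"{case}_vs_{control}",
                        "n_case": len(a),
                        "n_control": len(b),
                        "percent_difference": res["percent_difference"],
                        "t": res["statistic"],
                        "df": res["df"],
                        "p": res["p"],
                    }
                )
    return pd.DataFrame(rows)


def _window_stats(densities, fs_counts, config) -> pd.DataFrame:
    frames = []
    for region in sorted(densities["region"].unique()):
        sub = densities[densities["region"] == region]
        for cls in config.window_classes:
            for case, control in PAIRS:
                groups = {}
                for name in (case, control):
                    ids = sub.loc[sub["diagnosis"] == name, "sample_id"]
                    mats = [
                        fs_counts[i][cls]
                        for i in ids
                        if fs_counts[i].get(cls) is not None
                    ]
                    if len(mats) >= 2:
                        groups[name] = np.stack(mats)
                if len(groups) != 2:
                    continue
                table = window_group_tests(groups, config.window)
                table = table.rename(
                    columns={
                        f"mean_{case}": "mean_case",
                        f"sem_{case}": "sem_case",
                        f"mean_{control}": "mean_control",
                        f"sem_{control}": "sem_control",
                    }
                )
                table.insert(0, "region", region)
                table.insert(1, "class", cls)
                table.insert(2, "comparison", f"{case}_vs_{control}")
                frames.append(table)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _asymmetry_tables(densities: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for region in sorted(densities["region"].unique()):
        sub = densities[densities["region"] == region]
        for cls in DENSITY_TEST_CLASSES:
            res = asymmetry_analysis(sub, f"density_{cls}", cls, region)
            row = {"region": region, "class": cls}
            for diag, rate in res.rates.items():
                row[f"rate_{diag}"] = rate
            for comp, anova in res.anova.items():
                if anova is None:
                    continue
                row[f"F_interaction_{comp}"] = anova["F_interaction"]
                row[f"p_interaction_{comp}"] = anova["p_interaction"]
                row[f"F_group_{comp}"] = anova["F_group"]
                row[f"p_group_{comp}"] = anova["p_group"]
                row[f"df2_{comp}"] = anova["df2"]
            rows.append(row)
    return pd.DataFrame(rows)


def _confounders(densities: pd.DataFrame):
    screens, ancova_rows = [], []
    density_cols = [f"density_{c}" for c in DENSITY_TEST_CLASSES]
    for region in sorted(densities["region"].unique()):
        sub = densities[densities["region"] == region]
        covs = [c for c in SCREEN_COVARIATES if c in sub.columns]
        report = confounder_screen(sub, density_cols, covs)
        screen = report.screen.copy()
        screen.insert(0, "region", region)
        screens.append(screen)
        for cls_col in density_cols:
            flagged = report.flagged.get(cls_col, [])
            for case, control in PAIRS:
                pool = sub[sub["diagnosis"].isin((case, control))]
                if pool["diagnosis"].nunique() < 2:
                    continue
                if (pool["diagnosis"] == case).sum() < 2:
                    continue
                res = ancova_adjust(pool, cls_col, "diagnosis", flagged)
                ancova_rows.append(
                    {
                        "region": region,
                        "class": cls_col.removeprefix("density_"),
                        "comparison": f"{case}_vs_{control}",
                        "adjusted": res["adjusted"],
                        "covariates": ",".join(res["covariates"]),
                        "F": res["F"],
                        "p": res["p"],
                        "n": res["n"],
                    }
                )
    return pd.concat(screens, ignore_index=True), pd.DataFrame(ancova_rows)


def _exclusion_reanalysis(densities, fs_counts, config):
    try:
        kept = exclusion_filter(densities, config.pmi_max, config.refrigeration_max)
    except DataError:
        return pd.DataFrame(), pd.DataFrame()
    tests = _density_tests(kept)
    if not tests.empty:
        tests.insert(0, "analysis", "exclusion_matched")
    windows = _window_stats(kept, fs_counts, config)
    if not windows.empty:
        windows.insert(0, "analysis", "exclusion_matched")
    return tests, windows


def _subgroups(densities: pd.DataFrame) -> pd.DataFrame:
    frames = []
    density_cols = [f"density_{c}" for c in DENSITY_TEST_CLASSES]
    for region in sorted(densities["region"].unique()):
        sub = densities[
            (densities["region"] == region) & (densities["diagnosis"] != "control")
        ]
        if len(sub) < 3 or "disease_duration" not in sub.columns:
            continue
        table = subgroup_correlations(sub, density_cols)
        table.insert(0, "region", region)
        frames.append(table)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _categoricals(densities: pd.DataFrame) -> pd.DataFrame:
    frames = []
    density_cols = [f"density_{c}" for c in DENSITY_TEST_CLASSES]
    for region in sorted(densities["region"].unique()):
        sub = densities[densities["region"] == region]
        table = categorical_factor_tests(sub, density_cols)
        if not table.empty:
            table.insert(0, "region", region)
            frames.append(table)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def _config_dict(config: RunConfig) -> dict:
    """Analysis-identity view of the config: output location excluded."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in sorted(obj.items(), key=str)}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    out = convert(config)
    out.pop("out_dir", None)
    out.pop("log_level", None)
    return out


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _write_results(results: dict, config: RunConfig, dataset: CohortDataset) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in results.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.10g")
    import scipy
    import sklearn
    import statsmodels

    manifest = {
        "config": _config_dict(config),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "n_samples": len(dataset),
        "versions": {
            "nucleoflow": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
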