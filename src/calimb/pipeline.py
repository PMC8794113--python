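"""Full study orchestration: imbalance sweep x calibration method x threshold policy.

For each imbalance ratio the pipeline obtains a (calibration-fit, test) score
pair — synthetic by default, or externally supplied files — fits every
requested calibration method on the fit split, scores miscalibration (ECE
with Wilson CIs and non-overlap significance against the uncalibrated
baseline), selects the best method per ratio by minimum ECE, and evaluates
classification metrics at the default 0.5 threshold and at PR-guided optimal
thresholds.  Results are plain dataframes written as one CSV per table
analogue plus per-cell reliability and PR-curve files and a JSON manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrators import CalibrationMap, apply_map, fit_map, is_monotone
from .exceptions import InvalidSpecError
from .io import read_scores
from .metrics import (
    NA,
    MetricsReport,
    ReliabilityTable,
    ThresholdResult,
    is_na,
    metrics_at,
    pr_optimal_threshold,
    reliability,
)
from .stats import WilsonInterval, metric_interval, significant_difference
from .synthetic import DatasetSpec, DistortionSpec, ScoreSet, build_study_sets

_METHOD_ORDER = ("platt", "beta", "spline")


@dataclass
class ExperimentConfig:
    """Declarative description of one full study run."""

    ratios: tuple[float, ...] = (0.2, 0.6, 1.0)
    methods: tuple[str, ...] = _METHOD_ORDER
    n_bins: int = 10
    n_negative: int = 1000
    test_negative: int = 300
    test_ratio: float | str = 1.0
    distortion: DistortionSpec = field(default_factory=DistortionSpec)
    separability: float | None = None  # overrides distortion.separability if set
    seed: int = 0
    level: float = 0.95
    select_threshold_on: str = "test"  # "test" (replicates the source workflow) or "cal"
    reliability_mode: str = "positive_fraction"
    external_scores: dict | None = None  # {ratio: {"cal": path, "test": path}}

    def __post_init__(self) -> None:
        if not self.ratios:
            raise InvalidSpecError("ratios must be non-empty")
        if not self.methods:
            raise InvalidSpecError("methods must be non-empty")
        bad = [m for m in self.methods if m not in _METHOD_ORDER]
        if bad:
            raise InvalidSpecError(f"unknown methods {bad}; choose from {_METHOD_ORDER}")
        if self.select_threshold_on not in ("test", "cal"):
            raise InvalidSpecError("select_threshold_on must be 'test' or 'cal'")
        if self.separability is not None:
            self.distortion = DistortionSpec(
                family=self.distortion.family,
                params=self.distortion.params,
                separability=float(self.separability),
            )
            self.separability = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        dist = raw.pop("distortion", None)
        if dist is not None:
            raw["distortion"] = DistortionSpec(
                family=dist.get("family", "identity"),
                params=dist.get("params", {}) or {},
                separability=float(dist.get("separability", 1.0)),
            )
        for key in ("ratios", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_manifest_dict(self) -> dict:
        doc = asdict(self)
        doc["distortion"] = {
            "family": self.distortion.family,
            "params": dict(self.distortion.params),
            "separability": self.distortion.separability,
        }
        return doc


@dataclass
class ExperimentResult:
    """Machine-readable analogues of the study's result tables and figures."""

    config: ExperimentConfig
    ece_table: pd.DataFrame
    best_method: dict[float, str]
    metrics_default: pd.DataFrame
    thresholds: pd.DataFrame
    metrics_optimal: pd.DataFrame
    reliability_tables: dict[tuple[float, str], ReliabilityTable]
    pr_curves: dict[tuple[float, str], pd.DataFrame]
    maps: dict[tuple[float, str], CalibrationMap] = field(default_factory=dict)


def _obtain_sets(config: ExperimentConfig) -> dict[float, tuple[ScoreSet, ScoreSet]]:
    if config.external_scores:
        out = {}
        for ratio in config.ratios:
            try:
                paths = config.external_scores[ratio]
                out[ratio] = (read_scores(paths["cal"]), read_scores(paths["test"]))
            except Exception as exc:
                raise InvalidSpecError(f"ratio {ratio}: {exc}") from exc
        return out
    base = DatasetSpec(
        n_negative=config.n_negative,
        ratio=config.ratios[0],
        seed=config.seed,
        test_negative=config.test_negative,
        test_ratio=config.test_ratio,
    )
    return build_study_sets(base, list(config.ratios), config.distortion)


def _fit_seed(master_seed: int, ratio_index: int) -> int:
    # reserved child 3i+2 of the master SeedSequence (see build_study_sets)
    child = np.random.SeedSequence(master_seed).spawn(3 * (ratio_index + 1))[3 * ratio_index + 2]
    return int(child.generate_state(1)[0])


def _metric_row(
    ratio: float,
    variant: str,
    method: str,
    report: MetricsReport,
    n: int,
    level: float,
) -> dict:
    ci = metric_interval(report.mcc, "mcc", n, level)
    return {
        "ratio": ratio,
        "variant": variant,
        "method": method,
        "threshold": report.counts.threshold,
        "accuracy": report.accuracy,
        "auprc": report.auprc,
        "precision": report.precision,
        "recall": report.recall,
        "f_score": report.f_score,
        "mcc": report.mcc,
        "mcc_lower": ci.lower,
        "mcc_upper": ci.upper,
        "tp": report.counts.tp,
        "fp": report.counts.fp,
        "tn": report.counts.tn,
        "fn": report.counts.fn,
        "n": n,
    }


def _mcc_interval_for_comparison(report: MetricsReport, n: int, level: float) -> WilsonInterval:
    """Interval used in calibrated-vs-uncalibrated significance calls.

    An NA MCC (degenerate all-one-class prediction) is compared as a
    zero-association classifier: estimate 0 with its Wilson interval at the
    same n.  The reported value itself stays NA.
    """
    value = 0.0 if is_na(report.mcc) else report.mcc
    return metric_interval(value, "mcc", n, level)


def _pr_curve_frame(result: ThresholdResult) -> pd.DataFrame:
    return pd.DataFrame(result.curve, columns=["threshold", "precision", "recall", "f_score"])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full study; fully deterministic given the config's master seed."""
    sets = _obtain_sets(config)
    ece_rows: list[dict] = []
    default_rows: list[dict] = []
    threshold_rows: list[dict] = []
    optimal_rows: list[dict] = []
    best_method: dict[float, str] = {}
    rel_tables: dict[tuple[float, str], ReliabilityTable] = {}
    pr_curves: dict[tuple[float, str], pd.DataFrame] = {}
    maps: dict[tuple[float, str], CalibrationMap] = {}

    for i, ratio in enumerate(config.ratios):
        cal, test = sets[ratio]
        n_test = len(test)
        degenerate = len(np.unique(test.labels)) < 2 or len(np.unique(cal.labels)) < 2
        if degenerate:
            warnings.warn(f"ratio {ratio}: one-class split, reporting NA cells", stacklevel=2)
            ece_rows.append(
                {
                    "ratio": ratio,
                    "method": "baseline",
                    "ece": NA,
                    "ece_lower": NA,
                    "ece_upper": NA,
                    "n": n_test,
                    "significant_vs_baseline": False,
                }
            )
            continue

        baseline_rel = reliability(test.labels, test.scores, config.n_bins, config.reliability_mode)
        rel_tables[(ratio, "baseline")] = baseline_rel
        baseline_ci = metric_interval(baseline_rel.ece, "ece", n_test, config.level)
        ece_rows.append(
            {
                "ratio": ratio,
                "method": "baseline",
                "ece": baseline_rel.ece,
                "ece_lower": baseline_ci.lower,
                "ece_upper": baseline_ci.upper,
                "n": n_test,
                "significant_vs_baseline": False,
            }
        )

        per_method_ece: dict[str, float] = {}
        for method in config.methods:
            cmap = fit_map(
                method,
                cal.scores,
                cal.labels,
                seed=_fit_seed(config.seed, i),
            )
            maps[(ratio, method)] = cmap
            calibrated = apply_map(cmap, test.scores)
            rel = reliability(test.labels, calibrated, config.n_bins, config.reliability_mode)
            rel_tables[(ratio, method)] = rel
            ci = metric_interval(rel.ece, "ece", n_test, config.level)
            significant, _ = significant_difference(ci, baseline_ci)
            per_method_ece[method] = rel.ece
            ece_rows.append(
                {
                    "ratio": ratio,
                    "method": method,
                    "ece": rel.ece,
                    "ece_lower": ci.lower,
                    "ece_upper": ci.upper,
                    "n": n_test,
                    "significant_vs_baseline": significant,
                }
            )

        # bolding rule: min point-estimate ECE, ties by fixed method order
        best = min(
            per_method_ece,
            key=lambda m: (per_method_ece[m], _METHOD_ORDER.index(m)),
        )
        best_method[ratio] = best
        best_map = maps[(ratio, best)]
        calibrated_test = apply_map(best_map, test.scores)

        # Table-4 analogue: default threshold 0.5
        uncal_default = metrics_at(test.labels, test.scores, 0.5)
        cal_default = metrics_at(test.labels, calibrated_test, 0.5)
        row_u = _metric_row(ratio, "uncalibrated", "", uncal_default, n_test, config.level)
        row_c = _metric_row(ratio, "calibrated", best, cal_default, n_test, config.level)
        sig, _ = significant_difference(
            _mcc_interval_for_comparison(cal_default, n_test, config.level),
            _mcc_interval_for_comparison(uncal_default, n_test, config.level),
        )
        row_u["significant_vs_uncalibrated"] = False
        row_c["significant_vs_uncalibrated"] = sig
        default_rows += [row_u, row_c]

        # Table-5 analogue: PR-guided thresholds
        if config.select_threshold_on == "cal":
            select_uncal = (cal.labels, cal.scores)
            select_cal = (cal.labels, apply_map(best_map, cal.scores))
        else:
            select_uncal = (test.labels, test.scores)
            select_cal = (test.labels, calibrated_test)
        uncal_pr = pr_optimal_threshold(*select_uncal)
        cal_pr = pr_optimal_threshold(*select_cal)
        pr_curves[(ratio, "uncalibrated")] = _pr_curve_frame(uncal_pr)
        pr_curves[(ratio, "calibrated")] = _pr_curve_frame(cal_pr)
        threshold_rows += [
            {
                "ratio": ratio,
                "variant": "uncalibrated",
                "method": "",
                "optimal_threshold": uncal_pr.optimal_threshold,
                "f_at_optimum": uncal_pr.f_at_optimum,
                "selected_on": config.select_threshold_on,
            },
            {
                "ratio": ratio,
                "variant": "calibrated",
                "method": best,
                "optimal_threshold": cal_pr.optimal_threshold,
                "f_at_optimum": cal_pr.f_at_optimum,
                "selected_on": config.select_threshold_on,
            },
        ]

        # Table-6 analogue: metrics at the PR-guided thresholds
        uncal_opt = metrics_at(test.labels, test.scores, uncal_pr.optimal_threshold)
        cal_opt = metrics_at(test.labels, calibrated_test, cal_pr.optimal_threshold)
        row_u = _metric_row(ratio, "uncalibrated", "", uncal_opt, n_test, config.level)
        row_c = _metric_row(ratio, "calibrated", best, cal_opt, n_test, config.level)
        sig, _ = significant_difference(
            _mcc_interval_for_comparison(cal_opt, n_test, config.level),
            _mcc_interval_for_comparison(uncal_opt, n_test, config.level),
        )
        row_u["significant_vs_uncalibrated"] = False
        row_c["significant_vs_uncalibrated"] = sig
        optimal_rows += [row_u, row_c]

    return ExperimentResult(
        config=config,
        ece_table=pd.DataFrame(ece_rows),
        best_method=best_method,
        metrics_default=pd.DataFrame(default_rows),
        thresholds=pd.DataFrame(threshold_rows),
        metrics_optimal=pd.DataFrame(optimal_rows),
        reliability_tables=rel_tables,
        pr_curves=pr_curves,
        maps=maps,
    )


def compare_thresholds(result: ExperimentResult) -> pd.DataFrame:
    """Headline contrast: calibrated-vs-uncalibrated MCC at 0.5 and at PR thresholds."""
    rows = []
    for policy, frame in (
        ("default_0.5", result.metrics_default),
        ("pr_guided", result.metrics_optimal),
    ):
        if frame.empty:
            warnings.warn(f"missing cells for policy {policy}", stacklevel=2)
            continue
        for ratio, grp in frame.groupby("ratio", sort=False):
            cal_row = grp[grp.variant == "calibrated"]
            uncal_row = grp[grp.variant == "uncalibrated"]
            if cal_row.empty or uncal_row.empty:
                warnings.warn(f"ratio {ratio}: incomplete {policy} cells", stacklevel=2)
                continue
            mcc_c = float(cal_row.mcc.iloc[0])
            mcc_u = float(uncal_row.mcc.iloc[0])
            rows.append(
                {
                    "ratio": ratio,
                    "policy": policy,
                    "mcc_calibrated": mcc_c,
                    "mcc_uncalibrated": mcc_u,
                    "delta_mcc": NA if (is_na(mcc_c) or is_na(mcc_u)) else mcc_c - mcc_u,
                    "significant": bool(cal_row.significant_vs_uncalibrated.iloc[0]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report files


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    # repr-format floats so written values round-trip bit-exactly
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="NA")


def _rel_frame(table: ReliabilityTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin": np.arange(1, table.n_bins + 1),
            "lower_edge": table.edges[:-1],
            "upper_edge": table.edges[1:],
            "count": table.counts,
            "mean_pred": table.mean_pred,
            "accuracy": table.accuracy,
        }
    )


def _cell_name(ratio: float, tag: str) -> str:
    return f"ratio{ratio:g}_{tag}.csv"


def write_report(result: ExperimentResult, out_dir: str | Path) -> None:
    """Write every table analogue, per-cell curves and a run manifest."""
    out = Path(out_dir)
    (out / "reliability").mkdir(parents=True, exist_ok=True)
    (out / "pr_curves").mkdir(parents=True, exist_ok=True)
    _write_csv(result.ece_table, out / "ece_table.csv")
    _write_csv(result.metrics_default, out / "metrics_default.csv")
    _write_csv(result.thresholds, out / "thresholds.csv")
    _write_csv(result.metrics_optimal, out / "metrics_optimal.csv")
    _write_csv(compare_thresholds(result), out / "threshold_contrast.csv")
    for (ratio, tag), table in result.reliability_tables.items():
        _write_csv(_rel_frame(table), out / "reliability" / _cell_name(ratio, tag))
    for (ratio, tag), frame in result.pr_curves.items():
        _write_csv(frame, out / "pr_curves" / _cell_name(ratio, tag))
    manifest = {
        "package": "calimb",
        "version": __version__,
        "config": result.config.to_manifest_dict(),
        "best_method": {str(k): v for k, v in result.best_method.items()},
        "monotone_maps": {
            f"{ratio:g}/{method}": is_monotone(cmap)
            for (ratio, method), cmap in result.maps.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Load a report CSV with the NA token mapped back to NaN."""
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True, float_precision="round_trip")
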