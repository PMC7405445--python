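"""End-to-end pipeline: phantom -> extract -> perturb -> robustness ->
filter cascade -> benchmark -> transfer -> report.

The run is driven by one serializable :class:`RunConfig`; every stochastic
step derives its seed from ``config.seed``, so a rerun with the same config
reproduces every artifact.  Completed stages are detected by their output
files and skipped on resume.

Three feature-set conditions are carried through benchmarking and transfer,
mirroring the study design: all features without robustness screening
("nonrobust"), robustness-screened features under the sequence prior
("robust_sequence"), and robustness-screened features under the hand-picked
intensity-free prior ("robust_handpicked").
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bench import (
    Combo,
    OSBoundary,
    PriorSpec,
    drop_report,
    run_benchmark_grid,
    transfer_evaluate,
)
from .core import FeatureID, FeatureTable
from .features import DiscretizationSpec, ExtractionConfig, extract_feature_table
from .perturb import PlanConfig, apply_plan, build_plan, calibrate_noise_levels
from .phantom import (
    PhantomParams,
    generate_cohort,
    multi_center_profile,
    multi_center_survival,
    single_center_profile,
    single_center_survival,
)
from .robustness import (
    FilterConfig,
    RobustnessConfig,
    RobustnessReport,
    filter_cascade,
    robust_feature_set,
    robustness_report,
)
from .select import SELECTOR_METHODS

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully YAML-serializable.

    Defaults give a desk-scale smoke run (small grid, two sequences, three
    regions, two or three perturbation levels per family) that exercises
    every stage end to end on one CPU.
    """

    out_dir: str = "robustrad_run"
    seed: int = 0
    # cohorts
    n_train: int = 12
    n_test: int = 12
    n_robustness: int = 8  # subset of the training cohort used for ICC
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    # extraction
    sequences: tuple[str, ...] = ("T1c", "FLAIR")
    regions: tuple[str, ...] = ("cet", "wt", "core")
    n_bins: int = 80
    # perturbation plan (level counts per family; ranges stay the defaults)
    n_noise: int = 2
    n_binning: int = 2
    n_interrater: int = 2
    n_voxelsize: int = 2
    n_slicespacing: int = 2
    n_kspace: int = 3
    # robustness / cascade
    icc_threshold: float = 0.85
    sweep_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.95)
    cindex_min: float = 0.55
    # benchmarking
    boundary_days: tuple[float, ...] = (365.0,)
    selectors: tuple[str, ...] = ("MRMR", "RELF", "FSCR")
    models: tuple[str, ...] = ("logistic", "random_forest", "adaboost")
    selector_k: int = 8
    n_splits: int = 10

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _extraction_config(config: RunConfig) -> ExtractionConfig:
    return ExtractionConfig(
        sequences=config.sequences,
        regions=config.regions,
        discretization=DiscretizationSpec(mode="fixed_bin_count", n_bins=config.n_bins),
    )


def _fid_str(fid: FeatureID) -> str:
    return "|".join(fid)


def run_pipeline(config: RunConfig) -> Path:
    """Execute (or resume) the full pipeline; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }, indent=2))

    # --- cohorts (deterministic; regenerated on resume) -------------------
    params = PhantomParams(grid_shape=config.grid_shape)
    train, train_clin = generate_cohort(
        config.n_train, params, single_center_profile(), single_center_survival(),
        seed=config.seed,
    )
    test, test_clin = generate_cohort(
        config.n_test, params, multi_center_profile(), multi_center_survival(),
        seed=config.seed + 1,
    )
    train_clin.to_csv(out / "clinical_train.csv", index=False)
    test_clin.to_csv(out / "clinical_test.csv", index=False)

    ext = _extraction_config(config)

    # --- extraction -------------------------------------------------------
    feats_train_path = out / "features_train.csv"
    feats_test_path = out / "features_test.csv"
    if feats_train_path.exists():
        table_train = FeatureTable.read_csv(feats_train_path)
        log.info("extract: resumed from %s", feats_train_path)
    else:
        table_train = extract_feature_table(train, ext)
        table_train.to_csv(feats_train_path)
    if feats_test_path.exists():
        table_test = FeatureTable.read_csv(feats_test_path)
    else:
        table_test = extract_feature_table(test, ext)
        table_test.to_csv(feats_test_path)

    # --- perturbation + robustness ---------------------------------------
    robustness_path = out / "robustness.csv"
    if robustness_path.exists():
        report = RobustnessReport(pd.read_csv(robustness_path), config.n_robustness)
        log.info("robustness: resumed from %s", robustness_path)
    else:
        subset = train[: config.n_robustness]
        sigmas = calibrate_noise_levels(subset, config.n_noise, config.sequences)
        plan = build_plan(
            PlanConfig(
                n_noise=config.n_noise,
                n_binning=config.n_binning,
                n_interrater=config.n_interrater,
                n_voxelsize=config.n_voxelsize,
                n_slicespacing=config.n_slicespacing,
                n_kspace=config.n_kspace,
                sequences=config.sequences,
                regions=config.regions,
                base_seed=config.seed,
            ),
            noise_sigmas=sigmas,
        )
        with open(out / "plan.yaml", "w") as fh:
            yaml.safe_dump(
                [dataclasses.asdict(s) for s in plan.specs], fh, sort_keys=False
            )
        variants = apply_plan(subset, plan, ext)
        for family, tables in variants.items():
            for idx, t in enumerate(tables):
                t.to_csv(out / f"features_{family}_{idx:02d}.csv")
        original = variants[next(iter(variants))][0]
        report = robustness_report(original, variants)
        report.to_csv(robustness_path)

    sweep = {
        thr: len(robust_feature_set(report, RobustnessConfig(icc_threshold=thr)))
        for thr in config.sweep_thresholds
    }
    robust_ids = robust_feature_set(
        report, RobustnessConfig(icc_threshold=config.icc_threshold)
    )
    (out / "robustness_summary.json").write_text(json.dumps({
        "icc_threshold": config.icc_threshold,
        "n_features": len(report.feature_ids()),
        "n_robust": len(robust_ids),
        "threshold_sweep": {f"{t:g}": n for t, n in sweep.items()},
        "binning_exempt": True,
    }, indent=2))

    # --- filter cascade ---------------------------------------------------
    os_train = train_clin["os_days"].to_numpy()
    os_test = test_clin["os_days"].to_numpy()
    fconfig = FilterConfig(cindex_min=config.cindex_min)
    surviving, counts = filter_cascade(table_train, os_train, robust_ids, fconfig)
    (out / "cascade.json").write_text(json.dumps({
        "stage_counts": counts,
        "surviving": [_fid_str(f) for f in surviving],
    }, indent=2))

    # --- benchmark + transfer per feature-set condition -------------------
    boundaries = [OSBoundary(d) for d in config.boundary_days]
    conditions = {
        "nonrobust": (None, PriorSpec("none")),
        "robust_sequence": (robust_ids, PriorSpec("sequence")),
        "robust_handpicked": (robust_ids, PriorSpec("handpicked")),
    }
    bench_rows = []
    transfers: dict[str, list] = {}
    best_summary: dict[str, dict] = {}
    for name, (ids, prior) in conditions.items():
        tbl = table_train if ids is None else table_train.subset(
            [f for f in table_train.feature_ids if f in ids]
        )
        if tbl.n_features == 0:
            log.warning("condition %s: empty feature set, skipped", name)
            continue
        results, best = run_benchmark_grid(
            tbl, os_train, boundaries,
            selectors=config.selectors, models=config.models, prior=prior,
            seed=config.seed, selector_k=config.selector_k, n_splits=config.n_splits,
        )
        results.insert(0, "feature_set", name)
        bench_rows.append(results)
        transfers[name] = []
        best_summary[name] = {}
        for label, (combo, _res) in best.items():
            boundary = next(b for b in boundaries if b.label == label)
            cand = prior.apply(tbl.feature_ids)
            tr = transfer_evaluate(
                tbl.subset(cand), os_train,
                table_test, os_test, combo, boundary,
                seed=config.seed, n_splits=config.n_splits,
            )
            transfers[name].append(tr)
            best_summary[name][label] = {
                "selector": combo.selector.method,
                "model": combo.model_id,
                "auc_single": tr.single.auc,
                "auc_multi": tr.multi.auc,
                "auc_drop": tr.drop["auc"],
            }
    pd.concat(bench_rows, ignore_index=True).to_csv(out / "bench.csv", index=False)
    (out / "best_combos.json").write_text(json.dumps(best_summary, indent=2))
    drop_report(transfers).to_csv(out / "drops.csv", index=False)

    write_report(out)
    return out


def write_report(artifact_dir: str | Path) -> Path:
    """Human-readable markdown summary assembled from the stage artifacts."""
    out = Path(artifact_dir)
    summary = json.loads((out / "robustness_summary.json").read_text())
    cascade = json.loads((out / "cascade.json").read_text())
    best = json.loads((out / "best_combos.json").read_text())
    drops = pd.read_csv(out / "drops.csv")

    lines = ["# robustrad run report", ""]
    lines += ["## Robustness screening", ""]
    lines += [f"- features tested: {summary['n_features']}"]
    lines += [
        f"- robust at CI lower bound >= {summary['icc_threshold']}: "
        f"{summary['n_robust']}"
    ]
    lines += [
        "- gray-level binning perturbations are reported but exempt from "
        "exclusion decisions"
    ]
    lines += ["", "Threshold sweep (robust-set size):", ""]
    for thr, n in summary["threshold_sweep"].items():
        lines.append(f"- threshold {thr}: {n}")
    lines += ["", "## Filter cascade", ""]
    for stage, n in cascade["stage_counts"].items():
        lines.append(f"- {stage}: {n}")
    lines += ["", "## Best selector x model per boundary", ""]
    for feature_set, per_boundary in best.items():
        for label, info in per_boundary.items():
            lines.append(
                f"- {feature_set} @ {label}: {info['selector']} + {info['model']} "
                f"(AUC single {info['auc_single']:.2f}, multi {info['auc_multi']:.2f}, "
                f"drop {info['auc_drop']:.2f})"
            )
    lines += ["", "## Transfer drops (mean across boundaries)", ""]
    mean_rows = drops[drops["boundary"] == "mean"]
    for row in mean_rows.itertuples(index=False):
        lines.append(f"- {row.feature_set} / {row.metric}: {row.drop:+.3f}")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
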