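"""End-to-end study orchestration.

A study run takes a sample manifest plus per-sample chromatograms, reduces
every chromatogram with one shared crop/threshold, computes the baseline
characteristics table, and then executes each configured two-arm comparison
(arms are manifest query predicates) through the cross-validated
feature-selection + three-classifier harness, reporting the best classifier
per comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crossval, evaluate, synthetic
from .cohort_stats import baseline_table, baseline_table_frame
from .crossval import DEFAULT_SPECS, ClassifierSpec
from .errors import ComparisonError, SchemaError
from .preprocess import CropWindow, FeatureMatrix, build_matrix, calibrate_threshold

logger = logging.getLogger("vocims")

__all__ = ["ComparisonSpec", "RunConfig", "resolve_comparison", "run_study",
           "write_bundle", "load_run_config"]


@dataclass(frozen=True)
class ComparisonSpec:
    """Two study arms defined as manifest query predicates.

    Arm A is labeled 0 and arm B is labeled 1; the arms must be disjoint and
    non-empty on the manifest they are applied to.
    """

    name: str
    predicate_a: str
    predicate_b: str


@dataclass
class RunConfig:
    crop: CropWindow | None = None  # None = full grid
    threshold: float | None = None  # None = calibrate to target_nnz
    target_nnz: int = 10_000
    n_folds: int = 10
    k: int = 100
    classifiers: tuple[ClassifierSpec, ...] = DEFAULT_SPECS
    seed: int = 0
    comparisons: tuple[ComparisonSpec, ...] = ()


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML/JSON key-value file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    crop = CropWindow(**raw["crop"]) if raw.get("crop") else None
    comparisons = tuple(
        ComparisonSpec(c["name"], c["predicate_a"], c["predicate_b"])
        for c in raw.get("comparisons", [])
    )
    classifiers = tuple(
        ClassifierSpec(name=c) if isinstance(c, str) else ClassifierSpec(**c)
        for c in raw.get("classifiers", [s.name for s in DEFAULT_SPECS])
    )
    return RunConfig(
        crop=crop,
        threshold=raw.get("threshold"),
        target_nnz=int(raw.get("target_nnz", 10_000)),
        n_folds=int(raw.get("n_folds", 10)),
        k=int(raw.get("k", 100)),
        classifiers=classifiers,
        seed=int(raw.get("seed", 0)),
        comparisons=comparisons,
    )


def resolve_comparison(
    manifest: pd.DataFrame, spec: ComparisonSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Return (row positions, binary labels) for a comparison's two arms."""
    try:
        arm_a = manifest.query(spec.predicate_a)
        arm_b = manifest.query(spec.predicate_b)
    except Exception as exc:  # pandas raises many types for bad queries
        raise ComparisonError(f"{spec.name}: bad predicate ({exc})") from exc
    overlap = arm_a.index.intersection(arm_b.index)
    if len(overlap):
        raise ComparisonError(f"{spec.name}: arms overlap on {len(overlap)} samples")
    if arm_a.empty or arm_b.empty:
        raise ComparisonError(
            f"{spec.name}: empty arm (A={len(arm_a)}, B={len(arm_b)})"
        )
    idx = np.concatenate([
        manifest.index.get_indexer(arm_a.index),
        manifest.index.get_indexer(arm_b.index),
    ])
    labels = np.concatenate([np.zeros(len(arm_a), dtype=int), np.ones(len(arm_b), dtype=int)])
    logger.info("comparison %s: arm A n=%d, arm B n=%d", spec.name, len(arm_a), len(arm_b))
    return idx, labels


def _config_snapshot(config: RunConfig, tau: float, crop: CropWindow) -> dict:
    snap = {
        "crop": vars(crop),
        "threshold": float(tau),
        "n_folds": config.n_folds,
        "k": config.k,
        "seed": config.seed,
        "classifiers": [s.name for s in config.classifiers],
        "comparisons": [vars(c) for c in config.comparisons],
    }
    digest = hashlib.sha256(json.dumps(snap, sort_keys=True).encode()).hexdigest()[:16]
    snap["config_hash"] = digest
    return snap


def run_study(
    manifest: pd.DataFrame,
    grids: Mapping[str, synthetic.ChromatogramGrid],
    config: RunConfig,
) -> dict:
    """Execute preprocessing, baseline table and every configured comparison.

    Degenerate comparisons (empty arm, class too small to cross-validate)
    become explicit ``skipped`` entries rather than failures.  The returned
    bundle is a plain JSON-serializable dict, fully deterministic given the
    config seed.
    """
    missing = [s for s in manifest["sample_id"] if s not in grids]
    if missing:
        raise SchemaError(f"chromatograms missing for samples: {missing[:5]}")
    samples = [(str(s), grids[str(s)]) for s in manifest["sample_id"]]

    crop_window = config.crop or CropWindow.full(samples[0][1])
    cropped = [(sid, _crop_safe(g, crop_window)) for sid, g in samples]
    if config.threshold is not None:
        tau = float(config.threshold)
    else:
        tau = calibrate_threshold(cropped, config.target_nnz)
        logger.info("calibrated threshold: %.4g (target nnz %d)", tau, config.target_nnz)
    features = build_matrix(samples, crop_window, tau)

    baseline_rows = baseline_table(manifest, "delivery_class") \
        if manifest["delivery_class"].nunique() > 1 else []

    snapshot = _config_snapshot(config, tau, crop_window)
    comparisons_out = []
    for spec in config.comparisons:
        comparisons_out.append(
            _run_comparison(manifest, features, spec, config, snapshot)
        )

    return {
        "config": snapshot,
        "n_samples": int(len(manifest)),
        "n_features": int(features.n_features),
        "median_nnz": float(np.median((features.matrix > 0).sum(axis=1))),
        "baseline": [
            {
                "variable": r.variable,
                "test": r.test,
                "p_value": r.p_value,
                "n_missing": r.n_missing,
                "summaries": r.summaries,
            }
            for r in baseline_rows
        ],
        "comparisons": comparisons_out,
    }


def _crop_safe(grid, window):
    from .preprocess import crop

    return crop(grid, window)


def _run_comparison(
    manifest: pd.DataFrame,
    features: FeatureMatrix,
    spec: ComparisonSpec,
    config: RunConfig,
    snapshot: dict,
) -> dict:
    try:
        idx, labels = resolve_comparison(manifest, spec)
    except ComparisonError as exc:
        logger.warning("skipping %s: %s", spec.name, exc)
        return {"name": spec.name, "skipped": True, "reason": str(exc)}
    n_per_arm = (int((labels == 0).sum()), int((labels == 1).sum()))
    min_class = min(n_per_arm)
    # small arms (study subgroups run down to n=5-17) cannot fill 10 stratified
    # folds; fall back to the largest feasible fold count and record it
    n_folds = min(config.n_folds, min_class)
    if n_folds < 2:
        return {
            "name": spec.name,
            "skipped": True,
            "reason": f"arm too small for CV (n={min_class})",
            "n_per_arm": list(n_per_arm),
        }
    sub = features.matrix[idx]
    result = crossval.run_cv(
        sub,
        labels,
        specs=config.classifiers,
        n_folds=n_folds,
        k=config.k,
        seed=config.seed,
    )
    reports = [
        evaluate.evaluate_probabilities(name, probs, labels)
        for name, probs in result.probabilities.items()
    ]
    best = evaluate.select_best_classifier(reports)
    return {
        "name": spec.name,
        "skipped": False,
        "n_per_arm": list(n_per_arm),
        "n_folds_used": int(n_folds),
        "seed": config.seed,
        "config_hash": snapshot["config_hash"],
        "best": best.to_row(),
        "all_classifiers": [r.to_row() for r in reports],
        "fold_selected": [s.tolist() for s in result.fold_selected],
    }


def write_bundle(bundle: dict, outdir) -> Path:
    """Serialize the bundle deterministically (sorted keys, fixed layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(bundle, sort_keys=True, indent=1) + "\n")
    rows = [
        {
            "comparison": c["name"],
            "skipped": c.get("skipped", False),
            **({} if c.get("skipped") else _flatten_best(c["best"], c["n_per_arm"])),
        }
        for c in bundle["comparisons"]
    ]
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "comparisons.csv", index=False)
    if bundle["baseline"]:
        baseline_table_frame(
            [_RowShim(**r) for r in bundle["baseline"]]
        ).to_csv(outdir / "baseline.csv", index=False)
    return report_path


@dataclass
class _RowShim:
    variable: str
    test: str
    p_value: float | None
    n_missing: int
    summaries: dict


def _flatten_best(best: dict, n_per_arm: list) -> dict:
    return {
        "classifier": best["classifier"],
        "p_value": best["p_value"],
        "auc": best["auc"],
        "auc_ci_lo": best["auc_ci_95"][0],
        "auc_ci_hi": best["auc_ci_95"][1],
        "sensitivity": best["sensitivity"],
        "specificity": best["specificity"],
        "ppv": best["ppv"],
        "npv": best["npv"],
        "n_arm_a": n_per_arm[0],
        "n_arm_b": n_per_arm[1],
    }
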