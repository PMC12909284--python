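"""Evaluation metrics, the end-to-end pipeline, and sweep experiments.

AUC is computed by the rank statistic (Mann-Whitney, ties averaged), which
equals trapezoidal integration of the ROC curve.  Threshold metrics
(accuracy, precision, recall, F1, confusion counts) are taken at a decision
threshold tau on the provided scores/probabilities.  Sweeps rerun the full
generate -> preprocess -> select -> train -> evaluate pipeline over a grid
on one axis (sample size, feature count, optimizer iterations, or injected
noise level) and emit a tidy results table.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from .elm import ElmConfig, fit_elm, predict
from .gso import SwarmConfig
from .preprocessing import build_design_matrix, encode_boolean, smote_oversample
from .synthetic import GeneratorConfig, generate, generate_planted, noise_inject

logger = logging.getLogger("gsoelm.evaluation")

SWEEP_AXES = ("sample_size", "feature_count", "iterations", "noise_level")


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic, ties averaged."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size != scores.size:
        raise ValueError("y_true and scores must have the same length")
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """(threshold, FPR, TPR, precision, recall) at every unique score."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = max(int(y_true.sum()), 1)
    n_neg = max(int((1 - y_true).sum()), 1)
    rows = []
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int(np.sum(pred & (y_true == 1)))
        fp = int(np.sum(pred & (y_true == 0)))
        precision = tp / max(tp + fp, 1)
        rows.append({"threshold": float(thr), "fpr": fp / n_neg, "tpr": tp / n_pos,
                     "precision": precision, "recall": tp / n_pos})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Metric panel for one evaluation: threshold metrics, AUC, confusion."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float  # nan when only one class is present in the truth
    tp: int
    fp: int
    tn: int
    fn: int
    n: int
    roc: pd.DataFrame | None = None
    score_summary: dict = field(default_factory=dict)
    seconds: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "n": self.n, "score_summary": self.score_summary,
            "seconds": self.seconds,
        }


def compute_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    tau: float = 0.5,
    with_roc: bool = True,
) -> EvaluationReport:
    """Full metric panel from ranking scores and a decision threshold.

    ``scores`` may be any monotone ranking value (probabilities in the
    pipeline); labels are 1 iff score >= tau.  F1 follows the zero
    convention when precision + recall = 0.  With a single-class truth the
    AUC is undefined and reported as NaN (with a warning); threshold
    metrics are still returned.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size != scores.size:
        raise ValueError("y_true and scores must have the same length")
    pred = (scores >= tau).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    n = y_true.size
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    try:
        auc = auc_score(y_true, scores)
    except ValueError:
        logger.warning("AUC undefined (single-class truth); reporting NaN")
        auc = float("nan")
    score_summary = {
        "min": float(scores.min()), "max": float(scores.max()),
        "mean": float(scores.mean()),
        "mean_positive": float(scores[y_true == 1].mean()) if tp + fn else float("nan"),
        "mean_negative": float(scores[y_true == 0].mean()) if tn + fp else float("nan"),
    }
    return EvaluationReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, auc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn, n=n,
        roc=roc_points(y_true, scores) if with_roc else None,
        score_summary=score_summary,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stages of one end-to-end run.

    The master ``seed`` derives every stage seed (generation, outer split,
    swarm, ELM, folds), so a run is reproducible bit for bit.  Inner
    cross-validation refits preprocessing per fold when the data are a raw
    table and no noise injection / SMOTE intervened; otherwise the inner
    folds reuse the outer-training-fitted encoding.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scaler: str = "minmax"
    test_fraction: float = 0.2
    smote: bool = False
    use_selection: bool = True
    group_level: bool = True
    swarm: SwarmConfig = field(default_factory=lambda: SwarmConfig(G=10, T_max=10))
    fitness: "FitnessSpec" = None  # default constructed in __post_init__
    elm: ElmConfig = field(default_factory=ElmConfig)
    tune: bool = False
    tune_swarm: SwarmConfig | None = None
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        from .selection import FitnessSpec
        if self.fitness is None:
            self.fitness = FitnessSpec(k_folds=3)


def run_pipeline(config: PipelineConfig, table: pd.DataFrame | None = None,
                 schema=None) -> dict:
    """Generate (or accept) data, split, select, train, and evaluate.

    Returns a dict with the holdout EvaluationReport, the trained model,
    the fitted feature schema, the selected mask and (optionally) the
    selection/tuning artifacts.
    """
    t0 = time.perf_counter()
    seed = config.seed
    if table is None:
        ds = generate(dataclasses.replace(config.generator, seed=seed))
        table, schema = ds.table, ds.schema
    elif schema is None:
        from .synthetic import TODDLER_SCHEMA
        schema = TODDLER_SCHEMA
    table = table.reset_index(drop=True)
    y = _labels(table, schema)
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, stratify=y, random_state=seed + 4)
    out = _fit_and_evaluate(table, schema, y, train_idx, test_idx, config)
    out["report"].seconds = time.perf_counter() - t0
    return out


def _labels(table: pd.DataFrame, schema) -> np.ndarray:
    label = schema.label
    return np.array([encode_boolean(v, (label.true_value, label.false_value))
                     for v in table[label.name]])


def _fit_and_evaluate(table, schema, y, train_idx, test_idx,
                      config: PipelineConfig) -> dict:
    """Preprocess, select, tune, train on train_idx; score on test_idx."""
    from .selection import CVProblem, select_features, tune_hyperparameters

    seed = config.seed
    train_mask = np.zeros(len(table), dtype=bool)
    train_mask[train_idx] = True

    dm, fschema = build_design_matrix(table, schema, scaler=config.scaler,
                                      train_mask=train_mask)
    X = dm.X
    if config.noise_level > 0:
        X = noise_inject(X, config.noise_level, seed=seed + 6)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]
    if config.smote:
        X_tr, y_tr = smote_oversample(X_tr, y_tr, seed=seed + 5, schema=fschema)

    clean = config.noise_level == 0 and not config.smote
    if clean:
        problem = CVProblem(raw=table.iloc[train_idx], schema=schema,
                            scaler=config.scaler)
    else:
        problem = CVProblem(X=X_tr, y=y_tr)

    fitness_spec = dataclasses.replace(config.fitness, seed=seed + 3)
    elm_config = dataclasses.replace(config.elm, seed=seed + 2)

    selection_report = None
    mask = np.ones(X.shape[1], dtype=int)
    if config.use_selection:
        swarm = dataclasses.replace(config.swarm, seed=seed + 1)
        selection_report = select_features(
            problem, swarm, fitness_spec, elm_config,
            group_level=config.group_level)
        mask = selection_report.best_mask

    tuned = None
    scaler = config.scaler
    if config.tune:
        tune_swarm = config.tune_swarm or dataclasses.replace(
            config.swarm, seed=seed + 7)
        elm_config, scaler, tune_score, tune_trace = tune_hyperparameters(
            problem, mask, tune_swarm, elm_config, fitness_spec)
        tuned = {"config": elm_config, "scaler": scaler, "score_cv": tune_score,
                 "trace": tune_trace}
        if scaler != config.scaler and clean:
            dm, fschema = build_design_matrix(table, schema, scaler=scaler,
                                              train_mask=train_mask)
            X = dm.X
            X_tr, y_tr = X[train_idx], y[train_idx]
            X_te, y_te = X[test_idx], y[test_idx]

    model = fit_elm(X_tr, y_tr, elm_config, mask=mask.astype(bool))
    _, probs, _ = predict(model, X_te)
    report = compute_metrics(y_te, probs, tau=elm_config.tau)

    return {
        "report": report, "model": model, "schema": fschema, "mask": mask,
        "selection": selection_report, "tuned": tuned,
        "train_idx": train_idx, "test_idx": test_idx,
    }


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """One-axis sweep design: grid values and replicate count."""

    axis: str
    grid: list
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"axis must be one of {SWEEP_AXES}")
        if not self.grid:
            raise ValueError("sweep grid must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _planted_cell(n_features: int, config: PipelineConfig, seed: int) -> EvaluationReport:
    """Feature-count sweep cell on planted-signal Gaussian data."""
    from .selection import CVProblem, select_features

    X, y, _ = generate_planted(n=config.generator.n, n_features=n_features,
                               n_informative=min(5, n_features), seed=seed)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(idx, test_size=config.test_fraction,
                                           stratify=y, random_state=seed + 4)
    mask = np.ones(n_features, dtype=int)
    elm_config = dataclasses.replace(config.elm, seed=seed + 2)
    if config.use_selection:
        problem = CVProblem(X=X[train_idx], y=y[train_idx])
        report = select_features(
            problem, dataclasses.replace(config.swarm, seed=seed + 1),
            dataclasses.replace(config.fitness, seed=seed + 3), elm_config)
        mask = report.best_mask
    model = fit_elm(X[train_idx], y[train_idx], elm_config, mask=mask.astype(bool))
    _, probs, _ = predict(model, X[test_idx])
    return compute_metrics(y[test_idx], probs, tau=elm_config.tau)


def _learning_curve_rows(spec: SweepSpec, base: PipelineConfig,
                         n_test: int = 400) -> list[dict]:
    """Sample-size sweep as a proper learning curve.

    Per replicate one super-sample is generated; each grid value trains on
    a *nested* subset of the same training pool and is scored on the same
    held-out test block.  Common random numbers make accuracy differences
    across grid values reflect the training size, not dataset resampling.
    """
    n_max = int(max(spec.grid))
    rows = []
    for rep in range(spec.replicates):
        rep_seed = (spec.seed + 1000 * rep) % (2**31 - 1)
        ds = generate(dataclasses.replace(base.generator, n=n_max + n_test,
                                          seed=rep_seed))
        y = _labels(ds.table, ds.schema)
        perm = np.random.default_rng(rep_seed + 1).permutation(len(y))
        test_idx, pool = perm[:n_test], perm[n_test:]
        for value in spec.grid:
            config = dataclasses.replace(base, seed=rep_seed)
            t0 = time.perf_counter()
            try:
                train_idx = pool[: int(value)]
                report = _fit_and_evaluate(ds.table, ds.schema, y, train_idx,
                                           test_idx, config)["report"]
                rows.append({
                    "axis": spec.axis, "value": value, "replicate": rep,
                    "accuracy": report.accuracy, "auc": report.auc,
                    "f1": report.f1, "precision": report.precision,
                    "recall": report.recall,
                    "seconds": time.perf_counter() - t0, "status": "ok",
                })
            except Exception as exc:  # pragma: no cover - defensive path
                logger.error("sweep cell sample_size=%r replicate %d failed: %s",
                             value, rep, exc)
                rows.append({
                    "axis": spec.axis, "value": value, "replicate": rep,
                    "accuracy": np.nan, "auc": np.nan, "f1": np.nan,
                    "precision": np.nan, "recall": np.nan,
                    "seconds": time.perf_counter() - t0,
                    "status": f"error: {exc}",
                })
    return rows


def run_sweep(spec: SweepSpec, base: PipelineConfig) -> pd.DataFrame:
    """Run the pipeline over a grid on one axis; tidy long-format results.

    Per-cell failures are logged and marked in the ``status`` column rather
    than aborting the sweep.  Fully reproducible under the spec seed.
    """
    if spec.axis == "sample_size":
        return pd.DataFrame(_learning_curve_rows(spec, base))
    rows = []
    for value in spec.grid:
        for rep in range(spec.replicates):
            tag = zlib.crc32(f"{spec.axis}:{value}".encode())  # process-stable
            cell_seed = (spec.seed + 1000 * rep + tag % 997) % (2**31 - 1)
            config = dataclasses.replace(base, seed=cell_seed)
            t0 = time.perf_counter()
            try:
                if spec.axis == "noise_level":
                    config = dataclasses.replace(config, noise_level=float(value))
                    report = run_pipeline(config)["report"]
                elif spec.axis == "iterations":
                    config = dataclasses.replace(
                        config, swarm=dataclasses.replace(config.swarm, T_max=int(value)))
                    report = run_pipeline(config)["report"]
                else:  # feature_count
                    report = _planted_cell(int(value), config, cell_seed)
                rows.append({
                    "axis": spec.axis, "value": value, "replicate": rep,
                    "accuracy": report.accuracy, "auc": report.auc,
                    "f1": report.f1, "precision": report.precision,
                    "recall": report.recall,
                    "seconds": time.perf_counter() - t0, "status": "ok",
                })
            except Exception as exc:  # pragma: no cover - defensive path
                logger.error("sweep cell %s=%r replicate %d failed: %s",
                             spec.axis, value, rep, exc)
                rows.append({
                    "axis": spec.axis, "value": value, "replicate": rep,
                    "accuracy": np.nan, "auc": np.nan, "f1": np.nan,
                    "precision": np.nan, "recall": np.nan,
                    "seconds": time.perf_counter() - t0, "status": f"error: {exc}",
                })
    return pd.DataFrame(rows)
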