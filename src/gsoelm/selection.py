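"""Wrapper feature selection and hyperparameter tuning.

A candidate feature subset is scored by training the ELM on the masked
columns inside stratified k-fold cross-validation and penalizing subset
size:

    J(m) = Score_CV(m) - alpha * ||m||_1 / d,

so that, between two masks of equal cross-validated score, the sparser one
wins.  The glowworm swarm searches the continuous space whose positions
decode to masks (sigmoid transfer + threshold), either over all encoded
columns or over original-variable groups so one-hot blocks are kept whole.
The same swarm machinery refines ELM hyperparameters (hidden size L on
[20, 200], ridge coefficient on a log grid over [1e-6, 1e2], activation and
scaling choice) through a unit-interval decode map.

Leakage discipline: when the problem is built from a raw table, imputation
and scaling statistics are refit on each fold's training part before the
fold is scored (category vocabularies are pinned up front as table
structure, so mask indices mean the same columns in every fold).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .elm import ElmConfig, ElmModel, fit_elm, predict
from .evaluation import auc_score
from .gso import SwarmConfig, SwarmTrace, gso_optimize, position_to_mask
from .preprocessing import (
    FeatureSchema, RawSchema, build_design_matrix, encode_boolean,
    SCALER_KINDS,
)

logger = logging.getLogger("gsoelm.selection")

METRICS = ("auc", "balanced_accuracy", "accuracy")


@dataclass
class FitnessSpec:
    """Cross-validated fitness settings: metric, folds, sparsity weight.

    ``penalty_form`` selects between the default subtractive penalty
    J = Score - alpha k/d and an alternative score-per-size ratio
    J = Score / (1 + alpha k/d); both are strictly decreasing in the
    selected count at fixed score.
    """

    alpha_sparsity: float = 0.1
    metric: str = "auc"
    k_folds: int = 5
    penalty_form: str = "subtractive"  # subtractive | ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_sparsity <= 1:
            raise ValueError("alpha_sparsity must lie in [0, 1]")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.penalty_form not in ("subtractive", "ratio"):
            raise ValueError("penalty_form must be 'subtractive' or 'ratio'")


class CVProblem:
    """Leakage-free per-fold access to design matrices.

    Built either from a plain numeric (X, y) pair, or from a raw mixed-type
    table plus its role schema — in which case every fold refits imputers
    and scalers on the fold's training rows.  Category vocabularies are
    pinned from the full table so the encoded column layout (and therefore
    mask indexing) is identical across folds.
    """

    def __init__(
        self,
        X: np.ndarray | None = None,
        y: np.ndarray | None = None,
        raw: pd.DataFrame | None = None,
        schema: RawSchema | None = None,
        scaler: str = "minmax",
    ):
        self.scaler = scaler
        if raw is not None:
            if schema is None:
                raise ValueError("raw tables need a role schema")
            self.raw = raw.reset_index(drop=True)
            # pin vocabularies (table structure) so fold widths agree
            _, fitted = build_design_matrix(self.raw, schema, scaler=scaler)
            pinned = [
                dataclasses.replace(
                    c, vocabulary=fitted.vocabularies.get(c.name, c.vocabulary))
                for c in schema.columns
            ]
            self.schema = RawSchema(pinned)
            self.feature_schema = fitted
            label = schema.label
            self.y = np.array([
                encode_boolean(v, (label.true_value, label.false_value))
                for v in self.raw[label.name]
            ])
            self.X = None
        else:
            if X is None or y is None:
                raise ValueError("provide either (X, y) or (raw, schema)")
            self.raw = None
            self.schema = None
            self.feature_schema = None
            self.X = np.asarray(X, dtype=float)
            self.y = np.asarray(y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def d(self) -> int:
        if self.X is not None:
            return self.X.shape[1]
        return self.feature_schema.n_features

    @property
    def groups(self) -> dict[str, list[int]]:
        if self.feature_schema is not None:
            return self.feature_schema.groups
        return {f"x{j}": [j] for j in range(self.d)}

    def fold(
        self,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
        scaler: str | None = None,
        return_schema: bool = False,
    ):
        """Training and validation matrices with statistics fit on train only."""
        if self.X is not None:
            out = (self.X[train_idx], self.y[train_idx],
                   self.X[val_idx], self.y[val_idx])
            return (*out, None) if return_schema else out
        mask = np.zeros(self.n, dtype=bool)
        mask[train_idx] = True
        dm, fitted = build_design_matrix(
            self.raw, self.schema, scaler=scaler or self.scaler, train_mask=mask)
        out = (dm.X[train_idx], self.y[train_idx], dm.X[val_idx], self.y[val_idx])
        return (*out, fitted) if return_schema else out


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    """Stratified fold assignment; one reseed if a fold comes out single-class."""
    for attempt, s in enumerate((seed, seed + 1)):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=s)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[val])) == 2 for _, val in folds):
            return folds
        if attempt == 0:
            logger.warning("single-class validation fold; re-stratifying once")
    raise ValueError("cannot build stratified folds with both classes present")


def cross_validated_score(
    problem: CVProblem,
    mask: np.ndarray,
    elm_config: ElmConfig,
    spec: FitnessSpec,
    scaler: str | None = None,
) -> float:
    """Mean validation metric of the masked ELM over stratified k folds."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no columns")
    folds = _stratified_folds(problem.y, spec.k_folds, spec.seed)
    scores = []
    for train_idx, val_idx in folds:
        X_tr, y_tr, X_val, y_val = problem.fold(train_idx, val_idx, scaler=scaler)
        model = fit_elm(X_tr, y_tr, elm_config, mask=mask)
        _, probs, labels = predict(model, X_val)
        if spec.metric == "auc":
            scores.append(auc_score(y_val, probs))
        elif spec.metric == "balanced_accuracy":
            scores.append(balanced_accuracy_score(y_val, labels))
        else:
            scores.append(accuracy_score(y_val, labels))
    return float(np.mean(scores))


@dataclass
class FitnessResult:
    """Sparsity-penalized wrapper fitness of one mask."""

    J: float
    score_cv: float
    penalty: float
    n_selected: int


def fitness(
    problem: CVProblem,
    mask: np.ndarray,
    spec: FitnessSpec,
    elm_config: ElmConfig,
    scaler: str | None = None,
) -> FitnessResult:
    """J = Score_CV - alpha ||m||_1 / d; an empty mask scores -1 untrained."""
    mask = np.asarray(mask).astype(bool)
    d = mask.size
    k = int(mask.sum())
    if k == 0:
        return FitnessResult(J=-1.0, score_cv=float("nan"), penalty=0.0, n_selected=0)
    score = cross_validated_score(problem, mask, elm_config, spec, scaler=scaler)
    penalty = spec.alpha_sparsity * k / d
    if spec.penalty_form == "ratio":
        J = score / (1.0 + penalty)
    else:
        J = score - penalty
    return FitnessResult(J=J, score_cv=score, penalty=penalty, n_selected=k)


def expand_group_mask(u: np.ndarray, schema: FeatureSchema | dict[str, list[int]]) -> np.ndarray:
    """Expand a per-group mask to encoded columns: whole blocks on or off."""
    groups = schema.groups if isinstance(schema, FeatureSchema) else schema
    u = np.asarray(u).astype(int)
    if u.size != len(groups):
        raise ValueError(f"group mask length {u.size} != group count {len(groups)}")
    d = max(i for cols in groups.values() for i in cols) + 1
    m = np.zeros(d, dtype=int)
    for flag, cols in zip(u, groups.values()):
        if flag:
            m[cols] = 1
    return m


@dataclass
class SelectionReport:
    """Best mask found plus stability information across runs."""

    best_mask: np.ndarray
    best_J: float
    best_score_cv: float
    feature_names: list[str]
    frequencies: np.ndarray               # per encoded column, over runs
    group_frequencies: dict[str, float]
    run_masks: list[np.ndarray]
    run_J: list[float]
    run_scores: list[float]
    traces: list[SwarmTrace]

    @property
    def mean_J(self) -> float:
        return float(np.mean(self.run_J))

    @property
    def sd_J(self) -> float:
        return float(np.std(self.run_J))

    def frequency_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "frequency": self.frequencies,
            "in_best_mask": self.best_mask.astype(int),
        })

    def to_dict(self) -> dict:
        return {
            "best_mask": self.best_mask.astype(int).tolist(),
            "best_bitstring": "".join(map(str, self.best_mask.astype(int))),
            "selected_features": [n for n, m in zip(self.feature_names, self.best_mask) if m],
            "best_J": self.best_J,
            "best_score_cv": self.best_score_cv,
            "mean_J": self.mean_J,
            "sd_J": self.sd_J,
            "mean_score_cv": float(np.mean(self.run_scores)),
            "sd_score_cv": float(np.std(self.run_scores)),
            "frequencies": dict(zip(self.feature_names, self.frequencies.tolist())),
            "group_frequencies": self.group_frequencies,
            "n_runs": len(self.run_masks),
        }


def select_features(
    problem: CVProblem,
    swarm_config: SwarmConfig,
    fitness_spec: FitnessSpec,
    elm_config: ElmConfig,
    group_level: bool = False,
    n_runs: int = 1,
) -> SelectionReport:
    """GSO wrapper search for the best feature mask.

    Column-level search has dimension d; group-level search works in the
    (much smaller) space of original variables, expanding each group mask to
    whole encoded blocks.  Fitness results are memoized per mask, since the
    swarm frequently revisits masks.  With ``n_runs`` > 1 the search repeats
    under independent seeds and per-feature selection frequencies over the
    per-run best masks are reported.
    """
    groups = problem.groups
    d_search = len(groups) if group_level else problem.d
    names = problem.feature_schema.encoded_columns if problem.feature_schema is not None \
        else [f"x{j}" for j in range(problem.d)]

    run_masks, run_J, run_scores, traces = [], [], [], []
    best_overall = None

    for run in range(n_runs):
        run_swarm = dataclasses.replace(swarm_config, seed=swarm_config.seed + run)
        cache: dict[bytes, FitnessResult] = {}
        counts = np.zeros(d_search)
        repair_rng = np.random.default_rng(run_swarm.seed + 104729)

        def evaluate(unit_mask: np.ndarray) -> FitnessResult:
            mask = expand_group_mask(unit_mask, groups) if group_level else unit_mask
            key = mask.astype(np.int8).tobytes()
            if key not in cache:
                cache[key] = fitness(problem, mask, fitness_spec, elm_config)
            return cache[key]

        def objective(s: np.ndarray) -> float:
            unit = position_to_mask(s, run_swarm.tau)
            counts[unit.astype(bool)] += 1
            return evaluate(unit).J

        best_pos, best_J_run, trace = gso_optimize(objective, d_search, run_swarm)
        unit = position_to_mask(best_pos, run_swarm.tau)
        if unit.sum() == 0:
            # repair: enable the most-frequently-selected unit so far (or random)
            k = int(np.argmax(counts)) if counts.sum() > 0 else int(repair_rng.integers(d_search))
            unit = np.zeros(d_search, dtype=int)
            unit[k] = 1
            logger.info("empty best mask repaired by enabling unit %d", k)
        result = evaluate(unit)
        mask = expand_group_mask(unit, groups) if group_level else unit

        run_masks.append(mask.astype(int))
        run_J.append(result.J)
        run_scores.append(result.score_cv)
        traces.append(trace)
        if best_overall is None or result.J > best_overall[1].J:
            best_overall = (mask.astype(int), result)

    best_mask, best_result = best_overall
    freq = np.mean(np.vstack(run_masks), axis=0)
    group_freq = {
        name: float(np.mean([m[cols].max() for m in run_masks]))
        for name, cols in groups.items()
    }
    return SelectionReport(
        best_mask=best_mask, best_J=best_result.J, best_score_cv=best_result.score_cv,
        feature_names=names, frequencies=freq, group_frequencies=group_freq,
        run_masks=run_masks, run_J=run_J, run_scores=run_scores, traces=traces,
    )


# ---------------------------------------------------------------------------
# Hyperparameter refinement
# ---------------------------------------------------------------------------

def decode_hyper_position(p: np.ndarray) -> dict:
    """Decode unit-interval coordinates to (L, lam, activation, scaling).

    p has four entries, clipped to [0, 1]: L = round(20 + 180 p0),
    lam = 10^(-6 + 8 p1), activation sigmoid/rbf by p2 < 0.5, scaling one
    of four kinds by quartile of p3.
    """
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    L = int(round(20 + 180 * p[0]))
    lam = 10.0 ** (-6.0 + 8.0 * p[1])
    activation = "sigmoid" if p[2] < 0.5 else "rbf"
    scaling = SCALER_KINDS[min(3, int(4 * p[3]))]
    return {"L": L, "lam": lam, "activation": activation, "scaling": scaling}


def tune_hyperparameters(
    problem: CVProblem,
    mask: np.ndarray,
    swarm_config: SwarmConfig,
    base_config: ElmConfig,
    fitness_spec: FitnessSpec | None = None,
    tune_scaling: bool = True,
) -> tuple[ElmConfig, str, float, SwarmTrace]:
    """GSO refinement of (L, lam, activation, scaling) under a fixed mask.

    Swarm positions on [-1, 1]^4 map to unit-interval coordinates via
    (s + 1)/2 before decoding.  Scaling choice only has an effect for raw
    table problems (array problems arrive pre-scaled); pass
    ``tune_scaling=False`` to hold it fixed.  Returns the best decoded
    configuration, the chosen scaler kind, its cross-validated score, and
    the swarm trace.
    """
    if fitness_spec is None:
        fitness_spec = FitnessSpec()
    mask = np.asarray(mask).astype(bool)
    cache: dict[tuple, float] = {}

    def decoded_score(dec: dict) -> float:
        scaler = dec["scaling"] if (tune_scaling and problem.raw is not None) else None
        key = (dec["L"], round(np.log10(dec["lam"]), 6), dec["activation"], scaler)
        if key not in cache:
            cfg = dataclasses.replace(base_config, L=dec["L"], lam=dec["lam"],
                                      activation=dec["activation"])
            cache[key] = cross_validated_score(problem, mask, cfg, fitness_spec,
                                               scaler=scaler)
        return cache[key]

    def objective(s: np.ndarray) -> float:
        return decoded_score(decode_hyper_position((np.asarray(s) + 1.0) / 2.0))

    best_pos, best_score, trace = gso_optimize(objective, 4, swarm_config)
    dec = decode_hyper_position((best_pos + 1.0) / 2.0)
    best_cfg = dataclasses.replace(base_config, L=dec["L"], lam=dec["lam"],
                                   activation=dec["activation"])
    scaler = dec["scaling"] if (tune_scaling and problem.raw is not None) else problem.scaler
    return best_cfg, scaler, float(best_score), trace


def tune_hidden_weights(
    problem: CVProblem,
    mask: np.ndarray,
    L: int,
    swarm_config: SwarmConfig,
    base_config: ElmConfig,
    fitness_spec: FitnessSpec | None = None,
) -> tuple[dict[str, np.ndarray], float, SwarmTrace]:
    """Opt-in swarm tuning of the hidden weights W, b themselves.

    The search dimension is L*(d'+1), which is only tractable for small toy
    cases (L <= 10); the default pipeline tunes (L, lam, activation,
    scaling) instead.  Positions are used directly as weight values, scaled
    by the init half-width a.
    """
    if L > 10:
        raise ValueError("weight-space tuning is restricted to L <= 10 toy cases")
    if fitness_spec is None:
        fitness_spec = FitnessSpec()
    mask = np.asarray(mask).astype(bool)
    d_sel = int(mask.sum())
    cfg = dataclasses.replace(base_config, L=L, activation="sigmoid")

    def unpack(s: np.ndarray) -> dict[str, np.ndarray]:
        s = np.asarray(s, dtype=float) * cfg.a
        return {"W": s[: L * d_sel].reshape(L, d_sel), "b": s[L * d_sel:]}

    folds = _stratified_folds(problem.y, fitness_spec.k_folds, fitness_spec.seed)

    def objective(s: np.ndarray) -> float:
        params = unpack(s)
        scores = []
        for train_idx, val_idx in folds:
            X_tr, y_tr, X_val, y_val = problem.fold(train_idx, val_idx)
            model = fit_elm(X_tr, y_tr, cfg, mask=mask, hidden_params=params)
            _, probs, _ = predict(model, X_val)
            scores.append(auc_score(y_val, probs))
        return float(np.mean(scores))

    best_pos, best_score, trace = gso_optimize(objective, L * (d_sel + 1), swarm_config)
    return unpack(best_pos), float(best_score), trace


def selection_stability(
    reports: list[SelectionReport] | list[np.ndarray],
    feature_names: list[str] | None = None,
) -> dict:
    """Aggregate selection frequencies and performance spread across runs."""
    if len(reports) < 2:
        raise ValueError("stability needs at least 2 runs")
    if isinstance(reports[0], SelectionReport):
        masks = [r.best_mask for r in reports]
        Js = [r.best_J for r in reports]
        scores = [r.best_score_cv for r in reports]
        names = feature_names or reports[0].feature_names
    else:
        masks = [np.asarray(m).astype(int) for m in reports]
        Js, scores = [], []
        names = feature_names or [f"x{j}" for j in range(masks[0].size)]
    freq = np.mean(np.vstack(masks), axis=0)
    out = {
        "frequencies": pd.DataFrame({"feature": names, "frequency": freq}),
    }
    if Js:
        out["J_mean"], out["J_sd"] = float(np.mean(Js)), float(np.std(Js))
        out["score_mean"], out["score_sd"] = float(np.mean(scores)), float(np.std(scores))
    return out
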