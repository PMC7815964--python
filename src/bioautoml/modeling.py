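"""The experiment harness: stratified partitioning, repeated stratified
10-fold cross-validated grid tuning over a registry of classification
algorithms, holdout evaluation and model ranking.

The contract throughout is leakage safety and determinism:

* the holdout split is made once, before any tuning, and touched exactly
  once — after the winning hyperparameters are fixed;
* preprocessing is refit inside every CV fold on that fold's training part;
* every source of randomness is derived from a master seed by stable
  hashing of (resample, algorithm, purpose), so adding an algorithm to a
  run does not perturb any other algorithm's results, and serial and
  parallel execution produce identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import pickle
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset_io import Dataset
from .errors import BioAutoMLError, IntegrityError, ModelError
from .metrics import METRIC_NAMES, MetricSet, mean_metric_sets, score_metrics
from .mulset import (
    Resample,
    compute_signatures,
    extract_submatrix,
    filter_resamples,
    generate_resamples,
    whole_dataset_resample,
)
from .preprocess import (
    DEFAULT_CORR_THRESHOLD,
    DEFAULT_STEPS,
    PreprocessPlan,
    apply_preprocess,
    fit_preprocess,
    normalize_steps,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT = "bioautoml-model"
MODEL_FORMAT_VERSION = 1


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary string-able parts (always < 2**31)."""
    token = "\x1f".join(str(p) for p in parts)
    digest = hashlib.sha256(token.encode("utf-8")).hexdigest()
    return int(digest[:8], 16) % (2**31)


# ---------------------------------------------------------------------------
# Algorithm registry
# ---------------------------------------------------------------------------

def _build_estimator(algorithm_id: str, params: dict, seed: int, n_samples: int, n_features: int):
    """Instantiate the native estimator for a registry algorithm."""
    p = dict(params)
    if algorithm_id == "sda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=p.get("shrinkage", "auto"))
    if algorithm_id == "hdda":
        return QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 0.5))
    if algorithm_id == "svmLinear":
        # Platt-scaled linear SVM; ensemble=False keeps a single refit model
        return CalibratedClassifierCV(
            SVC(kernel="linear", C=p.get("C", 1.0), random_state=seed),
            method="sigmoid",
            cv=min(5, max(2, n_samples // 10)),
            ensemble=False,
        )
    if algorithm_id == "pcaNNet":
        n_comp = min(int(p.get("n_components", 8)), n_features, max(1, n_samples - 1))
        return Pipeline(
            [
                ("pca", PCA(n_components=n_comp, random_state=seed)),
                (
                    "nnet",
                    MLPClassifier(
                        hidden_layer_sizes=(int(p.get("hidden", 5)),),
                        alpha=1e-3,
                        max_iter=500,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if algorithm_id == "logitBoost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            n_estimators=int(p.get("n_estimators", 50)),
            random_state=seed,
        )
    if algorithm_id == "naiveBayes":
        return GaussianNB(var_smoothing=p.get("var_smoothing", 1e-9))
    if algorithm_id == "rf":
        return RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 100)),
            max_features=p.get("max_features", "sqrt"),
            random_state=seed,
        )
    if algorithm_id == "knn":
        return KNeighborsClassifier(n_neighbors=int(p.get("n_neighbors", 5)))
    if algorithm_id == "treebag":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=int(p.get("n_estimators", 25)),
            random_state=seed,
        )
    if algorithm_id == "gbm":
        return GradientBoostingClassifier(
            n_estimators=int(p.get("n_estimators", 100)),
            max_depth=int(p.get("max_depth", 2)),
            random_state=seed,
        )
    if algorithm_id == "nnet":
        return MLPClassifier(
            hidden_layer_sizes=(int(p.get("hidden", 8)),),
            alpha=p.get("alpha", 1e-3),
            max_iter=500,
            random_state=seed,
        )
    raise BioAutoMLError(f"unknown algorithm {algorithm_id!r}")


#: default hyperparameter grids (kept small; each list is a tuning axis)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "sda": {"shrinkage": ["auto", 0.1, 0.5]},
    "hdda": {"reg_param": [0.1, 0.5, 0.9]},
    "svmLinear": {"C": [0.25, 1.0, 4.0]},
    "pcaNNet": {"hidden": [3, 5]},
    "logitBoost": {"n_estimators": [25, 50]},
    "naiveBayes": {"var_smoothing": [1e-9, 1e-6]},
    "rf": {"max_features": ["sqrt", 0.5]},
    "knn": {"n_neighbors": [5, 7, 9]},
    "treebag": {"n_estimators": [25, 50]},
    "gbm": {"max_depth": [2, 3]},
    "nnet": {"hidden": [4, 8]},
}

REGISTRY: tuple[str, ...] = tuple(DEFAULT_GRIDS)


@dataclass(frozen=True)
class AlgorithmSpec:
    """An algorithm and its tuning grid.

    ``hyperparameter_grid`` maps a parameter name to candidate values; the
    Cartesian product of the lists is evaluated.  ``selection_metric`` names
    the CV metric maximised during tuning (AUROC by default; prAUC is
    recommended for strongly unbalanced data).
    """

    algorithm_id: str
    hyperparameter_grid: dict[str, list] | None = None
    selection_metric: str = "auroc"

    def grid_points(self) -> list[dict]:
        grid = self.hyperparameter_grid
        if grid is None:
            grid = DEFAULT_GRIDS.get(self.algorithm_id, {})
        if not grid:
            return [{}]
        names = list(grid)
        combos = itertools.product(*(grid[n] for n in names))
        return [dict(zip(names, c)) for c in combos]


def resolve_algorithms(specs) -> list[AlgorithmSpec]:
    """Accept algorithm ids or AlgorithmSpecs; validate against the registry."""
    out = []
    for s in specs:
        spec = AlgorithmSpec(algorithm_id=s) if isinstance(s, str) else s
        if spec.algorithm_id not in REGISTRY:
            raise BioAutoMLError(
                f"unknown algorithm {spec.algorithm_id!r}; registry: {sorted(REGISTRY)}"
            )
        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# Partitioning and CV folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionSpec:
    """Stratified train/holdout split: per-class train counts are
    round(class_count * train_fraction), clamped so both classes appear in
    both splits whenever class counts permit."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise BioAutoMLError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan (10 folds x 3 repeats by default)."""

    n_folds: int = 10
    n_repeats: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise BioAutoMLError("n_folds must be >= 2")


def partition(dataset: Dataset, spec: PartitionSpec) -> tuple[Dataset, Dataset]:
    """Stratified train/holdout split, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    outcome = dataset.outcome
    for label in sorted(outcome.unique()):
        members = [s for s in dataset.sample_ids if outcome.loc[s] == label]
        if len(members) < 2:
            raise BioAutoMLError(
                f"class {label!r} has {len(members)} sample(s); at least 2 required"
            )
        n_train = int(round(len(members) * spec.train_fraction))
        n_train = min(max(n_train, 1), len(members) - 1)  # both splits non-empty per class
        perm = rng.permutation(len(members))
        chosen = {members[i] for i in perm[:n_train]}
        train_ids.extend(s for s in members if s in chosen)
        test_ids.extend(s for s in members if s not in chosen)
    # keep dataset row order within each split
    order = {s: i for i, s in enumerate(dataset.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return dataset.select(sample_ids=train_ids), dataset.select(sample_ids=test_ids)


def make_folds(train: Dataset, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Positional (train_idx, validation_idx) pairs for every fold x repeat.

    The fold count is reduced to the minority-class count when the latter is
    smaller, so every fold keeps at least one sample of each class.
    """
    y = train.y()
    min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
    n_folds = min(plan.n_folds, max(2, min_class))
    folds = []
    for rep in range(plan.n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=derive_seed(plan.seed, "rep", rep)
        )
        folds.extend((tr, va) for tr, va in skf.split(np.zeros(len(y)), y))
    return folds


# ---------------------------------------------------------------------------
# Training, evaluation, results
# ---------------------------------------------------------------------------

@dataclass
class ModelHandle:
    """A fitted model plus everything needed to score new data."""

    algorithm_id: str
    estimator: Any
    plan: PreprocessPlan
    feature_names: list[str]
    classes: tuple[str, str]  # (negative, positive)
    class_order: list[str]    # estimator.classes_ as strings

    def predict_scores(self, data: Dataset) -> np.ndarray:
        """Positive-class probabilities for each row of *data* (raw scale)."""
        prepared = apply_preprocess(self.plan, data)
        X = prepared.values[self.plan.retained].to_numpy()
        proba = self.estimator.predict_proba(X)
        pos_idx = self.class_order.index(self.classes[1])
        return proba[:, pos_idx]


@dataclass
class ModelResult:
    """Everything measured for one algorithm on one resample."""

    algorithm_id: str
    resample_id: str
    cv_metrics: MetricSet
    cv_dispersion: MetricSet
    cv_fold_metrics: list[MetricSet]
    holdout_metrics: MetricSet
    best_hyperparameters: dict
    model_handle: ModelHandle | None
    importances: Any = None  # ImportanceTable, filled by the features module
    n_train: int = 0
    n_test: int = 0
    seed: int = 0
    elapsed_seconds: float = 0.0


def _fit_silently(estimator, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        estimator.fit(X, y)
    return estimator


def tune_and_train(
    train: Dataset,
    alg: AlgorithmSpec,
    cv: CVPlan,
    plan_steps=DEFAULT_STEPS,
    seed: int = 0,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> tuple[ModelHandle, MetricSet, MetricSet, list[MetricSet], dict]:
    """Grid search by repeated stratified CV, then refit on the full training split.

    For every grid point the metrics are averaged over all fold evaluations,
    with preprocessing refit inside each fold on the fold's training part.
    The winner maximises the selection metric (ties: first grid point).
    Returns (handle, cv_mean, cv_sd, per-fold metrics of the winner, best
    hyperparameters).
    """
    if alg.selection_metric not in METRIC_NAMES:
        raise BioAutoMLError(f"unknown selection metric {alg.selection_metric!r}")
    steps = normalize_steps(plan_steps)
    folds = make_folds(train, cv)
    neg, pos = train.classes
    grid = alg.grid_points()
    candidates = []
    for gi, params in enumerate(grid):
        fold_sets: list[MetricSet] = []
        failed = False
        for fi, (tr_idx, va_idx) in enumerate(folds):
            ftr = train.iselect(tr_idx)
            fva = train.iselect(va_idx)
            plan = fit_preprocess(ftr, steps, corr_threshold=corr_threshold)
            Xtr = apply_preprocess(plan, ftr)
            Xva = apply_preprocess(plan, fva)
            est = _build_estimator(
                alg.algorithm_id,
                params,
                derive_seed(seed, "cv", gi, fi),
                Xtr.n_samples,
                Xtr.n_features,
            )
            try:
                _fit_silently(est, Xtr.values.to_numpy(), Xtr.outcome.to_numpy())
                class_order = [str(c) for c in est.classes_]
                proba = est.predict_proba(Xva.values.to_numpy())
                scores = proba[:, class_order.index(pos)]
            except Exception as exc:  # noqa: BLE001 - a failing grid point is data, not a bug
                logger.warning(
                    "%s grid point %s failed on fold %d: %s", alg.algorithm_id, params, fi, exc
                )
                failed = True
                break
            fold_sets.append(score_metrics(scores, Xva.outcome.to_numpy(), pos, neg))
        if failed or not fold_sets:
            continue
        mean, sd = mean_metric_sets(fold_sets)
        candidates.append((gi, params, mean, sd, fold_sets))
    if not candidates:
        raise ModelError(f"all grid points failed for algorithm {alg.algorithm_id!r}")

    def sel(c):
        v = c[2].get(alg.selection_metric)
        return -np.inf if v is None else v

    best = max(candidates, key=lambda c: (sel(c), -c[0]))
    _, best_params, cv_mean, cv_sd, fold_sets = best

    final_plan = fit_preprocess(train, steps, corr_threshold=corr_threshold)
    prepared = apply_preprocess(final_plan, train)
    est = _build_estimator(
        alg.algorithm_id,
        best_params,
        derive_seed(seed, "final"),
        prepared.n_samples,
        prepared.n_features,
    )
    _fit_silently(est, prepared.values.to_numpy(), prepared.outcome.to_numpy())
    handle = ModelHandle(
        algorithm_id=alg.algorithm_id,
        estimator=est,
        plan=final_plan,
        feature_names=final_plan.retained,
        classes=(neg, pos),
        class_order=[str(c) for c in est.classes_],
    )
    return handle, cv_mean, cv_sd, fold_sets, best_params


def evaluate_holdout(handle: ModelHandle, test: Dataset) -> MetricSet:
    """Score the untouched holdout split with the fitted model."""
    scores = handle.predict_scores(test)
    neg, pos = handle.classes
    return score_metrics(scores, test.outcome.to_numpy(), pos, neg)


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MulsetConfig:
    """Settings for missingness-driven resample generation inside a run."""

    enabled: bool = False
    min_samples: int = 15
    min_features: int = 2
    min_test_samples: int | None = None  # applied with the partition's test fraction


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a run."""

    algorithms: list = field(default_factory=lambda: ["sda", "naiveBayes", "rf"])
    preprocess_steps: tuple[str, ...] = DEFAULT_STEPS
    partition: PartitionSpec = field(default_factory=PartitionSpec)
    cv: CVPlan = field(default_factory=CVPlan)
    mulset: MulsetConfig = field(default_factory=MulsetConfig)
    seed: int = 0
    n_jobs: int = 1
    compute_importance: bool = False
    n_permutations: int = 25
    corr_threshold: float = DEFAULT_CORR_THRESHOLD
    selection_metric: str = "auroc"


def _run_single(
    dataset: Dataset, resample: Resample, alg: AlgorithmSpec, config: ExperimentConfig
) -> ModelResult | None:
    t0 = time.perf_counter()
    seed = derive_seed(config.seed, resample.resample_id, alg.algorithm_id)
    part_seed = derive_seed(config.seed, resample.resample_id, "partition")
    try:
        if resample.feature_set == frozenset(dataset.feature_names) and set(
            resample.sample_ids
        ) == set(dataset.sample_ids):
            sub = dataset
        else:
            sub = extract_submatrix(dataset, resample)
        train, test = partition(
            sub, PartitionSpec(config.partition.train_fraction, seed=part_seed)
        )
        cv = CVPlan(
            n_folds=config.cv.n_folds,
            n_repeats=config.cv.n_repeats,
            stratified=config.cv.stratified,
            seed=derive_seed(seed, "cv"),
        )
        handle, cv_mean, cv_sd, fold_sets, best_params = tune_and_train(
            train, alg, cv, config.preprocess_steps, seed=seed,
            corr_threshold=config.corr_threshold,
        )
        holdout = evaluate_holdout(handle, test)
        importances = None
        if config.compute_importance:
            from .features import variable_importance

            importances = variable_importance(
                handle,
                train,
                method="auto",
                n_permutations=config.n_permutations,
                seed=derive_seed(seed, "importance"),
            )
        return ModelResult(
            algorithm_id=alg.algorithm_id,
            resample_id=resample.resample_id,
            cv_metrics=cv_mean,
            cv_dispersion=cv_sd,
            cv_fold_metrics=fold_sets,
            holdout_metrics=holdout,
            best_hyperparameters=best_params,
            model_handle=handle,
            importances=importances,
            n_train=train.n_samples,
            n_test=test.n_samples,
            seed=seed,
            elapsed_seconds=time.perf_counter() - t0,
        )
    except Exception as exc:  # noqa: BLE001 - one failed model must not sink the run
        logger.warning(
            "model %s on resample %s failed: %s", alg.algorithm_id, resample.resample_id, exc
        )
        return None


def plan_resamples(dataset: Dataset, config: ExperimentConfig) -> list[Resample]:
    """The resamples a run will iterate: mulset closure, or the whole table."""
    if config.mulset.enabled:
        sigs = compute_signatures(dataset)
        resamples = generate_resamples(
            sigs,
            min_samples=config.mulset.min_samples,
            min_features=config.mulset.min_features,
        )
        if config.mulset.min_test_samples is not None:
            resamples = filter_resamples(
                resamples,
                test_fraction=1 - config.partition.train_fraction,
                min_test_samples=config.mulset.min_test_samples,
            )
        return resamples
    return [whole_dataset_resample(dataset)]


def run_experiment(dataset: Dataset, config: ExperimentConfig) -> list[ModelResult]:
    """Run every algorithm on every resample; skip individual failures.

    Each (resample, algorithm) task derives its own seeds, so outputs are
    identical whether the tasks run serially or in parallel, and the same
    train/holdout split is shared by all algorithms on a given resample so
    that their models are directly comparable.
    """
    algorithms = resolve_algorithms(config.algorithms)
    if config.selection_metric != "auroc":
        algorithms = [
            AlgorithmSpec(a.algorithm_id, a.hyperparameter_grid, config.selection_metric)
            for a in algorithms
        ]
    prevalence = dataset.y().mean()
    if min(prevalence, 1 - prevalence) < 0.25 and config.selection_metric == "auroc":
        logger.warning(
            "minority-class prevalence %.2f < 0.25: AUROC can be optimistic; "
            "consider selection_metric='prauc'",
            min(prevalence, 1 - prevalence),
        )
    resamples = plan_resamples(dataset, config)
    if not resamples:
        raise BioAutoMLError("no resamples to run (check mulset minima)")
    tasks = [(r, a) for r in resamples for a in algorithms]
    if config.n_jobs == 1:
        results = [_run_single(dataset, r, a, config) for r, a in tasks]
    else:
        results = Parallel(n_jobs=config.n_jobs)(
            delayed(_run_single)(dataset, r, a, config) for r, a in tasks
        )
    results = [r for r in results if r is not None]
    if not results:
        raise BioAutoMLError("every model failed; empty result set")
    order = {r.resample_id: i for i, r in enumerate(resamples)}
    results.sort(key=lambda r: (order[r.resample_id], r.algorithm_id))
    return results


def rank_models(
    results: list[ModelResult], metric: str = "auroc", split: str = "cv"
) -> list[ModelResult]:
    """Order results by a metric, best first.

    Ties are broken by the same metric on the other split, then by
    algorithm id; undefined metrics sort last.
    """
    if split not in ("cv", "holdout"):
        raise BioAutoMLError("split must be 'cv' or 'holdout'")
    if metric not in METRIC_NAMES:
        raise BioAutoMLError(f"unknown metric {metric!r}")
    reverse = metric != "logloss"  # smaller logloss is better

    def value(ms: MetricSet):
        v = ms.get(metric)
        if v is None:
            return np.inf if not reverse else -np.inf
        return v

    def key(r: ModelResult):
        primary = r.cv_metrics if split == "cv" else r.holdout_metrics
        secondary = r.holdout_metrics if split == "cv" else r.cv_metrics
        sign = -1 if reverse else 1
        return (sign * value(primary), sign * value(secondary), r.algorithm_id)

    return sorted(results, key=key)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def results_table(results: list[ModelResult]) -> pd.DataFrame:
    """Tidy table: one row per model x metric x split."""
    rows = []
    for r in results:
        for split, ms in (("cv", r.cv_metrics), ("holdout", r.holdout_metrics)):
            for name in METRIC_NAMES:
                v = ms.get(name)
                rows.append(
                    {
                        "resample_id": r.resample_id,
                        "algorithm": r.algorithm_id,
                        "split": split,
                        "metric": name,
                        "value": np.nan if v is None else v,
                        "n_train": r.n_train,
                        "n_test": r.n_test,
                    }
                )
    return pd.DataFrame(rows)


def fold_metrics_table(results: list[ModelResult]) -> pd.DataFrame:
    """Per-fold CV metrics (for box plots): one row per model x fold x metric."""
    rows = []
    for r in results:
        for fi, ms in enumerate(r.cv_fold_metrics):
            for name in METRIC_NAMES:
                v = ms.get(name)
                rows.append(
                    {
                        "resample_id": r.resample_id,
                        "algorithm": r.algorithm_id,
                        "fold": fi,
                        "metric": name,
                        "value": np.nan if v is None else v,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(result: ModelResult, path: str | Path, fingerprint: Dataset | None = None) -> None:
    """Serialize a ModelResult with an embedded prediction fingerprint.

    ``fingerprint`` should be a few rows of raw (untransformed) data; its
    predicted scores are stored and re-verified on load, so a corrupted or
    environment-shifted artifact is detected instead of silently mis-scoring.
    """
    payload: dict[str, Any] = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "result": result,
    }
    if fingerprint is not None and result.model_handle is not None:
        payload["fingerprint_values"] = fingerprint.values
        payload["fingerprint_outcome"] = fingerprint.outcome
        payload["fingerprint_positive"] = fingerprint.positive_class
        payload["fingerprint_scores"] = result.model_handle.predict_scores(fingerprint)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> ModelResult:
    """Load a serialized ModelResult, verifying format, version and fingerprint."""
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, ImportError) as exc:
        raise IntegrityError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise IntegrityError(f"{path} is not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise IntegrityError(
            f"model format version {payload.get('version')} != supported {MODEL_FORMAT_VERSION}"
        )
    result: ModelResult = payload["result"]
    if "fingerprint_values" in payload and result.model_handle is not None:
        fp = Dataset(
            values=payload["fingerprint_values"],
            outcome=payload["fingerprint_outcome"],
            positive_class=payload["fingerprint_positive"],
        )
        got = result.model_handle.predict_scores(fp)
        if not np.allclose(got, payload["fingerprint_scores"], atol=1e-10):
            raise IntegrityError(f"prediction fingerprint mismatch in {path}")
    return result
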