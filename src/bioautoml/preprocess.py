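"""Leakage-safe preprocessing learned on the training split only.

A :class:`PreprocessPlan` stores every statistic (median, mean, sd, dropped
features) learned from a training split; applying the plan to any split —
including the untouched holdout — uses only those stored statistics, so no
information can flow from the holdout into the model.  Step order is fixed:
impute -> near-zero-variance drop -> correlated drop -> center -> scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import Dataset
from .errors import BioAutoMLError, SchemaError

logger = logging.getLogger(__name__)

#: canonical execution order of the supported steps
STEP_ORDER = ("impute_median", "drop_nzv", "drop_correlated", "center", "scale")

#: aliases accepted in configuration files (GUI-style vocabulary)
STEP_ALIASES = {
    "medianimpute": "impute_median",
    "impute": "impute_median",
    "impute_median": "impute_median",
    "nzv": "drop_nzv",
    "drop_nzv": "drop_nzv",
    "corr": "drop_correlated",
    "drop_correlated": "drop_correlated",
    "center": "center",
    "scale": "scale",
}

DEFAULT_STEPS = ("impute_median", "center", "scale")
DEFAULT_CORR_THRESHOLD = 0.9


def normalize_steps(steps) -> tuple[str, ...]:
    """Map user-facing step names onto canonical ones, in canonical order."""
    canon = []
    for s in steps:
        key = str(s).strip().lower()
        if key not in STEP_ALIASES:
            raise BioAutoMLError(f"unknown preprocessing step {s!r}")
        canon.append(STEP_ALIASES[key])
    return tuple(s for s in STEP_ORDER if s in set(canon))


@dataclass
class PreprocessPlan:
    """Per-feature statistics learned from a training split.

    ``retained`` lists the surviving features in training-data column order;
    ``dropped`` maps a removed feature to the reason it was removed.
    Features with zero training variance that survive (drop_nzv not
    requested) are centered but excluded from scaling.
    """

    steps: tuple[str, ...]
    retained: list[str]
    medians: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)
    scaled_features: list[str] = field(default_factory=list)


def fit_preprocess(
    train: Dataset,
    steps=DEFAULT_STEPS,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    corr_method: str = "pearson",
) -> PreprocessPlan:
    """Learn a preprocessing plan from the training split only."""
    if train.n_samples == 0:
        raise BioAutoMLError("training split is empty")
    steps = normalize_steps(steps)
    values = train.values.copy()
    dropped: dict[str, str] = {}
    medians: dict[str, float] = {}

    if "impute_median" in steps:
        for col in list(values.columns):
            med = values[col].median(skipna=True)
            if np.isnan(med):
                dropped[col] = "entirely missing in training split"
                logger.warning("feature %r entirely missing in train; dropped", col)
                values = values.drop(columns=[col])
            else:
                medians[col] = float(med)
                values[col] = values[col].fillna(med)

    if "drop_nzv" in steps:
        sds = values.std(ddof=1, skipna=True)
        for col in values.columns[(sds == 0) | sds.isna()]:
            dropped[col] = "zero variance"
        values = values.drop(columns=[c for c in dropped if c in values.columns])

    if "drop_correlated" in steps:
        to_drop = find_correlated(
            train.with_values(values), threshold=corr_threshold, method=corr_method
        )
        for col in to_drop:
            dropped[col] = f"|r| > {corr_threshold} with a retained feature"
        values = values.drop(columns=to_drop)

    retained = list(values.columns)
    means = {c: float(values[c].mean(skipna=True)) for c in retained}
    sds_all = values.std(ddof=1, skipna=True)
    sds = {}
    scaled = []
    if "scale" in steps:
        if train.n_samples < 2:
            raise BioAutoMLError("scaling requires at least 2 training samples")
        for c in retained:
            sd = float(sds_all[c]) if not np.isnan(sds_all[c]) else 0.0
            if sd > 0:
                sds[c] = sd
                scaled.append(c)
            else:
                # zero-variance survivor: mean-only centering
                sds[c] = 1.0
    return PreprocessPlan(
        steps=steps,
        retained=retained,
        medians={c: m for c, m in medians.items() if c in set(retained)},
        means=means,
        sds=sds,
        dropped=dropped,
        scaled_features=scaled,
    )


def apply_preprocess(plan: PreprocessPlan, data: Dataset) -> Dataset:
    """Apply a learned plan to any split using only its stored statistics."""
    missing = [c for c in plan.retained if c not in set(data.feature_names)]
    if missing:
        raise SchemaError(f"data lacks features required by the plan: {missing}")
    values = data.values[plan.retained].copy()
    if "impute_median" in plan.steps:
        for col in plan.retained:
            values[col] = values[col].fillna(plan.medians.get(col, np.nan))
    scaled = set(plan.scaled_features)
    for col in plan.retained:
        zero_var_scaled = "scale" in plan.steps and col not in scaled
        if "center" in plan.steps or zero_var_scaled:
            # zero-variance survivors under `scale` get mean-only centering
            values[col] = values[col] - plan.means[col]
        if "scale" in plan.steps and col in scaled:
            values[col] = values[col] / plan.sds[col]
    return data.with_values(values)


def invert_preprocess(plan: PreprocessPlan, data: Dataset) -> Dataset:
    """Undo centering/scaling with the stored statistics (imputation is not invertible)."""
    values = data.values[plan.retained].copy()
    scaled = set(plan.scaled_features)
    for col in plan.retained:
        zero_var_scaled = "scale" in plan.steps and col not in scaled
        if "scale" in plan.steps and col in scaled:
            values[col] = values[col] * plan.sds[col]
        if "center" in plan.steps or zero_var_scaled:
            values[col] = values[col] + plan.means[col]
    return data.with_values(values)


def find_correlated(
    dataset: Dataset,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    method: str = "pearson",
) -> list[str]:
    """Greedy removal list for highly correlated feature pairs.

    While any off-diagonal absolute correlation exceeds the threshold, the
    member of the worst pair with the larger mean absolute correlation to
    all remaining features is dropped (tie: the later column in dataset
    order).  Correlations involving a constant column are treated as 0.
    Returns feature names in drop order.
    """
    if not 0 < threshold < 1:
        raise BioAutoMLError("threshold must be in (0, 1)")
    if method not in ("pearson", "spearman"):
        raise BioAutoMLError(f"unknown correlation method {method!r}")
    if dataset.values.isna().any().any():
        raise BioAutoMLError("find_correlated requires a complete predictor grid")
    corr = dataset.values.corr(method=method).abs()
    corr = corr.fillna(0.0)  # constant columns
    np.fill_diagonal(corr.values, 0.0)
    order = {c: i for i, c in enumerate(dataset.feature_names)}
    dropped: list[str] = []
    while True:
        if corr.empty:
            break
        arr = corr.to_numpy()
        worst = np.unravel_index(np.argmax(arr), arr.shape)
        if arr[worst] <= threshold:
            break
        a, b = corr.index[worst[0]], corr.columns[worst[1]]
        mean_a = corr.loc[a].mean()
        mean_b = corr.loc[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = a if order[a] > order[b] else b
        dropped.append(victim)
        corr = corr.drop(index=victim, columns=victim)
    return dropped
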