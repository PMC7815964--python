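"""Variable-importance scoring, scaled 0-100, with cross-model aggregation.

Two routes are offered.  ``auto`` uses the model's native importance when
the algorithm family defines one: absolute coefficients for linear and
discriminant models (the inputs are standardized by the preprocessing plan,
so coefficients are comparable across features), total split-gain for tree
ensembles.  Everything else falls back to permutation importance: the mean
drop in training AUROC when one feature's column is shuffled.  Raw values
are shifted to min 0 and scaled so the maximum is 100, matching the common
display convention; the raw values are retained because min-max scaling
destroys cross-model comparability of magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import Dataset
from .errors import BioAutoMLError
from .metrics import roc_auc
from .modeling import ModelHandle, ModelResult, derive_seed
from .preprocess import apply_preprocess

logger = logging.getLogger(__name__)

#: raw importances below this are considered "no signal"
NO_SIGNAL_TOL = 1e-9

DEFAULT_N_PERMUTATIONS = 25


@dataclass
class ImportanceTable:
    """Per-feature importance for one fitted model.

    ``table`` has columns (feature, raw, score) with score in [0, 100];
    ``no_signal`` flags the degenerate case where every raw importance is
    (numerically) zero, in which case all scores are 0.
    """

    table: pd.DataFrame
    method: str  # "model_native" or "permutation"
    algorithm_id: str = ""
    no_signal: bool = False

    def scores(self) -> pd.Series:
        return self.table.set_index("feature")["score"]

    def top(self, k: int) -> list[str]:
        ordered = self.table.sort_values(
            ["score", "feature"], ascending=[False, True], kind="stable"
        )
        return ordered["feature"].head(k).tolist()


def _native_raw(handle: ModelHandle) -> np.ndarray | None:
    est = handle.estimator
    if hasattr(est, "coef_"):
        coef = np.asarray(est.coef_)
        return np.abs(coef).ravel() if coef.ndim > 1 else np.abs(coef)
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    return None


def _scale(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    shifted = raw - raw.min()
    mx = shifted.max()
    if raw.max() < NO_SIGNAL_TOL or mx <= 0:
        return np.zeros_like(raw), True
    return shifted / mx * 100.0, False


def variable_importance(
    handle: ModelHandle,
    train: Dataset,
    method: str = "auto",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> ImportanceTable:
    """Score each training feature's contribution to a fitted model.

    ``method='auto'`` prefers the model-native importance, falling back to
    permutation; ``method='permutation'`` forces the permutation route.
    Permutation importance is the mean drop in training AUROC over
    ``n_permutations`` seeded shuffles of a single feature's column; the
    per-feature random stream is derived from the feature name, so the
    result does not depend on column order.
    """
    if method not in ("auto", "permutation"):
        raise BioAutoMLError(f"unknown importance method {method!r}")
    features = handle.plan.retained
    raw = None
    used = "permutation"
    if method == "auto":
        raw = _native_raw(handle)
        if raw is not None:
            used = "model_native"
            if raw.size != len(features):
                raise BioAutoMLError(
                    "native importance length does not match the feature count"
                )
    if raw is None:
        if n_permutations < 2:
            raise BioAutoMLError("n_permutations must be >= 2")
        prepared = apply_preprocess(handle.plan, train)
        X = prepared.values[features].to_numpy()
        y = train.outcome.to_numpy()
        pos = handle.classes[1]
        pos_idx = handle.class_order.index(pos)
        _, baseline = roc_auc(
            handle.estimator.predict_proba(X)[:, pos_idx], y, pos
        )
        raw = np.zeros(len(features))
        for j, fname in enumerate(features):
            rng = np.random.default_rng(derive_seed(seed, "perm", fname))
            drops = []
            for _ in range(n_permutations):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                _, auc = roc_auc(
                    handle.estimator.predict_proba(Xp)[:, pos_idx], y, pos
                )
                drops.append(baseline - (0.5 if auc is None else auc))
            raw[j] = float(np.mean(drops))
    scores, no_signal = _scale(raw)
    if no_signal:
        logger.info("no signal: every raw importance below %.1e", NO_SIGNAL_TOL)
    table = pd.DataFrame({"feature": features, "raw": raw, "score": scores})
    return ImportanceTable(
        table=table, method=used, algorithm_id=handle.algorithm_id, no_signal=no_signal
    )


def aggregate_importance(results: list[ModelResult], top_k: int = 10) -> pd.DataFrame:
    """Summarise importances across models.

    Returns a DataFrame (feature, mean_score, n_models, top_k_count,
    best_rank) sorted by mean score descending.  A feature dropped by a
    model's preprocessing contributes no entry for that model.
    """
    tables = [r.importances for r in results if r.importances is not None]
    if not tables:
        raise BioAutoMLError("no results carry importances")
    records: dict[str, dict] = {}
    for t in tables:
        ordered = t.table.sort_values(
            ["score", "feature"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        for rank, row in ordered.iterrows():
            rec = records.setdefault(
                row["feature"],
                {"scores": [], "ranks": [], "top_k": 0},
            )
            rec["scores"].append(row["score"])
            rec["ranks"].append(rank + 1)
            if rank < top_k:
                rec["top_k"] += 1
    rows = [
        {
            "feature": f,
            "mean_score": float(np.mean(rec["scores"])),
            "n_models": len(rec["scores"]),
            "top_k_count": rec["top_k"],
            "best_rank": int(min(rec["ranks"])),
        }
        for f, rec in records.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["mean_score", "feature"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)


def importance_long_table(results: list[ModelResult]) -> pd.DataFrame:
    """One row per model x feature for TSV export."""
    rows = []
    for r in results:
        if r.importances is None:
            continue
        for _, row in r.importances.table.iterrows():
            rows.append(
                {
                    "resample_id": r.resample_id,
                    "algorithm": r.algorithm_id,
                    "feature": row["feature"],
                    "score": row["score"],
                    "raw": row["raw"],
                    "method": r.importances.method,
                }
            )
    return pd.DataFrame(rows)
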