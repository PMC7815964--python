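"""Shared fixtures and independent oracles used across the suite.

The oracles here are deliberately naive (brute-force enumeration, O(n^2)
pairwise comparison, direct summation) and independent of the package's
implementations; tests compare the fast paths against them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from bioautoml.dataset_io import Dataset


def make_dataset(values, outcome_labels, positive="case", negative="control",
                 sample_ids=None, feature_names=None) -> Dataset:
    """Build a Dataset from a 2-D array and a label sequence."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    cols = feature_names or [f"f{j + 1}" for j in range(p)]
    return Dataset(
        values=pd.DataFrame(values, index=ids, columns=cols),
        outcome=pd.Series(list(outcome_labels), index=ids, name="outcome"),
        positive_class=positive,
        negative_class=negative,
    )


def brute_force_closure(feature_sets: list[frozenset]) -> set[frozenset]:
    """All distinct non-empty intersections over non-empty subsets (oracle)."""
    out: set[frozenset] = set()
    for k in range(1, len(feature_sets) + 1):
        for subset in itertools.combinations(feature_sets, k):
            inter = frozenset.intersection(*subset)
            if inter:
                out.add(inter)
    return out


def concordance_auroc(scores, y01) -> float:
    """O(n^2) pairwise concordance AUROC with half-credit ties (oracle)."""
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01)
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_oracle(scores, y01) -> float:
    """Direct average-precision summation over descending thresholds (oracle)."""
    scores = np.asarray(scores, dtype=float)
    y01 = np.asarray(y01)
    n_pos = int(y01.sum())
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        called = scores >= t
        tp = int((y01 == 1)[called].sum())
        recall = tp / n_pos
        precision = tp / int(called.sum())
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def logloss_oracle(scores, y01, eps=1e-15) -> float:
    """Element-by-element negative log-likelihood summation (oracle)."""
    total = 0.0
    for p, y in zip(scores, y01):
        p = min(max(p, eps), 1 - eps)
        total += -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return total / len(scores)


@pytest.fixture
def two_block_dataset() -> Dataset:
    """Samples {A,B} observe {f1,f2}; {C,D} observe {f2,f3}: the toy case
    whose intersection closure is exactly three feature sets."""
    values = pd.DataFrame(
        {
            "f1": [1.0, 2.0, np.nan, np.nan],
            "f2": [3.0, 4.0, 5.0, 6.0],
            "f3": [np.nan, np.nan, 7.0, 8.0],
        },
        index=["A", "B", "C", "D"],
    )
    outcome = pd.Series(["case", "control", "case", "control"],
                        index=["A", "B", "C", "D"], name="outcome")
    return Dataset(values=values, outcome=outcome, positive_class="case")


@pytest.fixture
def separable_dataset() -> Dataset:
    """Two Gaussian classes 4 SD apart on two features: separable limit."""
    rng = np.random.default_rng(42)
    n = 60
    X = rng.standard_normal((2 * n, 2))
    X[:n] += 4.0
    labels = ["case"] * n + ["control"] * n
    return make_dataset(X, labels)


@pytest.fixture
def random_missing_dataset() -> Dataset:
    """10 x 6 grid with iid 30% missing cells (seeded)."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((10, 6))
    mask = rng.random((10, 6)) < 0.3
    X[mask] = np.nan
    labels = ["case", "control"] * 5
    return make_dataset(X, labels)
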