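"""Exploratory statistics: pairwise correlation, hierarchical clustering,
and SAM-style permutation differential analysis.

The SAM procedure implemented here is the two-class unpaired moderated
difference statistic: for feature i,

    d_i = (mean_2 - mean_1) / (s_i + s0)

where s_i is the pooled two-sample standard error and s0 a small "fudge
factor" that stabilises d for low-variance features.  The null distribution
of d comes from label permutations; for a threshold delta, features whose
sorted d departs from the permutation-expected order statistics by more
than delta are called, and the false-discovery rate is estimated as the
median number of permutation calls divided by the observed call count.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import pdist

from .dataset_io import Dataset
from .errors import BioAutoMLError

logger = logging.getLogger(__name__)

DEFAULT_REPORT_THRESHOLD = 0.75
DEFAULT_N_PERMUTATIONS = 200


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    matrix: pd.DataFrame          # feature x feature coefficients; NaN = undefined
    n_used: pd.DataFrame          # pairwise-complete observation counts
    method: str
    high_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    undefined_features: list[str] = field(default_factory=list)


def correlation_matrix(
    dataset: Dataset,
    method: str = "pearson",
    min_pairs: int = 3,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> CorrelationResult:
    """Pairwise-complete correlation across features.

    Each pair's coefficient uses only the rows where both features are
    observed; pairs with fewer than ``min_pairs`` shared rows, and any pair
    involving a constant feature, are undefined (NaN) and flagged.
    """
    if dataset.n_features < 2:
        raise BioAutoMLError("correlation requires >= 2 features")
    if method not in ("pearson", "spearman"):
        raise BioAutoMLError(f"unknown correlation method {method!r}")
    values = dataset.values
    corr = values.corr(method=method, min_periods=max(2, min_pairs))
    observed = values.notna().astype(int)
    n_used = observed.T @ observed
    constant = [
        c
        for c in values.columns
        if values[c].dropna().nunique() <= 1
    ]
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    for c in values.columns:
        if c not in constant:
            corr.loc[c, c] = 1.0
    high = []
    cols = list(values.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if pd.notna(r) and abs(r) >= report_threshold:
                high.append((a, b, float(r)))
    high.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    if constant:
        logger.warning("constant features with undefined correlations: %s", constant)
    return CorrelationResult(
        matrix=corr,
        n_used=n_used,
        method=method,
        high_pairs=high,
        undefined_features=constant,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

_LINKAGE_MAP = {"average": "average", "complete": "complete", "ward-like": "ward", "ward": "ward"}


@dataclass
class ClusteringResult:
    merge_matrix: np.ndarray      # scipy linkage matrix
    labels: list[str]             # leaf labels in input order
    ordered_leaves: list[str]     # labels in dendrogram order
    distance: str
    linkage: str
    axis: str

    def cut(self, n_clusters: int) -> pd.Series:
        assignment = fcluster(self.merge_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(assignment, index=self.labels, name="cluster")


def hierarchical_cluster(
    dataset: Dataset,
    distance: str = "euclidean",
    linkage_method: str = "average",
    axis: str = "samples",
) -> ClusteringResult:
    """Agglomerative clustering of samples (rows) or features (columns).

    The grid must be complete — impute first.  ``distance`` is "euclidean"
    or "correlation" (1 - Pearson r); linkage is average, complete or
    ward-like (ward requires euclidean distances).  Merge order is
    deterministic; ties resolve to the smaller leaf index.
    """
    if dataset.values.isna().any().any():
        raise BioAutoMLError("clustering requires a complete grid; impute missing cells first")
    if axis not in ("samples", "features"):
        raise BioAutoMLError("axis must be 'samples' or 'features'")
    if linkage_method not in _LINKAGE_MAP:
        raise BioAutoMLError(f"unknown linkage {linkage_method!r}")
    X = dataset.values.to_numpy() if axis == "samples" else dataset.values.to_numpy().T
    labels = dataset.sample_ids if axis == "samples" else dataset.feature_names
    if X.shape[0] < 2:
        raise BioAutoMLError("clustering requires at least 2 items")
    if distance == "euclidean":
        dists = pdist(X, metric="euclidean")
    elif distance in ("correlation", "1-correlation"):
        dists = pdist(X, metric="correlation")
    else:
        raise BioAutoMLError(f"unknown distance {distance!r}")
    method = _LINKAGE_MAP[linkage_method]
    if method == "ward" and distance != "euclidean":
        raise BioAutoMLError("ward-like linkage requires euclidean distance")
    Z = linkage(dists, method=method)
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    return ClusteringResult(
        merge_matrix=Z,
        labels=list(labels),
        ordered_leaves=[labels[i] for i in leaves],
        distance=distance,
        linkage=linkage_method,
        axis=axis,
    )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

@dataclass
class SAMTable:
    d: pd.Series                  # observed moderated difference per feature
    s: pd.Series                  # pooled standard error per feature
    s0: float
    dbar: np.ndarray              # permutation-expected order statistics (ascending)
    displacement: pd.Series       # per-feature |d_(i) - dbar_(i)| at its rank
    delta_table: pd.DataFrame     # delta, n_called, median_false, fdr
    n_permutations: int
    class_order: tuple[str, str]  # (class1, class2); d = mean2 - mean1

    def called(self, delta: float) -> list[str]:
        """Features whose departure from the expected order statistics
        exceeds delta.  Monotone: a larger delta calls a subset."""
        return [f for f, disp in self.displacement.items() if disp > delta]


def _d_stat(X: np.ndarray, y01: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated difference d and pooled SE s for each column of X."""
    g1 = X[y01 == 0]
    g2 = X[y01 == 1]
    n1, n2 = len(g1), len(g2)
    m1 = g1.mean(axis=0)
    m2 = g2.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    pooled_var = ss / (n1 + n2 - 2)
    s = np.sqrt((1 / n1 + 1 / n2) * pooled_var)
    return (m2 - m1) / (s + s0), s


def _tusher_s0(X: np.ndarray, y01: np.ndarray) -> float:
    """Fudge factor: the percentile of {s_i} minimising the coefficient of
    variation of d across windows of s (percentile grid 0, 5, ..., 100);
    falls back to the median of s when the search degenerates."""
    _, s = _d_stat(X, y01, 0.0)
    percentiles = np.percentile(s, np.arange(0, 101, 5))
    # windows of s defined by the same percentile grid
    edges = np.unique(percentiles)
    best_s0, best_cv = None, np.inf
    for cand in np.unique(percentiles):
        d, _ = _d_stat(X, y01, float(cand))
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            w = (s >= lo) & (s <= hi if hi == edges[-1] else s < hi)
            if w.sum() >= 3:
                dm = d[w]
                mads.append(np.median(np.abs(dm - np.median(dm))) / 0.64)
        if len(mads) >= 2 and np.mean(mads) > 0:
            cv = np.std(mads) / np.mean(mads)
            if cv < best_cv:
                best_cv, best_s0 = cv, float(cand)
    if best_s0 is None:
        best_s0 = float(np.median(s))
    return best_s0


def _displacement(d: np.ndarray, dbar: np.ndarray) -> np.ndarray:
    """|d_(i) - dbar_(i)| mapped back to the original feature order.

    Observed d values are sorted and compared against the permutation-
    expected order statistics at the same rank (the quantile-quantile
    displacement).  The identical rule is applied to each permutation when
    counting false calls, so under a pure-noise grid the expected false
    count matches the observed call count and the estimated FDR sits
    near 1.
    """
    order = np.argsort(d, kind="stable")
    disp_sorted = np.abs(d[order] - dbar)
    disp = np.empty_like(disp_sorted)
    disp[order] = disp_sorted
    return disp


def _permutation_labels(y01: np.ndarray, n_permutations: int, seed: int) -> np.ndarray:
    """Distinct label reassignments: full enumeration when the number of
    possible class-2 subsets is small, else seeded sampling."""
    n = len(y01)
    n2 = int(y01.sum())
    total = math.comb(n, n2)
    if total - 1 < 2:
        raise BioAutoMLError("fewer than 2 distinct label permutations possible")
    perms = []
    if total <= n_permutations:
        for combo in itertools.combinations(range(n), n2):
            lab = np.zeros(n, dtype=int)
            lab[list(combo)] = 1
            if np.array_equal(lab, y01):
                continue
            perms.append(lab)
    else:
        rng = np.random.default_rng(seed)
        seen = {tuple(y01.tolist())}
        while len(perms) < n_permutations:
            lab = rng.permutation(y01)
            key = tuple(lab.tolist())
            if key in seen:
                continue
            seen.add(key)
            perms.append(lab)
    return np.array(perms)


def sam_test(
    dataset: Dataset,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    s0_rule: str = "cv-minimizing",
    deltas: np.ndarray | None = None,
) -> SAMTable:
    """Two-class unpaired SAM with permutation-calibrated FDR.

    The two classes come from the dataset outcome (class 2 = positive
    class, so positive d means higher in the positive class).  The grid
    must be complete and each class needs >= 2 samples.
    """
    if dataset.values.isna().any().any():
        raise BioAutoMLError("SAM requires a complete grid; impute missing cells first")
    y01 = dataset.y()
    if min(int(y01.sum()), int((1 - y01).sum())) < 2:
        raise BioAutoMLError("SAM requires >= 2 samples per class")
    X = dataset.values.to_numpy()
    if s0_rule == "cv-minimizing":
        s0 = _tusher_s0(X, y01)
    elif s0_rule == "median":
        _, s_tmp = _d_stat(X, y01, 0.0)
        s0 = float(np.median(s_tmp))
    else:
        raise BioAutoMLError(f"unknown s0 rule {s0_rule!r}")

    d, s = _d_stat(X, y01, s0)
    perms = _permutation_labels(y01, n_permutations, seed)
    perm_sorted = np.sort(
        np.array([_d_stat(X, lab, s0)[0] for lab in perms]), axis=1
    )
    dbar = perm_sorted.mean(axis=0)

    disp = _displacement(d, dbar)
    perm_disp = np.abs(perm_sorted - dbar)  # same rule per permutation row

    if deltas is None:
        top = max(float(disp.max()), 1e-6)
        deltas = np.linspace(0.0, top, 25)[1:]
    rows = []
    for delta in deltas:
        called = int((disp > delta).sum())
        false_counts = (perm_disp > delta).sum(axis=1)
        median_false = float(np.median(false_counts))
        fdr = min(1.0, median_false / called) if called > 0 else 0.0
        rows.append(
            {
                "delta": float(delta),
                "n_called": called,
                "median_false": median_false,
                "fdr": fdr,
            }
        )
    neg, pos = dataset.classes
    return SAMTable(
        d=pd.Series(d, index=dataset.feature_names, name="d"),
        s=pd.Series(s, index=dataset.feature_names, name="s"),
        s0=s0,
        dbar=dbar,
        displacement=pd.Series(disp, index=dataset.feature_names, name="displacement"),
        delta_table=pd.DataFrame(rows),
        n_permutations=len(perms),
        class_order=(neg, pos),
    )
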