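"""Complete-submatrix ("resample") generation for tables with missing values.

Samples are grouped by their missingness signature — the exact set of
features observed for that sample.  Intersecting signatures yields feature
sets shared across signature groups; each distinct non-empty intersection
defines a *resample*: the feature set together with the maximal set of
samples observing every feature in it.  Extracting a resample gives a
complete (no-missing) submatrix, so standard learners can be run on each
resample independently.  This is how multi-assay tables with block
missingness are turned into an ensemble of fully observed analysis sets.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

from .dataset_io import Dataset
from .errors import BioAutoMLError, ResourceError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLES = 15
DEFAULT_MIN_FEATURES = 2
DEFAULT_CLOSURE_CAP = 10_000


@dataclass(frozen=True)
class Signature:
    """A missingness signature: the observed-feature set shared by a group of samples."""

    observed_features: frozenset[str]
    sample_ids: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def resample_id_for(feature_set: frozenset[str] | set[str]) -> str:
    """Stable content hash of a feature set (sorted, newline-joined names)."""
    digest = hashlib.sha1("\n".join(sorted(feature_set)).encode("utf-8"))
    return digest.hexdigest()[:16]


@dataclass(frozen=True)
class Resample:
    """A complete submatrix: a feature set and the maximal sample set observing it."""

    feature_set: frozenset[str]
    sample_ids: tuple[str, ...]
    resample_id: str

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_set)


def compute_signatures(dataset: Dataset) -> list[Signature]:
    """Partition the samples by their observed-feature sets.

    Samples with zero observed features are excluded with a warning.  The
    result is sorted by descending group size, ties broken by the
    lexicographic order of the sorted feature list, so the output does not
    depend on input row or column order.
    """
    if dataset.n_samples < 1:
        raise BioAutoMLError("dataset has no samples")
    observed = dataset.values.notna()
    groups: dict[frozenset[str], list[str]] = {}
    for sid in dataset.sample_ids:
        feats = frozenset(observed.columns[observed.loc[sid].to_numpy()])
        if not feats:
            logger.warning("sample %r has zero observed features; excluded", sid)
            continue
        groups.setdefault(feats, []).append(sid)
    sigs = [
        Signature(observed_features=feats, sample_ids=tuple(sorted(sids)))
        for feats, sids in groups.items()
    ]
    sigs.sort(key=lambda s: (-s.n_samples, tuple(sorted(s.observed_features))))
    return sigs


def _intersection_closure(
    base_sets: list[frozenset[str]], cap: int
) -> set[frozenset[str]]:
    """All distinct non-empty intersections over non-empty subsets of *base_sets*.

    Computed by iterated pairwise intersection to a fixed point with
    hash-based deduplication.  Equivalent to enumerating every subset
    because intersection is associative: any k-way intersection is reachable
    through k-1 pairwise steps, and the fixed point adds nothing new.
    """
    closure: set[frozenset[str]] = {s for s in base_sets if s}
    frontier = set(closure)
    while frontier:
        new: set[frozenset[str]] = set()
        for f in frontier:
            for s in closure:
                inter = f & s
                if inter and inter not in closure and inter not in new:
                    new.add(inter)
        closure |= new
        if len(closure) > cap:
            raise ResourceError(
                f"intersection closure exceeded the cap of {cap} feature sets; "
                "consider coarser assay blocks or raising the cap"
            )
        frontier = new
    return closure


def generate_resamples(
    signatures: list[Signature],
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_features: int = DEFAULT_MIN_FEATURES,
    closure_cap: int = DEFAULT_CLOSURE_CAP,
) -> list[Resample]:
    """Enumerate all resamples implied by a set of missingness signatures.

    The emitted feature sets are the intersection closure of the signature
    feature sets.  Each resample's sample set is maximal: it contains every
    sample whose observed set is a superset of the resample's feature set.
    Resamples below ``min_samples`` or ``min_features`` are dropped after
    the closure is computed.  Output order is canonical (descending
    n_samples, then descending n_features, then resample_id) and therefore
    invariant to input sample/feature order.
    """
    if not signatures:
        raise BioAutoMLError("no signatures given")
    base = [s.observed_features for s in signatures]
    closure = _intersection_closure(base, closure_cap)
    resamples = []
    for feats in closure:
        members: list[str] = []
        for sig in signatures:
            if feats <= sig.observed_features:
                members.extend(sig.sample_ids)
        if len(members) < min_samples or len(feats) < min_features:
            continue
        resamples.append(
            Resample(
                feature_set=frozenset(feats),
                sample_ids=tuple(sorted(members)),
                resample_id=resample_id_for(feats),
            )
        )
    resamples.sort(key=lambda r: (-r.n_samples, -r.n_features, r.resample_id))
    return resamples


def filter_resamples(
    resamples: list[Resample], test_fraction: float, min_test_samples: int
) -> list[Resample]:
    """Keep resamples whose holdout split would contain enough samples.

    A resample survives when ``floor(n_samples * test_fraction) >=
    min_test_samples``; undersized holdout sets give overly optimistic
    estimates.  Order is preserved.
    """
    if not 0 < test_fraction < 1:
        raise BioAutoMLError("test_fraction must be in (0, 1)")
    return [
        r
        for r in resamples
        if math.floor(r.n_samples * test_fraction) >= min_test_samples
    ]


def extract_submatrix(dataset: Dataset, resample: Resample) -> Dataset:
    """Materialize a resample as a complete dataset.

    Rows and columns are restricted to the resample and kept in the parent
    dataset's order; the outcome is carried over.  The result has zero
    missing cells by construction.
    """
    missing_samples = set(resample.sample_ids) - set(dataset.sample_ids)
    missing_feats = set(resample.feature_set) - set(dataset.feature_names)
    if missing_samples or missing_feats:
        raise BioAutoMLError(
            "stale resample: absent samples "
            f"{sorted(missing_samples)} / features {sorted(missing_feats)}"
        )
    rows = [s for s in dataset.sample_ids if s in set(resample.sample_ids)]
    cols = [f for f in dataset.feature_names if f in resample.feature_set]
    sub = dataset.select(sample_ids=rows, feature_names=cols)
    if sub.values.isna().any().any():
        raise BioAutoMLError(
            f"resample {resample.resample_id} is not complete on this dataset"
        )
    return sub


def whole_dataset_resample(dataset: Dataset) -> Resample:
    """The trivial resample covering every sample and feature (complete data)."""
    feats = frozenset(dataset.feature_names)
    return Resample(
        feature_set=feats,
        sample_ids=tuple(sorted(dataset.sample_ids)),
        resample_id=resample_id_for(feats),
    )
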