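"""Missingness signatures, intersection closure and resample filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioautoml.errors import ResourceError
from bioautoml.mulset import (
    Resample,
    compute_signatures,
    extract_submatrix,
    filter_resamples,
    generate_resamples,
    resample_id_for,
)

from conftest import brute_force_closure, make_dataset


def random_missing(seed, n=10, p=6, rate=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X[rng.random((n, p)) < rate] = np.nan
    labels = ["case", "control"] * (n // 2)
    return make_dataset(X, labels)


class TestSignatures:
    def test_complete_matrix_single_signature(self):
        ds = make_dataset(np.ones((6, 4)), ["case", "control"] * 3)
        sigs = compute_signatures(ds)
        assert len(sigs) == 1
        assert sigs[0].sample_ids == tuple(sorted(ds.sample_ids))
        assert sigs[0].observed_features == frozenset(ds.feature_names)

    def test_two_blocks(self, two_block_dataset):
        sigs = compute_signatures(two_block_dataset)
        assert len(sigs) == 2
        families = {s.observed_features for s in sigs}
        assert families == {frozenset({"f1", "f2"}), frozenset({"f2", "f3"})}

    @pytest.mark.parametrize("seed", range(5))
    def test_signatures_partition_samples(self, seed):
        ds = random_missing(seed)
        sigs = compute_signatures(ds)
        covered = [s for sig in sigs for s in sig.sample_ids]
        observed_any = [
            s for s in ds.sample_ids if ds.values.loc[s].notna().any()
        ]
        assert sorted(covered) == sorted(observed_any)
        assert len(covered) == len(set(covered))  # disjoint

    def test_all_missing_sample_excluded_with_warning(self, caplog):
        X = np.array([[1.0, 2.0], [np.nan, np.nan]])
        ds = make_dataset(X, ["case", "control"])
        sigs = compute_signatures(ds)
        assert len(sigs) == 1
        assert "zero observed features" in caplog.text


class TestGenerateResamples:
    def test_complete_matrix_single_resample(self):
        ds = make_dataset(np.ones((6, 4)), ["case", "control"] * 3)
        rs = generate_resamples(compute_signatures(ds), min_samples=1, min_features=1)
        assert len(rs) == 1
        assert rs[0].n_samples == 6 and rs[0].n_features == 4

    def test_two_block_closure(self, two_block_dataset):
        rs = generate_resamples(
            compute_signatures(two_block_dataset), min_samples=1, min_features=1
        )
        got = {(frozenset(r.feature_set), r.sample_ids) for r in rs}
        assert got == {
            (frozenset({"f1", "f2"}), ("A", "B")),
            (frozenset({"f2", "f3"}), ("C", "D")),
            (frozenset({"f2"}), ("A", "B", "C", "D")),
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_closure_equals_brute_force(self, seed):
        ds = random_missing(seed, n=12, p=7, rate=0.35)
        sigs = compute_signatures(ds)
        rs = generate_resamples(sigs, min_samples=1, min_features=1)
        expected = brute_force_closure([frozenset(s.observed_features) for s in sigs])
        assert {frozenset(r.feature_set) for r in rs} == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_maximality(self, seed):
        ds = random_missing(seed)
        rs = generate_resamples(compute_signatures(ds), min_samples=1, min_features=1)
        observed = ds.values.notna()
        for r in rs:
            cols = sorted(r.feature_set)
            inside = set(r.sample_ids)
            for s in ds.sample_ids:
                fully_observed = bool(observed.loc[s, cols].all())
                assert (s in inside) == fully_observed

    def test_closure_property_pairwise(self):
        ds = random_missing(3, n=12, p=7, rate=0.35)
        rs = generate_resamples(compute_signatures(ds), min_samples=1, min_features=1)
        family = {frozenset(r.feature_set) for r in rs}
        for a in family:
            for b in family:
                inter = a & b
                assert not inter or inter in family

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariance(self, seed):
        ds = random_missing(seed)
        rng = np.random.default_rng(seed + 100)
        shuffled = ds.select(
            sample_ids=[ds.sample_ids[i] for i in rng.permutation(ds.n_samples)],
            feature_names=[ds.feature_names[j] for j in rng.permutation(ds.n_features)],
        )
        rs1 = generate_resamples(compute_signatures(ds), 1, 1)
        rs2 = generate_resamples(compute_signatures(shuffled), 1, 1)
        assert [(r.resample_id, r.sample_ids) for r in rs1] == [
            (r.resample_id, r.sample_ids) for r in rs2
        ]

    def test_monotonicity_adding_sample_keeps_feature_sets(self):
        ds = random_missing(11, n=8)
        before = {
            frozenset(r.feature_set)
            for r in generate_resamples(compute_signatures(ds), 1, 1)
        }
        X = ds.values.to_numpy()
        Xplus = np.vstack([X, np.ones(ds.n_features)])
        plus = make_dataset(Xplus, (["case", "control"] * 5)[: len(Xplus)])
        after = {
            frozenset(r.feature_set)
            for r in generate_resamples(compute_signatures(plus), 1, 1)
        }
        assert before <= after

    def test_minima_filter_applied_after_closure(self, two_block_dataset):
        rs = generate_resamples(
            compute_signatures(two_block_dataset), min_samples=3, min_features=1
        )
        # only the shared single-feature set has >= 3 samples
        assert [sorted(r.feature_set) for r in rs] == [["f2"]]

    def test_closure_cap_raises_resource_error(self):
        # 14 two-hot-complement signatures generate a combinatorial closure
        p = 14
        sets = []
        for i in range(p):
            feats = frozenset(f"f{j}" for j in range(p) if j != i)
            sets.append(feats)
        from bioautoml.mulset import Signature

        sigs = [
            Signature(observed_features=s, sample_ids=(f"S{i}",))
            for i, s in enumerate(sets)
        ]
        with pytest.raises(ResourceError, match="cap"):
            generate_resamples(sigs, 1, 1, closure_cap=50)

    def test_resample_id_stable_and_order_free(self):
        assert resample_id_for({"b", "a"}) == resample_id_for({"a", "b"})
        assert resample_id_for({"a"}) != resample_id_for({"b"})


class TestFilterResamples:
    def _resample(self, n):
        feats = frozenset({"f1", "f2"})
        return Resample(
            feature_set=feats,
            sample_ids=tuple(f"S{i}" for i in range(n)),
            resample_id=resample_id_for(feats),
        )

    def test_kept_at_47(self):
        assert filter_resamples([self._resample(47)], 0.25, 10)

    def test_dropped_at_39(self):
        assert not filter_resamples([self._resample(39)], 0.25, 10)

    def test_sweep_matches_arithmetic(self):
        rs = [self._resample(n) for n in range(10, 101)]
        kept = filter_resamples(rs, 0.25, 10)
        assert {r.n_samples for r in kept} == {
            n for n in range(10, 101) if math.floor(n * 0.25) >= 10
        }
        assert min(r.n_samples for r in kept) == 40


class TestExtractSubmatrix:
    def test_complete_matrix_roundtrip(self):
        ds = make_dataset(np.arange(24, dtype=float).reshape(6, 4),
                          ["case", "control"] * 3)
        (r,) = generate_resamples(compute_signatures(ds), 1, 1)
        assert extract_submatrix(ds, r).equals(ds)

    def test_two_block_shapes(self, two_block_dataset):
        rs = generate_resamples(compute_signatures(two_block_dataset), 1, 1)
        shapes = sorted(
            extract_submatrix(two_block_dataset, r).values.shape for r in rs
        )
        assert shapes == [(2, 2), (2, 2), (4, 1)]

    @pytest.mark.parametrize("seed", range(3))
    def test_extraction_always_complete(self, seed):
        ds = random_missing(seed)
        for r in generate_resamples(compute_signatures(ds), 1, 1):
            assert extract_submatrix(ds, r).n_missing == 0

    def test_stale_resample_rejected(self, two_block_dataset):
        feats = frozenset({"zzz"})
        stale = Resample(feats, ("A",), resample_id_for(feats))
        with pytest.raises(Exception, match="stale"):
            extract_submatrix(two_block_dataset, stale)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_closure_oracle_property(seed):
    """Property: emitted feature-set family == brute-force subset enumeration."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 12))
    p = int(rng.integers(2, 8))
    X = rng.standard_normal((n, p))
    X[rng.random((n, p)) < 0.4] = np.nan
    labels = (["case", "control"] * n)[:n]
    ds = make_dataset(X, labels)
    if ds.values.notna().any(axis=1).sum() == 0:
        return
    sigs = compute_signatures(ds)
    got = {
        frozenset(r.feature_set)
        for r in generate_resamples(sigs, 1, 1)
    }
    assert got == brute_force_closure([frozenset(s.observed_features) for s in sigs])
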