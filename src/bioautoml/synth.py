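"""Seeded generators for the benchmark dataset archetypes.

Real biomedical tables come in a few recurring shapes: modest clinical
tables (~500 x 20), multi-assay immunology panels with block missingness
(whole assay blocks absent for subsets of donors, 8-21% of cells missing),
wide p >> n omics tables, and strongly unbalanced two-class tables
(e.g. 374 tumor vs 50 normal).  The generators here emulate those shapes
with a Gaussian class-conditional model (equal covariance, unit variance),
chosen because its separability is analytic: a single informative feature
with standardized mean difference ``e`` has a theoretical AUROC of
``Phi(e / sqrt(2))``.  They make every pipeline stage testable without
downloads; matching real data's marginal distributions is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset_io import Dataset
from .errors import BioAutoMLError


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic two-class table.

    ``effect_size`` is the standardized between-class mean difference of
    each informative feature (unit-variance features, so effect_size = 1.5
    means the class means differ by 1.5 SD).  ``class_balance`` is the
    proportion of positive-class samples.  ``missingness`` is None,
    ``("iid", rate)`` for independent cell dropout, or ``("blocks",
    [(feature_list, sample_fraction), ...])`` for assay-block dropout.
    """

    n_samples: int = 200
    n_features: int = 20
    n_informative: int = 5
    effect_size: float = 1.5
    class_balance: float = 0.5
    missingness: tuple | None = None
    correlated_pairs: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0
    positive_class: str = "case"
    negative_class: str = "control"

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise BioAutoMLError("n_informative cannot exceed n_features")
        if not 0 <= self.class_balance <= 1:
            raise BioAutoMLError("class_balance must be in [0, 1]")


def make_classification_data(spec: SynthSpec) -> tuple[Dataset, dict]:
    """Generate a dataset and its ground-truth sidecar.

    Informative features get a between-class mean shift of ``effect_size``
    (positive class higher); the rest are standard normal noise.  The truth
    dict records the informative feature names, the effect size and the
    class counts; recovery tests should read the truth only from this
    sidecar, never from generator internals.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_samples * spec.class_balance))
    n_neg = spec.n_samples - n_pos
    if n_pos == 0 or n_neg == 0:
        raise BioAutoMLError(
            f"class_balance {spec.class_balance} leaves a class empty at n={spec.n_samples}"
        )
    width = len(str(spec.n_features))
    names = [f"F{str(i + 1).zfill(width)}" for i in range(spec.n_features)]
    informative = sorted(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False).tolist()
    )
    labels = np.array(
        [spec.positive_class] * n_pos + [spec.negative_class] * n_neg
    )
    labels = labels[rng.permutation(spec.n_samples)]
    y01 = (labels == spec.positive_class).astype(int)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    for j in informative:
        X[:, j] += spec.effect_size * y01
    for a, b, target_r in spec.correlated_pairs:
        ia, ib = names.index(a), names.index(b)
        noise = rng.standard_normal(spec.n_samples)
        X[:, ib] = target_r * X[:, ia] + np.sqrt(max(0.0, 1 - target_r**2)) * noise

    ids = [f"S{str(i + 1).zfill(len(str(spec.n_samples)))}" for i in range(spec.n_samples)]
    values = pd.DataFrame(X, index=ids, columns=names)
    outcome = pd.Series(labels, index=ids, name="outcome")
    ds = Dataset(
        values=values,
        outcome=outcome,
        positive_class=spec.positive_class,
        negative_class=spec.negative_class,
    )
    if spec.missingness is not None:
        kind = spec.missingness[0]
        if kind == "iid":
            rate = float(spec.missingness[1])
            mask = np.random.default_rng(spec.seed + 1).random(X.shape) < rate
            vals = ds.values.copy()
            vals[pd.DataFrame(mask, index=ids, columns=names)] = np.nan
            ds = ds.with_values(vals)
        elif kind == "blocks":
            ds = inject_block_missingness(ds, spec.missingness[1], seed=spec.seed + 1)
        else:
            raise BioAutoMLError(f"unknown missingness kind {kind!r}")
    truth = {
        "informative_features": [names[j] for j in informative],
        "effect_size": spec.effect_size,
        "n_positive": int(n_pos),
        "n_negative": int(n_neg),
        "positive_class": spec.positive_class,
        "seed": spec.seed,
    }
    return ds, truth


def inject_block_missingness(dataset: Dataset, blocks, seed: int = 0) -> Dataset:
    """Blank whole feature blocks for random sample subsets.

    ``blocks`` is a list of (feature_names, sample_fraction): each block's
    features are set missing for a seeded random ``round(fraction * n)``
    subset of samples, emulating assays run on only part of a cohort.
    """
    rng = np.random.default_rng(seed)
    values = dataset.values.copy()
    known = set(dataset.feature_names)
    for bi, (feats, fraction) in enumerate(blocks):
        feats = list(feats)
        unknown = [f for f in feats if f not in known]
        if unknown:
            raise BioAutoMLError(f"block {bi} references unknown features: {unknown}")
        if not 0 <= fraction <= 1:
            raise BioAutoMLError(f"block {bi} fraction {fraction} outside [0, 1]")
        n_hit = int(round(fraction * dataset.n_samples))
        hit = rng.choice(dataset.n_samples, size=n_hit, replace=False)
        values.iloc[hit, [dataset.feature_names.index(f) for f in feats]] = np.nan
    return dataset.with_values(values)


def missing_rate(dataset: Dataset) -> float:
    """Fraction of missing predictor cells."""
    return float(dataset.values.isna().to_numpy().mean())


# ---------------------------------------------------------------------------
# Archetype presets
# ---------------------------------------------------------------------------

def _block_names(prefix_count: int, start: int, size: int) -> list[str]:
    width = len(str(prefix_count))
    return [f"F{str(i + 1).zfill(width)}" for i in range(start, start + size)]


def archetype_spec(name: str, seed: int = 0) -> SynthSpec:
    """Named presets reproducing the benchmark dataset shapes.

    * ``clinical``  — 534 x 14 complete clinical table, mild signal.
    * ``cytometry`` — 195 samples, 30 features, two assay blocks missing
      for part of the cohort (~8% missing cells overall).
    * ``serology``  — 72 samples, 20 features, heavier block dropout
      (~21% missing cells overall), unbalanced 26:46.
    * ``microbiome`` — 184 samples x 500 features (p >> n), near-balanced.
    * ``expression`` — 424 samples at 374:50 positives:negatives, the
      strongly unbalanced archetype where PR-based ranking matters.
    """
    presets = {
        "clinical": SynthSpec(
            n_samples=534, n_features=14, n_informative=3, effect_size=1.2,
            class_balance=0.5, seed=seed,
        ),
        "cytometry": SynthSpec(
            n_samples=195, n_features=30, n_informative=6, effect_size=1.5,
            class_balance=120 / 195,
            # two 8-feature assay blocks each absent for 15% of donors:
            # expected missing rate 2 * 8 * 0.15 / 30 = 8%
            missingness=(
                "blocks",
                [
                    (_block_names(30, 14, 8), 0.15),
                    (_block_names(30, 22, 8), 0.15),
                ],
            ),
            seed=seed,
        ),
        "serology": SynthSpec(
            n_samples=72, n_features=20, n_informative=4, effect_size=1.0,
            class_balance=26 / 72,
            # two 6-feature blocks each absent for 35% of donors:
            # expected missing rate 2 * 6 * 0.35 / 20 = 21%
            missingness=(
                "blocks",
                [
                    (_block_names(20, 8, 6), 0.35),
                    (_block_names(20, 14, 6), 0.35),
                ],
            ),
            seed=seed,
        ),
        "microbiome": SynthSpec(
            n_samples=184, n_features=500, n_informative=10, effect_size=1.0,
            class_balance=91 / 184, seed=seed,
        ),
        "expression": SynthSpec(
            n_samples=424, n_features=100, n_informative=8, effect_size=1.5,
            class_balance=374 / 424, positive_class="tumor",
            negative_class="normal", seed=seed,
        ),
    }
    if name not in presets:
        raise BioAutoMLError(f"unknown archetype {name!r}; options: {sorted(presets)}")
    return presets[name]


ARCHETYPES = ("clinical", "cytometry", "serology", "microbiome", "expression")


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    """Write the ground-truth sidecar as JSON next to a generated CSV."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
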