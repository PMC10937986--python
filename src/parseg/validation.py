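"""Classifier-based validation of a pixel subset.

One subset of the partition is validated by repeatedly (``B`` times)
drawing a subsample of size ``s``, splitting it into a learning and a
validation part with cardinality ratio ``pi = |learn|/|validate|``,
training a binary classifier (CART by default) on the learning part,
and scoring the predicted labels on the validation part with
sensitivity ``phi``.  The replicate mean ``phi_bar`` and standard
deviation ``sigma`` summarize the subset at that size; the consistency
index ``psi`` compares them against the same statistics at the full
subset size ``n``:

    psi(s) = |phi_bar(s) - phi_bar(n)| * |sigma(s) - sigma(n)|

so ``psi(n) = 0`` by construction and small ``psi`` means the
subsample validates the segmentation as well as the whole subset does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from ._rng import spawn_int
from .exceptions import DegenerateSampleError, ParsegError
from .pixel_data import PixelDataset

__all__ = [
    "PixelSample",
    "SplitPair",
    "ClassifierSpec",
    "ReplicateStats",
    "ConsistencyIndex",
    "draw_sample",
    "split_learn_validate",
    "train_and_predict",
    "sensitivity",
    "replicate_validation",
    "consistency_index",
    "register_classifier",
]

MAX_RETRIES = 10  # bounded redraws for degenerate samples/splits


@dataclass(frozen=True)
class PixelSample:
    """``size`` record indices drawn without replacement from one subset."""

    subset_id: int
    indices: np.ndarray

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SplitPair:
    """A learning/validation split of a sample with ratio ``pi``."""

    learning: np.ndarray
    validation: np.ndarray
    pi: float


def _cart_factory(**hyperparameters: object) -> DecisionTreeClassifier:
    defaults: dict = {"criterion": "gini", "min_samples_leaf": 1}
    defaults.update(hyperparameters)
    return DecisionTreeClassifier(**defaults)


_CLASSIFIERS: dict[str, Callable[..., object]] = {"cart": _cart_factory}


def register_classifier(name: str, factory: Callable[..., object]) -> None:
    """Register ``factory(**hyperparameters) -> estimator`` under ``name``.

    The estimator must expose sklearn-style ``fit(X, y)`` and
    ``predict(X)``.
    """
    _CLASSIFIERS[name] = factory


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier + hyperparameters; default CART (Gini, unpruned)."""

    name: str = "cart"
    hyperparameters: dict = field(default_factory=dict)

    def build(self, random_state: int | None = None):
        try:
            factory = _CLASSIFIERS[self.name]
        except KeyError:
            raise ParsegError(
                f"unknown classifier {self.name!r}; known: {sorted(_CLASSIFIERS)}"
            ) from None
        est = factory(**self.hyperparameters)
        if random_state is not None and hasattr(est, "random_state"):
            est.random_state = random_state
        return est


@dataclass(frozen=True)
class ReplicateStats:
    """Sensitivity of ``B`` replicates at one (subset, size)."""

    subset_id: int
    size: int
    phis: np.ndarray

    @property
    def B(self) -> int:
        return len(self.phis)

    @property
    def phi_bar(self) -> float:
        return float(np.mean(self.phis))

    @property
    def sigma(self) -> float:
        return float(np.std(self.phis, ddof=1))

    def to_row(self) -> dict:
        return {
            "subset_id": self.subset_id,
            "size": self.size,
            "B": self.B,
            "phi_bar": self.phi_bar,
            "sigma": self.sigma,
        }


def stats_to_csv(stats: list[ReplicateStats], path) -> None:
    """Audit export of replicate summaries."""
    pd.DataFrame([s.to_row() for s in stats]).to_csv(path, index=False)


@dataclass(frozen=True)
class ConsistencyIndex:
    subset_id: int
    size: int
    psi: float


def draw_sample(
    data: PixelDataset,
    subset: np.ndarray,
    s: int,
    rng: np.random.Generator,
    subset_id: int = 0,
) -> PixelSample:
    """Uniform draw of ``s`` indices without replacement from a subset.

    Redraws (bounded) until both label classes are represented, which
    a later learn/validate split needs; a subset that cannot supply
    both classes raises.
    """
    n = len(subset)
    if not 1 <= s <= n:
        raise DegenerateSampleError(f"sample size {s} outside [1, {n}]")
    if s == n:
        return PixelSample(subset_id, subset.copy())
    for _ in range(MAX_RETRIES):
        idx = rng.choice(subset, size=s, replace=False)
        labels = data.labels[idx]
        if s == 1 or (labels.min() == 0 and labels.max() == 1):
            return PixelSample(subset_id, idx)
    raise DegenerateSampleError(
        f"could not draw a two-class sample of size {s} after {MAX_RETRIES} tries"
    )


def split_learn_validate(
    sample: PixelSample, pi: float, rng: np.random.Generator
) -> SplitPair:
    """Randomly split a sample into learning and validation parts.

    ``|learning| = round(s * pi / (pi + 1))`` (half-up), the rest
    validates.
    """
    if pi <= 0:
        raise DegenerateSampleError("pi must be > 0")
    s = sample.size
    t_size = math.floor(s * pi / (pi + 1.0) + 0.5)
    v_size = s - t_size
    if v_size < 1:
        raise DegenerateSampleError(
            f"validation set empty after rounding (s={s}, pi={pi})"
        )
    if t_size < 1:
        raise DegenerateSampleError(f"learning set empty (s={s}, pi={pi})")
    perm = rng.permutation(sample.indices)
    return SplitPair(perm[:t_size], perm[t_size:], pi)


def train_and_predict(
    split: SplitPair,
    data: PixelDataset,
    spec: ClassifierSpec,
    random_state: int | None = None,
) -> np.ndarray:
    """Train on the learning records, predict the validation records."""
    y_learn = data.labels[split.learning]
    if y_learn.min() == y_learn.max():
        raise DegenerateSampleError("degenerate learning set: single class")
    clf = spec.build(random_state=random_state)
    clf.fit(data.features[split.learning], y_learn)
    return np.asarray(clf.predict(data.features[split.validation]), dtype=np.uint8)


def sensitivity(
    y_true: np.ndarray, y_pred: np.ndarray, mode: str = "standard"
) -> float:
    """Sensitivity (true positive rate) of predicted vs observed labels.

    ``standard``: TP / actual positives.  ``literal_eq3``: predicted
    positives / actual positives — an audit mode that can exceed 1
    when the classifier over-predicts foreground.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    positives = int(y_true.sum())
    if positives == 0:
        raise DegenerateSampleError("no actual positives in validation set")
    if mode == "standard":
        return float((y_pred * y_true).sum() / positives)
    if mode == "literal_eq3":
        return float(y_pred.sum() / positives)
    raise ValueError(f"unknown sensitivity mode {mode!r}")


def _one_replicate(
    data: PixelDataset,
    subset: np.ndarray,
    s: int,
    pi: float,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    subset_id: int,
    mode: str,
) -> float:
    # a split whose validation part has no positives, or whose learning
    # part is single-class, is redrawn a bounded number of times; if the
    # sample itself cannot support a valid split (e.g. a single positive,
    # which can never sit in both parts), the whole replicate is redrawn
    for _ in range(MAX_RETRIES):
        sample = draw_sample(data, subset, s, rng, subset_id=subset_id)
        for _ in range(MAX_RETRIES):
            split = split_learn_validate(sample, pi, rng)
            y_true = data.labels[split.validation]
            y_learn = data.labels[split.learning]
            if y_true.sum() > 0 and y_learn.min() == 0 and y_learn.max() == 1:
                y_pred = train_and_predict(
                    split, data, spec, random_state=spawn_int(rng)
                )
                return sensitivity(y_true, y_pred, mode=mode)
    raise DegenerateSampleError(
        f"retry budget exhausted drawing a usable replicate at size {s}"
    )


def replicate_validation(
    data: PixelDataset,
    subset: np.ndarray,
    s: int,
    B: int,
    pi: float,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    subset_id: int = 0,
    mode: str = "standard",
) -> ReplicateStats:
    """``B`` independent draw + split + fit + score cycles at size ``s``."""
    if B < 2:
        raise ParsegError("B must be >= 2 (sample SD needs B-1 > 0)")
    phis = np.array(
        [
            _one_replicate(data, subset, s, pi, spec, rng, subset_id, mode)
            for _ in range(B)
        ]
    )
    return ReplicateStats(subset_id, s, phis)


def consistency_index(
    stats_s: ReplicateStats, stats_n: ReplicateStats
) -> ConsistencyIndex:
    """``psi = |phi_bar(s) - phi_bar(n)| * |sigma(s) - sigma(n)|``."""
    if stats_s.subset_id != stats_n.subset_id:
        raise ParsegError(
            f"subset mismatch: {stats_s.subset_id} vs {stats_n.subset_id}"
        )
    if stats_s.size > stats_n.size:
        raise ParsegError("reference stats must come from the full subset size")
    psi = abs(stats_s.phi_bar - stats_n.phi_bar) * abs(stats_s.sigma - stats_n.sigma)
    return ConsistencyIndex(stats_s.subset_id, stats_s.size, psi)
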