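"""Per-reaction normal/abnormal classifiers trained on weak labels.

One binary classifier is trained per reaction: a multilayer perceptron
with four hidden layers, softmax output and the Adam optimiser, fed the
reaction's trajectory resampled to a fixed length and min-max scaled per
series.  Hyperparameters (epochs, batch size, layer width) are tuned by
brute force over a 3x3x3 grid; reactions whose best network stays under
70% holdout accuracy — or whose weak labels contain a single class — are
dropped.  The surviving classifiers turn each simulation into a binary
flux profile: one bit per retained reaction, 1 meaning abnormal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .errors import (
    DegenerateInputError,
    DegenerateLabelError,
    InvalidArgumentError,
    MissingSeriesError,
)
from .types import FluxProfile, FluxSeries, SimulationRecord

#: the brute-force hyperparameter grid
EPOCH_GRID = (5, 10, 15)
BATCH_GRID = (50, 100, 150)
WIDTH_GRID = (750, 1500, 2250)

#: holdout accuracy below which a reaction's classifier is discarded
MIN_ACCURACY = 0.70

#: default fixed input length for the network
DEFAULT_INPUT_LENGTH = 500


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of one per-reaction network.

    Four hidden layers are fixed; ``width`` applies to every hidden
    layer.  ``epochs`` is the number of passes over the training data and
    ``batch_size`` the number of samples per weight update.
    """

    width: int = 750
    epochs: int = 10
    batch_size: int = 100
    hidden_layers: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers != 4:
            raise InvalidArgumentError("the architecture fixes 4 hidden layers")
        if min(self.width, self.epochs, self.batch_size) < 1:
            raise InvalidArgumentError(
                "width, epochs and batch_size must be positive"
            )


def full_grid(seed: int = 0) -> list[ClassifierSpec]:
    """The canonical 27-point grid: epochs x batch x width."""
    return [
        ClassifierSpec(width=w, epochs=e, batch_size=b, seed=seed)
        for e, b, w in product(EPOCH_GRID, BATCH_GRID, WIDTH_GRID)
    ]


def prepare_classifier_input(
    series: FluxSeries, target_length: int = DEFAULT_INPUT_LENGTH
) -> np.ndarray:
    """Resample a trajectory onto ``target_length`` uniform time points
    (linear interpolation) and min-max scale it to [0, 1] per series.

    A constant series has zero range and maps to the all-zero vector —
    the network then sees shape, not absolute flux magnitude.
    """
    if len(series) == 0:
        raise DegenerateInputError("empty series")
    if target_length < 1:
        raise InvalidArgumentError("target_length must be positive")
    t, y = series.times, series.values
    if len(series) == 1:
        resampled = np.full(target_length, y[0])
    else:
        grid = np.linspace(t[0], t[-1], target_length)
        resampled = np.interp(grid, t, y)
    lo, hi = resampled.min(), resampled.max()
    if hi == lo:
        return np.zeros(target_length)
    return (resampled - lo) / (hi - lo)


def _make_mlp(spec: ClassifierSpec, n_train: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(spec.width,) * spec.hidden_layers,
        solver="adam",
        batch_size=min(spec.batch_size, n_train),
        max_iter=spec.epochs,
        shuffle=True,
        random_state=spec.seed,
        # no internal early-stopping holdout: the split is managed here
        early_stopping=False,
    )


def _check_two_classes(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise DegenerateLabelError(
            "need >= 2 examples of each class to train and hold out"
        )


@dataclass
class TrainedClassifier:
    """A fitted per-reaction network plus what is needed to apply it."""

    reaction_id: str
    spec: ClassifierSpec
    model: MLPClassifier
    target_length: int
    holdout_accuracy: float

    def predict_series(self, series: FluxSeries) -> int:
        x = prepare_classifier_input(series, self.target_length)
        return int(self.model.predict(x[None, :])[0])


def train_reaction_classifier(
    inputs: np.ndarray,
    weak_labels: np.ndarray,
    spec: ClassifierSpec,
    reaction_id: str = "",
) -> TrainedClassifier:
    """Train one network on fixed-length inputs and report its accuracy
    on a stratified 20% holdout.

    The split, weight initialisation and shuffling are all seeded through
    ``spec.seed``, so the reported accuracy is reproducible run to run.
    """
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(weak_labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidArgumentError("inputs and labels must align")
    _check_two_classes(y)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=spec.seed
    )
    model = _make_mlp(spec, X_train.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_train, y_train)
    accuracy = float(model.score(X_test, y_test))
    return TrainedClassifier(
        reaction_id=reaction_id,
        spec=spec,
        model=model,
        target_length=X.shape[1],
        holdout_accuracy=accuracy,
    )


@dataclass(frozen=True)
class ClassifierRecord:
    """Registry row for one reaction's tuned classifier."""

    reaction_id: str
    spec: ClassifierSpec
    holdout_accuracy: float
    fold_accuracies: tuple[float, ...] = ()
    retained: bool = False

    @property
    def mean_cv_accuracy(self) -> float:
        if not self.fold_accuracies:
            return float("nan")
        return float(np.mean(self.fold_accuracies))


def grid_search(
    inputs: np.ndarray,
    weak_labels: np.ndarray,
    grid: Sequence[ClassifierSpec],
    reaction_id: str = "",
) -> tuple[TrainedClassifier, ClassifierRecord]:
    """Train every grid point and keep the most accurate network.

    Ties break toward fewer epochs, then smaller width, then larger
    batch, so the selected point is reproducible.
    """
    if not grid:
        raise InvalidArgumentError("empty hyperparameter grid")
    best: Optional[TrainedClassifier] = None
    best_key = None
    for spec in grid:
        trained = train_reaction_classifier(
            inputs, weak_labels, spec, reaction_id
        )
        key = (
            -trained.holdout_accuracy,
            spec.epochs,
            spec.width,
            -spec.batch_size,
        )
        if best is None or key < best_key:
            best, best_key = trained, key
    record = ClassifierRecord(
        reaction_id=reaction_id,
        spec=best.spec,
        holdout_accuracy=best.holdout_accuracy,
    )
    return best, record


def cross_validate(
    inputs: np.ndarray,
    weak_labels: np.ndarray,
    spec: ClassifierSpec,
    k: int = 10,
) -> tuple[float, ...]:
    """Stratified k-fold accuracies under one spec, as the overfitting
    check: a mean fold accuracy far below the holdout accuracy flags an
    over-tuned network."""
    X = np.asarray(inputs, dtype=float)
    y = np.asarray(weak_labels, dtype=int)
    if k < 2:
        raise InvalidArgumentError("k-fold needs k >= 2")
    if k > X.shape[0]:
        raise InvalidArgumentError(f"k={k} exceeds {X.shape[0]} examples")
    _check_two_classes(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        model = _make_mlp(spec, train_idx.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X[train_idx], y[train_idx])
        accs.append(float(model.score(X[test_idx], y[test_idx])))
    return tuple(accs)


def filter_classifiers(
    records: Sequence[ClassifierRecord], min_accuracy: float = MIN_ACCURACY
) -> list[ClassifierRecord]:
    """Keep records with holdout accuracy >= ``min_accuracy`` (exactly
    70% is kept), marked retained and ordered by reaction id."""
    kept = [
        replace(r, retained=True)
        for r in records
        if r.holdout_accuracy >= min_accuracy
    ]
    return sorted(kept, key=lambda r: r.reaction_id)


def make_flux_profile(
    simulation: SimulationRecord,
    classifiers: Mapping[str, TrainedClassifier],
) -> FluxProfile:
    """Classify each retained reaction's series in one simulation into a
    binary flux profile (bit order: sorted reaction id)."""
    reaction_ids = tuple(sorted(classifiers))
    bits = np.empty(len(reaction_ids), dtype=int)
    for i, rid in enumerate(reaction_ids):
        if rid not in simulation.series:
            raise MissingSeriesError(
                f"simulation {simulation.simulation_id} lacks series "
                f"for retained reaction {rid}"
            )
        bits[i] = classifiers[rid].predict_series(simulation.series[rid])
    return FluxProfile(
        simulation_id=simulation.simulation_id,
        reaction_ids=reaction_ids,
        bits=bits,
    )
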