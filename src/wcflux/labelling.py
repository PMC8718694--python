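"""Weak labelling of reaction normality from wild-type feature boundaries.

For one reaction, the 2-D principal-component scores of the wild-type
simulations define the range of normal behaviour.  Three axis-aligned
boxes of decreasing size are drawn around them — the extrema (bounding
box), a 99% box, and a 95% box, the latter two from per-axis empirical
percentiles — and each acts as a labelling function: a simulation whose
score falls outside the box is labelled abnormal.  The three noisy label
columns are then combined into one probabilistic weak label per simulation
by an agreement-weighted vote, a small transparent stand-in for a full
generative label model (which can be slotted in behind the same contract).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientReferenceError, InvalidArgumentError
from .types import ABNORMAL, NORMAL

#: per-axis percentile pairs of the three boundary schemes
SCHEMES = {
    "extrema": (0.0, 100.0),
    "ci99": (0.5, 99.5),
    "ci95": (2.5, 97.5),
}

#: labelling-function order used in every LabelMatrix
DEFAULT_SCHEMES = ("extrema", "ci99", "ci95")


@dataclass(frozen=True)
class Boundary:
    """Axis-aligned box in PC space marking the normal range.

    Points inside or on the box are normal (the boundary is closed: ties
    resolve toward normal, since only points *outside* are abnormal).
    """

    scheme: str
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise InvalidArgumentError("lower/upper must be 1-D and aligned")
        if np.any(lower > upper):
            raise InvalidArgumentError("boundary has lower > upper")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def contains(self, score: np.ndarray) -> bool:
        score = np.asarray(score, dtype=float)
        return bool(
            np.all(score >= self.lower) and np.all(score <= self.upper)
        )


def build_boundary(wildtype_scores: np.ndarray, scheme: str) -> Boundary:
    """Per-axis box around the wild-type scores.

    ``extrema`` is the exact bounding box; ``ci99`` / ``ci95`` are
    empirical per-axis percentile boxes ([0.5, 99.5] and [2.5, 97.5]).
    Needs at least 3 reference points.
    """
    if scheme not in SCHEMES:
        raise InvalidArgumentError(
            f"unknown scheme {scheme!r}; one of {sorted(SCHEMES)}"
        )
    X = np.atleast_2d(np.asarray(wildtype_scores, dtype=float))
    if X.shape[0] < 3:
        raise InsufficientReferenceError(
            f"need >= 3 wild-type points to build a boundary, got {X.shape[0]}"
        )
    lo_q, hi_q = SCHEMES[scheme]
    lower = np.percentile(X, lo_q, axis=0)
    upper = np.percentile(X, hi_q, axis=0)
    return Boundary(scheme=scheme, lower=lower, upper=upper)


def apply_labelling_function(boundary: Boundary, score: np.ndarray) -> int:
    """0 (normal) iff the score lies inside or on the closed box."""
    return NORMAL if boundary.contains(score) else ABNORMAL


def label_matrix(
    boundaries: Sequence[Boundary], scores: np.ndarray
) -> np.ndarray:
    """Apply every labelling function to every score: an n x k matrix of
    0/1 labels, one column per boundary. Labelling functions never
    abstain, so there are no missing entries."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    out = np.empty((scores.shape[0], len(boundaries)), dtype=int)
    for j, b in enumerate(boundaries):
        inside = np.all(
            (scores >= b.lower) & (scores <= b.upper), axis=1
        )
        out[:, j] = np.where(inside, NORMAL, ABNORMAL)
    return out


@dataclass(frozen=True)
class WeakLabel:
    """A combined label with the confidence of the emitted side,
    in [0.5, 1]."""

    label: int
    probability: float


def _agreement_weights(L: np.ndarray) -> np.ndarray:
    """Per-function weights from mean pairwise agreement.

    A labelling function that often agrees with the others is presumed
    more accurate and gets a larger vote.  With a single function the
    weight is 1; weights are floored at a small epsilon so a fully
    disagreeing function can still break what would otherwise be an
    empty vote.
    """
    n, k = L.shape
    if k == 1:
        return np.ones(1)
    agree = np.zeros(k)
    for j in range(k):
        others = [m for m in range(k) if m != j]
        agree[j] = np.mean(
            [(L[:, j] == L[:, m]).mean() for m in others]
        )
    return np.maximum(agree, 1e-6)


def combine_labels(L: np.ndarray) -> list[WeakLabel]:
    """Collapse a label matrix to one probabilistic weak label per row.

    Each labelling function's accuracy is estimated from its mean
    agreement rate with the other functions; each row is then decided by
    an accuracy-weighted vote, with probability the winning side's share
    of the total vote mass.  Unanimous rows get probability 1; with two
    label values the winner's share is always >= 0.5.  Ties (impossible
    with 3 functions under equal weights) break toward normal, matching
    the convention that only clear outliers are abnormal.
    """
    L = np.asarray(L)
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 1:
        raise InvalidArgumentError("label matrix must be non-empty 2-D")
    if not np.isin(L, (NORMAL, ABNORMAL)).all():
        raise InvalidArgumentError("label matrix entries must be 0/1")
    w = _agreement_weights(L)
    total = float(w.sum())
    out = []
    for row in L:
        mass_abnormal = float(w[row == ABNORMAL].sum())
        mass_normal = total - mass_abnormal
        if mass_abnormal > mass_normal:
            label, prob = ABNORMAL, mass_abnormal / total
        else:
            label, prob = NORMAL, mass_normal / total
        out.append(WeakLabel(label=label, probability=prob))
    return out


def weak_label_reaction(
    wildtype_scores: np.ndarray,
    all_scores: np.ndarray,
    schemes: Sequence[str] = DEFAULT_SCHEMES,
) -> list[WeakLabel]:
    """End-to-end weak labelling for one reaction: build the boundary set
    from wild-type scores, label every simulation's score with each
    boundary, and combine the columns into probabilistic labels."""
    boundaries = [build_boundary(wildtype_scores, s) for s in schemes]
    L = label_matrix(boundaries, all_scores)
    return combine_labels(L)
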