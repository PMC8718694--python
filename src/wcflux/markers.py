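"""Phenotype classification and marker-reaction discovery.

A knockout simulation's phenotype class is read off a fixed table of
production flags (DNA, RNA, protein production; growth; division).  The
slow-growing and septum-disruption classes share a printed flag row and are
told apart by whether division was initiated before the simulation ended.

Marker discovery asks which driver reactions of the metabolic network
individually predict phenotype: flux profiles are reduced to two principal
components, a linear support-vector machine is fitted per driver reaction
on its normal/abnormal split of the 2-D points, and the association between
a reaction's abnormality and membership of each phenotype class is scored
with the phi coefficient.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .errors import (
    DegenerateLabelError,
    InvalidArgumentError,
    UnclassifiedPhenotypeError,
    UndefinedStatisticError,
    DegenerateFitWarning,
)
from .features import ReducedScores
from .network import DriverSet
from .types import PhenotypeClass, PhenotypeFlags

# Flag rows of the phenotype table, keyed (dna, rna, protein, growth,
# division). The (T, T, T, T, F) row is shared by slow_growing and septum
# and resolved by division_initiated.
_FLAG_ROWS: dict[tuple[bool, ...], PhenotypeClass] = {
    (False, False, False, False, False): PhenotypeClass.METABOLIC,
    (True, False, False, False, False): PhenotypeClass.RNA,
    (True, True, False, False, False): PhenotypeClass.PROTEIN,
    (False, True, True, True, False): PhenotypeClass.DNA,
    (True, True, True, True, True): PhenotypeClass.NON_ESSENTIAL,
}

_AMBIGUOUS_ROW = (True, True, True, True, False)


def classify_phenotype(flags: PhenotypeFlags) -> PhenotypeClass:
    """Map production flags to a phenotype class.

    Raises
    ------
    UnclassifiedPhenotypeError
        If the flag combination is not a row of the class table. Unlisted
        combinations are never guessed.
    """
    key = (flags.dna, flags.rna, flags.protein, flags.growth, flags.division)
    if key == _AMBIGUOUS_ROW:
        return (
            PhenotypeClass.SLOW_GROWING
            if flags.division_initiated
            else PhenotypeClass.SEPTUM
        )
    try:
        return _FLAG_ROWS[key]
    except KeyError:
        raise UnclassifiedPhenotypeError(
            f"flag combination {key} is not in the phenotype class table"
        ) from None


def flags_for_class(phenotype_class: PhenotypeClass) -> PhenotypeFlags:
    """Canonical flag combination for a phenotype class (the inverse of
    :func:`classify_phenotype` on the table's rows)."""
    if phenotype_class is PhenotypeClass.SLOW_GROWING:
        return PhenotypeFlags(*_AMBIGUOUS_ROW, division_initiated=True)
    if phenotype_class is PhenotypeClass.SEPTUM:
        return PhenotypeFlags(*_AMBIGUOUS_ROW, division_initiated=False)
    for row, cls in _FLAG_ROWS.items():
        if cls is phenotype_class:
            return PhenotypeFlags(*row)
    raise InvalidArgumentError(f"unknown phenotype class {phenotype_class!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 association test.

    Rows are reaction behaviour (normal / abnormal), columns are class
    membership (in-class / out-of-class)::

                       in-class   out-of-class
        normal            a            b
        abnormal          c            d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidArgumentError("contingency counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise InvalidArgumentError("contingency table is empty")


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """Phi coefficient of a 2x2 contingency table.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) — the Pearson correlation
    of two binary variables. Undefined when any margin is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise UndefinedStatisticError(
            f"phi undefined: zero margin in table ({a},{b};{c},{d})"
        )
    return (a * d - b * c) / math.sqrt(math.prod(margins))


def contingency_from_labels(
    reaction_abnormal: np.ndarray, in_class: np.ndarray
) -> ContingencyTable2x2:
    """Tabulate per-simulation reaction abnormality against class
    membership."""
    reaction_abnormal = np.asarray(reaction_abnormal, dtype=bool)
    in_class = np.asarray(in_class, dtype=bool)
    if reaction_abnormal.shape != in_class.shape:
        raise InvalidArgumentError("label vectors must have equal length")
    return ContingencyTable2x2(
        a=int(np.sum(~reaction_abnormal & in_class)),
        b=int(np.sum(~reaction_abnormal & ~in_class)),
        c=int(np.sum(reaction_abnormal & in_class)),
        d=int(np.sum(reaction_abnormal & ~in_class)),
    )


def reduce_profiles(
    profile_matrix: np.ndarray, n_components: int = 2
) -> ReducedScores:
    """Centred PCA of the simulations x reactions binary profile matrix.

    Bits share a scale, so no per-column standardisation is applied.  A
    matrix of identical profiles has zero variance; the scores are then all
    zeros and a :class:`DegenerateFitWarning` is emitted.
    """
    X = np.asarray(profile_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidArgumentError(
            "profile matrix must be 2-D with at least 2 simulations"
        )
    if np.allclose(X, X[0]):
        warnings.warn(
            "all flux profiles identical; PCA is degenerate, returning "
            "zero scores",
            DegenerateFitWarning,
        )
        k = min(n_components, X.shape[1])
        return ReducedScores(
            scores=np.zeros((X.shape[0], k)),
            explained_variance_fraction=0.0,
            loadings=np.eye(X.shape[1], k),
            feature_means=X[0].copy(),
            feature_scales=np.ones(X.shape[1]),
        )
    n_components = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-magnitude loading entry positive per axis
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return ReducedScores(
        scores=scores,
        explained_variance_fraction=float(
            np.sum(pca.explained_variance_ratio_)
        ),
        loadings=loadings,
        feature_means=pca.mean_.copy(),
        feature_scales=np.ones(X.shape[1]),
    )


@dataclass(frozen=True)
class SeparabilityResult:
    """Outcome of the per-reaction linear-separability test in profile-PC
    space: the fitted hyperplane, its training accuracy, and whether it
    clears the pass threshold."""

    reaction_id: str
    weights: np.ndarray
    offset: float
    accuracy: float
    passes: bool


def svm_separability(
    scores: np.ndarray,
    reaction_normality: np.ndarray,
    reaction_id: str = "",
    pass_accuracy: float = 0.95,
) -> SeparabilityResult:
    """Fit a linear SVM splitting 2-D profile scores by one reaction's
    normality and report its training accuracy.

    Accuracy is evaluated on the fitted points themselves: the question is
    whether the plotted point cloud is linearly separable by this
    reaction's behaviour, not generalisation. ``passes`` requires accuracy
    strictly above ``pass_accuracy``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(reaction_normality, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != y.shape[0]:
        raise InvalidArgumentError("scores and labels must align")
    if np.unique(y).size < 2:
        raise DegenerateLabelError(
            f"reaction {reaction_id or '<anon>'}: single-class labels"
        )
    svm = SVC(kernel="linear", C=1.0, random_state=0)
    svm.fit(scores, y)
    accuracy = float(svm.score(scores, y))
    return SeparabilityResult(
        reaction_id=reaction_id,
        weights=svm.coef_[0].copy(),
        offset=float(svm.intercept_[0]),
        accuracy=accuracy,
        passes=accuracy > pass_accuracy,
    )


def marker_report(
    drivers: DriverSet,
    separability: Mapping[str, SeparabilityResult],
    phi_by_class: Mapping[str, Mapping[PhenotypeClass, float]],
    pathways: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """One row per driver reaction: pathway annotation, separability pass
    flag, and the phenotype class with the strongest phi association.

    ``phi_by_class[r]`` maps each phenotype class to the phi coefficient
    between reaction ``r``'s abnormality and membership of that class;
    the best class maximises |phi|.
    """
    rows = []
    for rid in sorted(drivers.drivers):
        sep = separability.get(rid)
        phis = phi_by_class.get(rid, {})
        if phis:
            best_class = max(phis, key=lambda c: abs(phis[c]))
            best_phi = phis[best_class]
        else:
            best_class, best_phi = None, float("nan")
        rows.append(
            {
                "reaction_id": rid,
                "pathways": ";".join(pathways.get(rid, ["n/a"]))
                if pathways
                else "n/a",
                "separability_accuracy": sep.accuracy if sep else float("nan"),
                "separable": bool(sep.passes) if sep else False,
                "best_class": best_class.value if best_class else "n/a",
                "best_phi": best_phi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "reaction_id",
            "pathways",
            "separability_accuracy",
            "separable",
            "best_class",
            "best_phi",
        ],
    )
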