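"""Shared domain containers.

The pipeline moves a small set of objects between stages: per-reaction flux
trajectories grouped into simulation records, regression feature vectors,
2-D principal-component scores, binary flux profiles, and phenotype flags.
They are plain frozen/slotted dataclasses over numpy arrays — cheap to
construct in bulk and trivially serialisable to the TSV interchange formats
in :mod:`wcflux.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from .errors import InvalidArgumentError

NORMAL = 0
ABNORMAL = 1

WILD_TYPE = "wild_type"

#: Identifier prefix marking a transport (boundary-crossing) reaction.
TRANSPORT_PREFIX = "TX_"


@dataclass(frozen=True)
class FluxSeries:
    """One reaction's flux trajectory in one simulation.

    Parameters
    ----------
    times : array of float
        Time points in seconds, strictly increasing.
    values : array of float
        Flux at each time point. Negative values are legal (reversible
        reactions run backwards).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1 or times.shape != values.shape:
            raise InvalidArgumentError(
                "times and values must be 1-D arrays of equal length"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


class PhenotypeClass(str, Enum):
    """Phenotypic class of a knockout simulation, determined by which
    substances the simulated cell still produces and whether it grows
    and divides."""

    METABOLIC = "metabolic"
    RNA = "rna"
    PROTEIN = "protein"
    SLOW_GROWING = "slow_growing"
    DNA = "dna"
    SEPTUM = "septum"
    NON_ESSENTIAL = "non_essential"


@dataclass(frozen=True)
class PhenotypeFlags:
    """Per-simulation production/behaviour booleans.

    ``dna``, ``rna`` and ``protein`` mean active production of that
    substance; ``growth`` and ``division`` that the cell grows / completes
    division. ``division_initiated`` is an auxiliary flag distinguishing a
    slow-growing cell (division starts near the end of the simulated life
    cycle but does not complete) from a septum-disrupted one (division
    never starts); a completed division implies an initiated one.
    """

    dna: bool
    rna: bool
    protein: bool
    growth: bool
    division: bool
    division_initiated: bool = False

    def __post_init__(self):
        if self.division and not self.division_initiated:
            object.__setattr__(self, "division_initiated", True)


@dataclass
class SimulationRecord:
    """All flux series of one simulation, plus optional ground truth.

    ``truth_labels`` maps reaction id to 0 (normal) / 1 (abnormal) and is
    present only for synthetic ensembles, where the generator knows which
    reactions it perturbed.
    """

    simulation_id: str
    genotype: str
    series: Mapping[str, FluxSeries]
    truth_labels: Optional[Mapping[str, int]] = None
    phenotype_flags: Optional[PhenotypeFlags] = None

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.series)


@dataclass(frozen=True)
class FeatureVector:
    """Summary of a flux trajectory by an ordinary least-squares line fit:
    intercept and gradient of the fitted line, coefficient of
    determination, and mean squared residual."""

    intercept: float
    gradient: float
    r_squared: float
    mse: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intercept, self.gradient, self.r_squared, self.mse]
        )

    #: Column order used everywhere a feature matrix is assembled.
    FIELDS = ("intercept", "gradient", "r_squared", "mse")


@dataclass(frozen=True)
class FluxProfile:
    """Binary abnormality fingerprint of one simulation: one bit per
    retained reaction, 0 = normal, 1 = abnormal."""

    simulation_id: str
    reaction_ids: tuple[str, ...]
    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=int)
        if bits.shape != (len(self.reaction_ids),):
            raise InvalidArgumentError(
                "profile length must equal the retained-reaction count"
            )
        if not np.isin(bits, (0, 1)).all():
            raise InvalidArgumentError("profile bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Signed integer stoichiometric coefficients, metabolites x reactions.

    Transport reactions are identified purely by the ``TX_`` id prefix.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    coefficients: np.ndarray

    def __post_init__(self):
        coeff = np.asarray(self.coefficients)
        if coeff.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise InvalidArgumentError(
                "coefficient shape must be (n_metabolites, n_reactions)"
            )
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise InvalidArgumentError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise InvalidArgumentError("duplicate reaction ids")
        object.__setattr__(self, "coefficients", coeff)

    def is_transport(self, reaction_id: str) -> bool:
        return reaction_id.startswith(TRANSPORT_PREFIX)
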