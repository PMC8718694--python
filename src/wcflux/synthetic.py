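"""Synthetic flux ensembles with known ground truth.

Whole-cell-model metabolic fluxes vary drastically between reactions —
some sit at steady levels, some ramp through the cell cycle, some
oscillate strongly or fire in bursts.  This module generates ensembles
that emulate that variety so every downstream stage (feature extraction,
weak labelling, classification, profiling, network analysis) can be
exercised and validated against known truth labels without the original
multi-hundred-gigabyte simulation archive.

A wild-type ensemble draws each reaction's trajectory from its archetype
with per-simulation parameter jitter (the source model is stochastic: the
same genotype shows a range of behaviours).  A knockout ensemble applies
perturbations — slope, amplitude or offset shifts, or a collapse to zero
flux — to a chosen reaction subset and records exactly those reactions as
abnormal in the truth labels.  Random stoichiometric matrices with
transport reactions (``TX_`` prefix) provide graph fixtures for the
driver-node analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, MissingSeriesError
from .markers import flags_for_class
from .types import (
    ABNORMAL,
    NORMAL,
    WILD_TYPE,
    FluxSeries,
    PhenotypeClass,
    SimulationRecord,
    StoichiometricMatrix,
    TRANSPORT_PREFIX,
)

KINDS = ("steady", "ramp", "oscillation", "step", "burst")
MODES = ("slope_shift", "amplitude_shift", "offset_shift", "collapse_to_zero")

#: default time grid: a 50,000 s cell cycle sampled every 100 s
DEFAULT_DURATION_S = 50_000.0
DEFAULT_DT_S = 100.0

#: relative per-simulation jitter of archetype parameters
DEFAULT_JITTER = 0.10


@dataclass(frozen=True)
class ReactionArchetype:
    """Parametric shape of one reaction's wild-type flux.

    kind:
        ``steady`` — constant at ``baseline``;
        ``ramp`` — ``baseline + slope * t``;
        ``oscillation`` — sinusoid of ``amplitude`` and ``period`` around
        ``baseline`` (random phase per simulation);
        ``step`` — jumps from ``baseline`` to ``baseline + amplitude``
        halfway through the cycle;
        ``burst`` — rectangular pulses of height ``amplitude`` at
        Poisson-distributed times with mean spacing ``period``.
    Gaussian noise of sd ``noise_sd`` is added to every kind.
    """

    reaction_id: str
    kind: str = "steady"
    baseline: float = 1.0
    slope: float = 0.0
    amplitude: float = 0.0
    period: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidArgumentError(
                f"unknown archetype kind {self.kind!r}; one of {KINDS}"
            )
        if self.kind in ("oscillation", "burst") and self.period <= 0:
            raise InvalidArgumentError(
                f"{self.kind} archetype needs period > 0"
            )
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PerturbationSpec:
    """How a knockout disturbs one reaction.

    ``effect_size`` is a dimensionless multiple of the wild-type
    parameter's own scale: a slope_shift of effect_size e adds a trend
    that moves the flux by e x the baseline scale over the cell cycle; an
    amplitude_shift / offset_shift adds e x the parameter's scale.
    ``collapse_to_zero`` forces the flux to exactly zero and ignores
    ``effect_size``.
    """

    reaction_id: str
    mode: str = "offset_shift"
    effect_size: float = 5.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidArgumentError(
                f"unknown perturbation mode {self.mode!r}; one of {MODES}"
            )
        if self.effect_size < 0:
            raise InvalidArgumentError("effect_size must be >= 0")


def _time_grid(duration_s: float, dt_s: float) -> np.ndarray:
    if duration_s <= 0 or dt_s <= 0:
        raise InvalidArgumentError("duration_s and dt_s must be positive")
    n = int(round(duration_s / dt_s))
    if n < 2:
        raise InvalidArgumentError("time grid needs at least 2 points")
    return np.arange(n, dtype=float) * dt_s


def _scale(value: float, fallback: float = 1.0) -> float:
    return abs(value) if value != 0 else fallback


def _simulate_series(
    arch: ReactionArchetype,
    times: np.ndarray,
    rng: np.random.Generator,
    jitter: float,
    perturbation: Optional[PerturbationSpec] = None,
) -> FluxSeries:
    if perturbation is not None and perturbation.mode == "collapse_to_zero":
        return FluxSeries(times=times, values=np.zeros_like(times))

    j = lambda: 1.0 + rng.uniform(-jitter, jitter)  # noqa: E731
    baseline = arch.baseline * j()
    slope = arch.slope * (j() if arch.slope else 1.0)
    amplitude = arch.amplitude * (j() if arch.amplitude else 1.0)
    duration = times[-1] - times[0] if times.size > 1 else 1.0

    if perturbation is not None:
        e = perturbation.effect_size
        if perturbation.mode == "slope_shift":
            slope += e * _scale(arch.baseline) / max(duration, 1.0)
        elif perturbation.mode == "amplitude_shift":
            amplitude += e * _scale(arch.amplitude, _scale(arch.baseline))
        elif perturbation.mode == "offset_shift":
            baseline += e * _scale(arch.baseline)

    if arch.kind == "steady":
        values = np.full_like(times, baseline)
    elif arch.kind == "ramp":
        values = baseline + slope * times
    elif arch.kind == "oscillation":
        phase = rng.uniform(0.0, 2.0 * math.pi)
        values = baseline + amplitude * np.sin(
            2.0 * math.pi * times / arch.period + phase
        )
    elif arch.kind == "step":
        values = np.where(
            times < times[0] + duration / 2.0, baseline, baseline + amplitude
        )
    else:  # burst
        values = np.full_like(times, baseline)
        width = max(arch.period / 5.0, times[1] - times[0])
        t = times[0] + rng.exponential(arch.period)
        while t < times[-1]:
            values[(times >= t) & (times < t + width)] += amplitude
            t += width + rng.exponential(arch.period)
    # a shifted slope applies to every kind: a knocked-out reaction can
    # drift even if its wild-type shape has no trend
    if arch.kind != "ramp" and slope != 0.0:
        values = values + slope * times
    if arch.noise_sd > 0:
        values = values + rng.normal(0.0, arch.noise_sd, size=times.shape)
    return FluxSeries(times=times, values=values)


def _check_archetypes(archetypes: Sequence[ReactionArchetype]) -> None:
    ids = [a.reaction_id for a in archetypes]
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate reaction ids in archetypes")


def generate_wildtype_ensemble(
    archetypes: Sequence[ReactionArchetype],
    n_sims: int,
    duration_s: float = DEFAULT_DURATION_S,
    dt_s: float = DEFAULT_DT_S,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    id_prefix: str = "WT",
) -> list[SimulationRecord]:
    """Simulate ``n_sims`` wild-type cells; every reaction's truth label
    is normal.  The same seed reproduces the ensemble bit for bit."""
    _check_archetypes(archetypes)
    if n_sims < 0:
        raise InvalidArgumentError("n_sims must be >= 0")
    times = _time_grid(duration_s, dt_s)
    streams = np.random.SeedSequence(seed).spawn(max(n_sims, 1))
    records = []
    for i in range(n_sims):
        rng = np.random.default_rng(streams[i])
        series = {
            a.reaction_id: _simulate_series(a, times, rng, jitter)
            for a in archetypes
        }
        records.append(
            SimulationRecord(
                simulation_id=f"{id_prefix}_{i:04d}",
                genotype=WILD_TYPE,
                series=series,
                truth_labels={a.reaction_id: NORMAL for a in archetypes},
            )
        )
    return records


def generate_knockout_ensemble(
    archetypes: Sequence[ReactionArchetype],
    phenotype_class: PhenotypeClass,
    perturbations: Sequence[PerturbationSpec],
    n_sims: int,
    duration_s: float = DEFAULT_DURATION_S,
    dt_s: float = DEFAULT_DT_S,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    genotype: Optional[str] = None,
    id_prefix: Optional[str] = None,
) -> list[SimulationRecord]:
    """Simulate ``n_sims`` knockout cells of one genotype.

    Exactly the perturbed reactions carry abnormal truth labels; every
    record's phenotype flags are the canonical combination of
    ``phenotype_class``.
    """
    _check_archetypes(archetypes)
    if n_sims < 0:
        raise InvalidArgumentError("n_sims must be >= 0")
    by_id = {a.reaction_id: a for a in archetypes}
    perturbed: dict[str, PerturbationSpec] = {}
    for p in perturbations:
        if p.reaction_id not in by_id:
            raise MissingSeriesError(
                f"perturbation targets unknown reaction {p.reaction_id!r}"
            )
        perturbed[p.reaction_id] = p
    genotype = genotype or f"KO_{phenotype_class.value}"
    id_prefix = id_prefix or genotype
    flags = flags_for_class(phenotype_class)
    truth = {
        rid: (ABNORMAL if rid in perturbed else NORMAL) for rid in by_id
    }
    times = _time_grid(duration_s, dt_s)
    streams = np.random.SeedSequence(seed).spawn(max(n_sims, 1))
    records = []
    for i in range(n_sims):
        rng = np.random.default_rng(streams[i])
        series = {
            a.reaction_id: _simulate_series(
                a, times, rng, jitter, perturbed.get(a.reaction_id)
            )
            for a in archetypes
        }
        records.append(
            SimulationRecord(
                simulation_id=f"{id_prefix}_{i:04d}",
                genotype=genotype,
                series=series,
                truth_labels=dict(truth),
                phenotype_flags=flags,
            )
        )
    return records


def default_archetypes(
    n_reactions: int, seed: int = 0
) -> list[ReactionArchetype]:
    """A mixed bag of archetypes cycling through the five kinds, with
    randomised baselines, trends, amplitudes and noise levels."""
    rng = np.random.default_rng(seed)
    archetypes = []
    for i in range(n_reactions):
        kind = KINDS[i % len(KINDS)]
        baseline = float(rng.uniform(0.5, 20.0))
        archetypes.append(
            ReactionArchetype(
                reaction_id=f"R_{i:04d}",
                kind=kind,
                baseline=baseline,
                slope=(
                    float(rng.uniform(-1, 1)) * baseline / DEFAULT_DURATION_S
                    if kind == "ramp"
                    else 0.0
                ),
                amplitude=(
                    float(rng.uniform(0.3, 1.0)) * baseline
                    if kind in ("oscillation", "step", "burst")
                    else 0.0
                ),
                period=(
                    float(rng.uniform(2_000, 10_000))
                    if kind in ("oscillation", "burst")
                    else 0.0
                ),
                noise_sd=float(rng.uniform(0.01, 0.05)) * baseline,
            )
        )
    return archetypes


def generate_stoichiometric_matrix(
    n_metabolites: int,
    n_internal_reactions: int,
    n_transport_reactions: int,
    connectivity: float = 3.0,
    seed: int = 0,
) -> StoichiometricMatrix:
    """Random signed stoichiometric matrix with transport reactions.

    Internal reactions consume/produce random internal metabolite subsets
    (on average ``connectivity`` substrates each); every transport
    reaction gets its own boundary metabolite row and touches exactly one
    internal metabolite plus that boundary metabolite, mirroring uptake
    and secretion across the cell membrane.
    """
    if min(n_metabolites, n_internal_reactions, n_transport_reactions) < 0:
        raise InvalidArgumentError("counts must be >= 0")
    if connectivity < 1:
        raise InvalidArgumentError("connectivity must be >= 1")
    if (n_internal_reactions or n_transport_reactions) and n_metabolites < 2:
        raise InvalidArgumentError(
            "need >= 2 internal metabolites to build reactions"
        )
    rng = np.random.default_rng(seed)
    metabolites = [f"M_{i:04d}" for i in range(n_metabolites)]
    boundary = [f"B_{i:04d}" for i in range(n_transport_reactions)]
    reactions = [f"R_{i:04d}" for i in range(n_internal_reactions)] + [
        f"{TRANSPORT_PREFIX}{i:04d}" for i in range(n_transport_reactions)
    ]
    S = np.zeros(
        (n_metabolites + len(boundary), len(reactions)), dtype=int
    )
    for j in range(n_internal_reactions):
        n_sub = min(
            1 + rng.poisson(connectivity - 1.0), max(n_metabolites - 1, 1)
        )
        subs = rng.choice(n_metabolites, size=n_sub, replace=False)
        remaining = np.setdiff1d(np.arange(n_metabolites), subs)
        n_prod = min(1 + rng.poisson(connectivity - 1.0), remaining.size)
        prods = rng.choice(remaining, size=n_prod, replace=False)
        S[subs, j] = -rng.integers(1, 3, size=n_sub)
        S[prods, j] = rng.integers(1, 3, size=n_prod)
    for k in range(n_transport_reactions):
        j = n_internal_reactions + k
        internal = int(rng.integers(0, n_metabolites))
        S[internal, j] = 1
        S[n_metabolites + k, j] = -1
    return StoichiometricMatrix(
        metabolite_ids=tuple(metabolites + boundary),
        reaction_ids=tuple(reactions),
        coefficients=S,
    )
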