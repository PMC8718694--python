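"""The package's reference synthetic study.

A fixed, fully specified ensemble used by the documentation, the test
suite and the acceptance script: 20 reactions of mixed archetype, 60
wild-type simulations, and 200 knockout simulations spread over four
phenotype classes (50 each).  Each knockout class strongly perturbs a
known reaction subset (effect size 6, mostly trend shifts plus one flux
collapse), and one reaction — the planted marker — is perturbed in exactly
one class, so the end of the pipeline should rediscover it as a
class-specific marker.  A matching stoichiometric network places the
reactions on a chain, keeps the marker isolated (an isolated node is
always a driver node), and adds transport reactions at the boundary.

Everything is deterministic in ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import (
    PerturbationSpec,
    ReactionArchetype,
    default_archetypes,
    generate_knockout_ensemble,
    generate_wildtype_ensemble,
)
from .types import (
    PhenotypeClass,
    SimulationRecord,
    StoichiometricMatrix,
    TRANSPORT_PREFIX,
)

#: study conditions
N_REACTIONS = 20
N_WILDTYPE = 60
N_KNOCKOUT_PER_CLASS = 50
DURATION_S = 50_000.0
DT_S = 100.0
EFFECT_SIZE = 6.0

#: the reaction perturbed in exactly one class
MARKER_REACTION = "R_0010"
MARKER_CLASS = PhenotypeClass.METABOLIC

#: per-class perturbed reaction indices (R_%04d)
CLASS_PERTURBATIONS: dict[PhenotypeClass, tuple[int, ...]] = {
    PhenotypeClass.METABOLIC: (0, 1, 2, 3, 4, 5, 10),
    PhenotypeClass.RNA: (2, 3, 4, 5, 6, 7),
    PhenotypeClass.PROTEIN: (6, 7, 8, 9),
    PhenotypeClass.NON_ESSENTIAL: (),
}


@dataclass
class BenchmarkStudy:
    """The assembled reference study and its ground truth."""

    records: list[SimulationRecord]
    archetypes: list[ReactionArchetype]
    stoichiometry: StoichiometricMatrix
    perturbed_by_class: dict[PhenotypeClass, tuple[str, ...]]
    marker_reaction: str = MARKER_REACTION
    marker_class: PhenotypeClass = MARKER_CLASS

    @property
    def perturbed_reactions(self) -> set[str]:
        return set().union(*self.perturbed_by_class.values())


def _perturbations(
    archetypes: list[ReactionArchetype], indices: tuple[int, ...]
) -> list[PerturbationSpec]:
    specs = []
    for i in indices:
        rid = archetypes[i].reaction_id
        # one flux collapse per study; every other perturbation is a
        # strong trend shift, visible in both feature and trajectory space
        mode = "collapse_to_zero" if i == 5 else "slope_shift"
        specs.append(
            PerturbationSpec(
                reaction_id=rid, mode=mode, effect_size=EFFECT_SIZE
            )
        )
    return specs


def benchmark_ensemble(seed: int = 1) -> BenchmarkStudy:
    """Generate the reference study at its canonical size."""
    archetypes = default_archetypes(N_REACTIONS, seed=seed)
    records = generate_wildtype_ensemble(
        archetypes,
        N_WILDTYPE,
        duration_s=DURATION_S,
        dt_s=DT_S,
        seed=seed,
    )
    perturbed_by_class = {}
    for k, (cls, idxs) in enumerate(sorted(CLASS_PERTURBATIONS.items())):
        perturbations = _perturbations(archetypes, idxs)
        records += generate_knockout_ensemble(
            archetypes,
            cls,
            perturbations,
            N_KNOCKOUT_PER_CLASS,
            duration_s=DURATION_S,
            dt_s=DT_S,
            seed=seed + 1_000 * (k + 1),
        )
        perturbed_by_class[cls] = tuple(p.reaction_id for p in perturbations)
    return BenchmarkStudy(
        records=records,
        archetypes=archetypes,
        stoichiometry=benchmark_stoichiometry(
            [a.reaction_id for a in archetypes]
        ),
        perturbed_by_class=perturbed_by_class,
    )


def benchmark_stoichiometry(
    reaction_ids: list[str],
    isolated: tuple[str, ...] = (MARKER_REACTION,),
    n_transport: int = 3,
) -> StoichiometricMatrix:
    """Chain-structured stoichiometric matrix over the study reactions.

    Non-isolated reactions form a metabolic chain (reaction i consumes the
    chain metabolite produced by reaction i-1), so the reaction graph is a
    path; each isolated reaction gets private metabolites and becomes an
    isolated node, hence a guaranteed driver.  ``n_transport`` transport
    reactions import the first chain metabolites across the boundary.
    """
    chain = [r for r in reaction_ids if r not in isolated]
    n_transport = min(n_transport, len(chain))
    metabolites: list[str] = [f"M_{i:04d}" for i in range(len(chain) + 1)]
    reactions = list(reaction_ids) + [
        f"{TRANSPORT_PREFIX}{i:04d}" for i in range(n_transport)
    ]
    priv = {rid: (f"P_{rid}_a", f"P_{rid}_b") for rid in isolated}
    for a, b in priv.values():
        metabolites += [a, b]
    boundary = [f"B_{i:04d}" for i in range(n_transport)]
    metabolites += boundary
    m_index = {m: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)), dtype=int)
    r_index = {r: j for j, r in enumerate(reactions)}
    for i, rid in enumerate(chain):
        S[m_index[f"M_{i:04d}"], r_index[rid]] = -1
        S[m_index[f"M_{i + 1:04d}"], r_index[rid]] = 1
    for rid, (a, b) in priv.items():
        S[m_index[a], r_index[rid]] = -1
        S[m_index[b], r_index[rid]] = 1
    for k in range(n_transport):
        j = r_index[f"{TRANSPORT_PREFIX}{k:04d}"]
        S[m_index[boundary[k]], j] = -1
        S[m_index[f"M_{k:04d}"], j] = 1
    return StoichiometricMatrix(
        metabolite_ids=tuple(metabolites),
        reaction_ids=tuple(reactions),
        coefficients=S,
    )
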