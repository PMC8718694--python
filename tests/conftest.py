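import numpy as np
import pytest

from wcflux import (
    PerturbationSpec,
    ReactionArchetype,
    generate_knockout_ensemble,
    generate_wildtype_ensemble,
)
from wcflux.types import PhenotypeClass


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mixed_archetypes():
    """One archetype of each kind, modest noise."""
    return [
        ReactionArchetype("R_A", kind="steady", baseline=5.0, noise_sd=0.1),
        ReactionArchetype(
            "R_B", kind="ramp", baseline=2.0, slope=1e-4, noise_sd=0.05
        ),
        ReactionArchetype(
            "R_C",
            kind="oscillation",
            baseline=3.0,
            amplitude=1.0,
            period=5_000.0,
            noise_sd=0.05,
        ),
        ReactionArchetype(
            "R_D", kind="step", baseline=1.0, amplitude=2.0, noise_sd=0.05
        ),
        ReactionArchetype(
            "R_E",
            kind="burst",
            baseline=0.5,
            amplitude=3.0,
            period=6_000.0,
            noise_sd=0.05,
        ),
    ]


@pytest.fixture
def small_ensemble(mixed_archetypes):
    """12 wild-type + 10 knockout simulations on a short grid; knockouts
    strongly perturb R_A (trend) and R_B (collapse)."""
    wt = generate_wildtype_ensemble(
        mixed_archetypes, 12, duration_s=10_000, dt_s=100, seed=101
    )
    ko = generate_knockout_ensemble(
        mixed_archetypes,
        PhenotypeClass.METABOLIC,
        [
            PerturbationSpec("R_A", "slope_shift", 6.0),
            PerturbationSpec("R_B", "collapse_to_zero"),
        ],
        10,
        duration_s=10_000,
        dt_s=100,
        seed=202,
    )
    return wt + ko
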