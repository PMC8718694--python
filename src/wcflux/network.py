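"""Stoichiometric-network structure: reaction graph, driver nodes,
abnormality frequencies, and per-class affected sub-networks.

The metabolic network is viewed as an undirected reaction graph: binarise
the stoichiometric matrix S entrywise and form SᵀS, so two reactions are
adjacent iff they share at least one metabolite.  Driver nodes — the
reactions that must be controlled to control the whole network — are the
nodes left unmatched by a matching of that graph.  The default strategy is
a maximum-cardinality matching, which minimises the driver count; a greedy
maximal matching over lexicographically sorted edges is kept as a
deterministic alternative.

Abnormality frequencies (how often each reaction is flagged abnormal
within a group of simulations) are compared against a noise threshold
derived from the wild-type ensemble: an exponential distribution is fitted
by maximum likelihood to the wild-type frequencies and the quantile
containing 95% of that distribution is the cutoff above which a reaction
counts as consistently abnormal.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import DegenerateFitWarning, InvalidArgumentError, ParseError
from .types import FluxProfile, StoichiometricMatrix, TRANSPORT_PREFIX


def adjacency_from_stoichiometry(S: StoichiometricMatrix) -> nx.Graph:
    """Reaction-reaction graph from a stoichiometric matrix.

    Entrywise-binarised S gives B; the product BᵀB counts shared
    metabolites, which is binarised and its diagonal zeroed (a reaction
    trivially shares metabolites with itself; self-loops carry no matching
    information).  Nodes are all reaction ids, including isolated ones.
    """
    if len(S.reaction_ids) == 0:
        raise InvalidArgumentError("empty stoichiometric matrix")
    B = (S.coefficients != 0).astype(int)
    A = (B.T @ B > 0).astype(int)
    np.fill_diagonal(A, 0)
    G = nx.Graph()
    G.add_nodes_from(S.reaction_ids)
    idx = np.argwhere(np.triu(A, k=1))
    G.add_edges_from(
        (S.reaction_ids[i], S.reaction_ids[j]) for i, j in idx
    )
    return G


@dataclass(frozen=True)
class DriverSet:
    """Reactions left unmatched by a matching of the reaction graph, plus
    the matching that produced them."""

    drivers: tuple[str, ...]
    matching: tuple[tuple[str, str], ...]
    strategy: str

    @property
    def transport_fraction(self) -> float:
        """Fraction of driver reactions that are transport reactions
        (``TX_`` id prefix).  NaN when there are no drivers."""
        if not self.drivers:
            return float("nan")
        n_tx = sum(r.startswith(TRANSPORT_PREFIX) for r in self.drivers)
        return n_tx / len(self.drivers)


def _greedy_matching(G: nx.Graph) -> set[frozenset]:
    """Maximal matching by scanning edges in lexicographic id order."""
    matched: set[str] = set()
    matching: set[frozenset] = set()
    for u, v in sorted(tuple(sorted(e)) for e in G.edges()):
        if u not in matched and v not in matched:
            matching.add(frozenset((u, v)))
            matched.update((u, v))
    return matching


def find_driver_nodes(
    adjacency: nx.Graph, strategy: str = "maximum"
) -> DriverSet:
    """Driver nodes of an undirected reaction graph.

    strategy="maximum" computes a maximum-cardinality matching, giving the
    minimum possible driver count (n - 2 * matching size) independently of
    edge iteration order.  strategy="greedy_sorted" builds a maximal
    matching by a single pass over lexicographically sorted edges — a
    deterministic rendering of the greedy pair-iteration approach — and
    never yields fewer drivers than the maximum matching.  Isolated nodes
    are always drivers.
    """
    if strategy == "maximum":
        matching = nx.max_weight_matching(adjacency, maxcardinality=True)
        matching = {frozenset(e) for e in matching}
    elif strategy == "greedy_sorted":
        matching = _greedy_matching(adjacency)
    else:
        raise InvalidArgumentError(
            f"unknown matching strategy {strategy!r}; "
            "use 'maximum' or 'greedy_sorted'"
        )
    matched = set().union(*matching) if matching else set()
    drivers = tuple(sorted(n for n in adjacency.nodes if n not in matched))
    edges = tuple(sorted(tuple(sorted(e)) for e in matching))
    return DriverSet(drivers=drivers, matching=edges, strategy=strategy)


def abnormality_frequencies(
    profiles: Sequence[FluxProfile],
    groups: Optional[Mapping[str, str]] = None,
) -> dict[str, dict[str, float]]:
    """Per-reaction fraction of simulations flagged abnormal, per group.

    ``groups`` maps simulation id to a group key (phenotype class or
    genotype); simulations without a key are skipped.  With ``groups``
    omitted every profile falls into one group ``"all"``.
    """
    if not profiles:
        raise InvalidArgumentError("no profiles given")
    by_group: dict[str, list[FluxProfile]] = {}
    for p in profiles:
        key = groups.get(p.simulation_id) if groups is not None else "all"
        if key is None:
            continue
        by_group.setdefault(key, []).append(p)
    if not by_group:
        raise InvalidArgumentError("no profile belongs to any group")
    out: dict[str, dict[str, float]] = {}
    for key, members in by_group.items():
        rids = members[0].reaction_ids
        if any(m.reaction_ids != rids for m in members):
            raise InvalidArgumentError(
                "profiles within a group must share the reaction set"
            )
        bits = np.vstack([m.bits for m in members])
        freqs = bits.mean(axis=0)
        out[key] = dict(zip(rids, freqs.tolist()))
    return out


@dataclass(frozen=True)
class NoiseThreshold:
    """Exponential-fit cutoff separating stochastic wild-type flicker from
    consistently abnormal behaviour.

    ``rate`` is the maximum-likelihood exponential rate (1/mean of the
    wild-type abnormality frequencies); ``threshold`` the quantile below
    which ``coverage`` of that distribution lies:
    threshold = -ln(1 - coverage) / rate.
    """

    rate: float
    coverage: float
    threshold: float


def noise_threshold(
    wildtype_frequencies: Mapping[str, float] | Sequence[float],
    coverage: float = 0.95,
) -> NoiseThreshold:
    """Fit an exponential to wild-type abnormality frequencies and return
    its ``coverage`` quantile as the consistently-abnormal cutoff.

    Wild-type reactions should in principle never be flagged abnormal, but
    the underlying cell model is stochastic, so a low background rate of
    flags remains; frequencies above the returned threshold are treated as
    signal.  An all-zero frequency vector makes the fit degenerate: the
    threshold is defined as 0 and a warning is emitted.
    """
    if not 0 <= coverage < 1:
        raise InvalidArgumentError("coverage must be in [0, 1)")
    if isinstance(wildtype_frequencies, Mapping):
        freqs = np.array(list(wildtype_frequencies.values()), dtype=float)
    else:
        freqs = np.asarray(wildtype_frequencies, dtype=float)
    if freqs.size == 0:
        raise InvalidArgumentError("no frequencies given")
    if np.any(freqs < 0) or np.any(freqs > 1):
        raise InvalidArgumentError("frequencies must lie in [0, 1]")
    mean = float(freqs.mean())
    if mean == 0.0:
        warnings.warn(
            "all wild-type abnormality frequencies are zero; exponential "
            "fit degenerate, threshold set to 0",
            DegenerateFitWarning,
        )
        return NoiseThreshold(rate=math.inf, coverage=coverage, threshold=0.0)
    rate = 1.0 / mean
    threshold = -math.log(1.0 - coverage) / rate
    return NoiseThreshold(rate=rate, coverage=coverage, threshold=threshold)


def class_subnetwork(
    adjacency: nx.Graph,
    group_frequencies: Mapping[str, float],
    threshold: float,
) -> nx.Graph:
    """Induced subgraph on the reactions whose abnormality frequency is
    strictly above the threshold; each node carries its frequency as the
    ``frequency`` attribute for colour-gradient rendering/export.
    An empty subgraph is a legal result."""
    selected = [
        r
        for r in adjacency.nodes
        if group_frequencies.get(r, 0.0) > threshold
    ]
    H = adjacency.subgraph(selected).copy()
    nx.set_node_attributes(
        H, {r: float(group_frequencies[r]) for r in selected}, "frequency"
    )
    return H


def annotate_pathways(
    drivers: DriverSet,
    annotation: Mapping[str, Sequence[str]],
    adjacency: Optional[nx.Graph] = None,
) -> dict[str, list[str]]:
    """Attach pathway annotations to driver reactions.

    A driver with no annotation of its own inherits the union of the
    pathways of its degree-1 neighbours in the reaction graph (sorted,
    deduplicated); if neither it nor any neighbour is annotated it maps to
    ``["n/a"]``.
    """
    for rid, paths in annotation.items():
        if isinstance(paths, str) or not all(
            isinstance(p, str) for p in paths
        ):
            raise ParseError(
                f"annotation for {rid!r} must be a list of pathway names"
            )
    out: dict[str, list[str]] = {}
    for rid in drivers.drivers:
        paths = list(annotation.get(rid, []))
        if not paths and adjacency is not None and rid in adjacency:
            inherited: set[str] = set()
            for nb in adjacency.neighbors(rid):
                inherited.update(annotation.get(nb, []))
            paths = sorted(inherited)
        out[rid] = paths if paths else ["n/a"]
    return out
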