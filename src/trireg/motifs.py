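"""miRNA-TF interplay extraction and feed-forward-loop motif analysis.

The interplay subnetwork keeps the edges whose two endpoints are both
regulators (miRNA or TF), in either direction. Feed-forward loops (FFLs)
are ordered triples (A, B, C) with edges A->B, B->C and A->C involving at
least two regulator nodes. Significance is judged against a
degree-preserving edge-switching null model that also preserves the
mutual-dyad census (the 2-node subgraph counts) and the five-type role
feasibility, so randomised networks keep the real network's low-order
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ALLOWED_TARGETS,
    GeneRole,
    GlobalNetwork,
    TypedEdge,
    edge_type_label,
)

__all__ = [
    "MotifInstance",
    "MotifReport",
    "extract_interplay",
    "enumerate_ffls",
    "randomize_network",
    "motif_significance",
]

_REGULATOR_ROLES = {GeneRole.MIRNA, GeneRole.TF}


@dataclass(frozen=True)
class MotifInstance:
    """One FFL: edges a->b, b->c and a->c, with its regulator count."""

    a: str
    b: str
    c: str
    regulator_count: int


@dataclass(frozen=True)
class MotifReport:
    """FFL count in the real network against the randomised null.

    ``empirical_p`` uses add-one smoothing: (1 + #{null >= real}) /
    (1 + n_random). ``z_score`` is None when the null counts have zero
    spread.
    """

    real_count: int
    null_counts: tuple[int, ...]
    z_score: float | None
    empirical_p: float
    n_random: int
    swap_factor: int
    instances: tuple[MotifInstance, ...] = field(default=(), repr=False)


def extract_interplay(network: GlobalNetwork) -> GlobalNetwork:
    """Subnetwork of edges between miRNAs and TFs (either direction)."""
    kept = [
        c
        for e, c in network.confidences.items()
        if network.roles[e.source] in _REGULATOR_ROLES
        and network.roles[e.target] in _REGULATOR_ROLES
    ]
    return GlobalNetwork(network.roles, kept, network.threshold)


def _as_edges_roles(network) -> tuple[frozenset[TypedEdge], dict[str, GeneRole]]:
    if isinstance(network, GlobalNetwork):
        return network.edges, network.roles
    edges, roles = network
    return frozenset(edges), dict(roles)


def enumerate_ffls(network, min_regulators: int = 2) -> list[MotifInstance]:
    """All FFL instances, in deterministic (a, b, c) lexicographic order.

    ``network`` is a :class:`GlobalNetwork` or an ``(edges, roles)`` pair.
    In networks produced by this pipeline mRNAs have out-degree 0, so the
    first two nodes of any FFL are regulators and the filter removes
    nothing; it matters only for externally supplied graphs.
    """
    edges, roles = _as_edges_roles(network)
    succ: dict[str, set[str]] = {}
    for e in edges:
        succ.setdefault(e.source, set()).add(e.target)
    instances: list[MotifInstance] = []
    for a in sorted(succ):
        for b in sorted(succ[a]):
            if b not in succ:
                continue
            for c in sorted(succ[a] & succ[b]):
                if c == a:
                    continue
                n_reg = sum(roles[n] in _REGULATOR_ROLES for n in (a, b, c))
                if n_reg >= min_regulators:
                    instances.append(MotifInstance(a, b, c, n_reg))
    return instances


def _type_ok(source: str, target: str, roles: dict[str, GeneRole]) -> bool:
    return source != target and roles[target] in ALLOWED_TARGETS[roles[source]]


def randomize_network(
    network, swap_factor: int = 10, seed: int | np.random.Generator = 0
) -> tuple[frozenset[TypedEdge], dict[str, GeneRole]]:
    """Degree-preserving randomisation by edge switching.

    ``swap_factor * |edges|`` swaps are attempted. Mutual dyads (X<->Y) are
    swapped only with mutual dyads and single edges only with single edges,
    which preserves per-node in/out degrees *and* the 2-node subgraph
    census. A proposed swap that would create a self-loop, a duplicate
    edge, a role-forbidden edge type, or convert a single edge into a
    mutual dyad (or vice versa) is rejected.
    """
    if swap_factor < 1:
        raise ValueError("swap_factor must be >= 1")
    edges, roles = _as_edges_roles(network)
    rng = np.random.default_rng(seed)
    pairs = {(e.source, e.target) for e in edges}
    mutual_pairs = sorted(
        frozenset((a, b)) for (a, b) in pairs if (b, a) in pairs
    )
    mutuals: list[tuple[str, str]] = sorted(tuple(sorted(p)) for p in set(mutual_pairs))
    singles: list[tuple[str, str]] = sorted(
        (a, b) for (a, b) in pairs if (b, a) not in pairs
    )
    current = set(pairs)
    n_attempts = swap_factor * len(pairs)
    for _ in range(n_attempts):
        # choose a unit class in proportion to how many units it holds
        n_units = len(singles) + len(mutuals)
        if n_units < 2:
            break
        u = rng.integers(0, n_units)
        if u < len(singles) and len(singles) >= 2:
            i, j = rng.choice(len(singles), size=2, replace=False)
            (a, b), (c, d) = singles[i], singles[j]
            new1, new2 = (a, d), (c, b)
            if new1 == new2 or new1[0] == new1[1] or new2[0] == new2[1]:
                continue
            if new1 in current or new2 in current:
                continue
            # keep the swapped edges single: their reverses must stay absent
            if (new1[1], new1[0]) in current or (new2[1], new2[0]) in current:
                continue
            if not (_type_ok(*new1, roles) and _type_ok(*new2, roles)):
                continue
            current.discard((a, b))
            current.discard((c, d))
            current.add(new1)
            current.add(new2)
            singles[i], singles[j] = new1, new2
        elif len(mutuals) >= 2:
            i, j = rng.choice(len(mutuals), size=2, replace=False)
            (a, b), (c, d) = mutuals[i], mutuals[j]
            if rng.integers(0, 2):
                c, d = d, c
            if {a, b} & {c, d}:
                continue
            p1, p2 = (a, d), (c, b)
            new_edges = [p1, (p1[1], p1[0]), p2, (p2[1], p2[0])]
            if any(e in current for e in new_edges):
                continue
            if not all(_type_ok(x, y, roles) for x, y in new_edges):
                continue
            for e in ((a, b), (b, a), (c, d), (d, c)):
                current.discard(e)
            current.update(new_edges)
            mutuals[i], mutuals[j] = tuple(sorted(p1)), tuple(sorted(p2))
    out = frozenset(
        TypedEdge(s, t, edge_type_label(roles[s], roles[t])) for s, t in current
    )
    return out, roles


def motif_significance(
    network,
    n_random: int = 1000,
    swap_factor: int = 10,
    seed: int = 0,
) -> MotifReport:
    """FFL enrichment of *network* against the edge-switching null.

    Each of the ``n_random`` randomised replicates gets an independent RNG
    stream derived from the master seed, so the null is reproducible and
    order-independent.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    instances = enumerate_ffls(network)
    real = len(instances)
    null_counts = []
    for r in range(n_random):
        stream = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        randomized = randomize_network(network, swap_factor, stream)
        null_counts.append(len(enumerate_ffls(randomized)))
    null = np.asarray(null_counts, dtype=float)
    sd = float(null.std(ddof=0))
    z = float((real - null.mean()) / sd) if sd > 0 else None
    emp_p = (1 + int(np.sum(null >= real))) / (1 + n_random)
    return MotifReport(
        real_count=real,
        null_counts=tuple(null_counts),
        z_score=z,
        empirical_p=emp_p,
        n_random=n_random,
        swap_factor=swap_factor,
        instances=tuple(instances),
    )
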