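"""Synthetic ground truth, expression data, and decoyed target lists.

The generator emulates a two-condition regulatory study: a typed random
network over K miRNAs, I TFs and J mRNAs; binary (or continuous) expression
in which each child follows a logistic conditional on its parents,
P(child = 1) = logistic(b0 + sum_p sign_c(p) * w * value_p); and a target
edge list that mixes the true edges with type-valid decoys, imitating the
high false-discovery rate of sequence-based target prediction. A fraction
of edges are "mix-regulating": their sign flips between the two conditions
(up-regulation in one, down-regulation in the other), the situation the
condition-wise splitting strategy exists for. Feedback pairs, if the random
topology contains them, are resolved with a single settle pass so cyclic
networks are exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ALLOWED_TARGETS,
    ExpressionDataset,
    GeneRole,
    PriorNetwork,
    TypedEdge,
    EDGE_TYPES,
    edge_type_label,
)

__all__ = ["SyntheticTruth", "generate_truth", "simulate_expression", "generate_target_info"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted network plus regulation parameters.

    ``signs[edge]`` maps condition index (0, 1) -> +1/-1; mix-regulation
    edges carry opposite signs in the two conditions. ``baselines[gene]``
    is the logistic intercept b0.
    """

    network: PriorNetwork
    weight: float
    signs: dict[TypedEdge, tuple[int, int]]
    baselines: dict[str, float]
    seed: int

    @property
    def mix_edges(self) -> frozenset[TypedEdge]:
        return frozenset(e for e, s in self.signs.items() if s[0] != s[1])


def _role_ids(K: int, I: int, J: int) -> dict[str, GeneRole]:
    roles: dict[str, GeneRole] = {}
    roles.update({f"miR{k:03d}": GeneRole.MIRNA for k in range(K)})
    roles.update({f"tf{i:03d}": GeneRole.TF for i in range(I)})
    roles.update({f"gene{j:03d}": GeneRole.MRNA for j in range(J)})
    return roles


def generate_truth(
    K: int,
    I: int,
    J: int,
    edges_per_type: dict[str, int] | int,
    mix_fraction: float = 0.2,
    weight: float = 3.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant a typed random network without self-loops or duplicates.

    ``edges_per_type`` is a count per edge-type label (or one count for all
    five types). Requesting more edges of a type than there are admissible
    pairs is an error. ``mix_fraction`` of the edges (rounded down) flip
    their regulation sign between the two conditions.
    """
    if isinstance(edges_per_type, int):
        edges_per_type = {t: edges_per_type for t in EDGE_TYPES}
    roles = _role_ids(K, I, J)
    by_role = {r: sorted(g for g, rr in roles.items() if rr == r) for r in GeneRole}
    rng = np.random.default_rng(seed)
    edges: list[TypedEdge] = []
    for etype in EDGE_TYPES:
        want = edges_per_type.get(etype, 0)
        if want == 0:
            continue
        src_role, tgt_role = (GeneRole[p] for p in etype.split("->"))
        pool = [
            (s, t)
            for s in by_role[src_role]
            for t in by_role[tgt_role]
            if s != t
        ]
        if want > len(pool):
            raise ValueError(
                f"requested {want} {etype} edges but only {len(pool)} pairs exist"
            )
        chosen = rng.choice(len(pool), size=want, replace=False)
        edges.extend(TypedEdge(*pool[i], etype) for i in sorted(chosen))
    n_mix = int(mix_fraction * len(edges))
    mix_idx = set(rng.choice(len(edges), size=n_mix, replace=False)) if n_mix else set()
    signs: dict[TypedEdge, tuple[int, int]] = {}
    for i, e in enumerate(edges):
        base = -1 if e.source_role is GeneRole.MIRNA else 1  # miRNAs repress
        signs[e] = (base, -base) if i in mix_idx else (base, base)
    network = PriorNetwork(roles, edges)
    # centre each child's logit: b0 = -(w/2) * sum_p mean_c sign_c(p), so a
    # single positive parent with w=4 gives b0=-2 and P(1) in {0.12, 0.88}
    sign_sum: dict[str, float] = {g: 0.0 for g in roles}
    for e in edges:
        sign_sum[e.target] += 0.5 * (signs[e][0] + signs[e][1])
    baselines = {g: -0.5 * weight * sign_sum[g] for g in roles}
    return SyntheticTruth(network, float(weight), signs, baselines, seed)


def _scc_generation_order(truth: SyntheticTruth) -> list[list[str]]:
    """Strongly connected components in topological order (deterministic).

    Cross-component edges always point forward, so every gene outside a
    feedback core is drawn after its parents are final; cyclic components
    (mutual TF/miRNA regulation) are listed as multi-member blocks and
    resolved by the settle pass.
    """
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(truth.network.roles))
    graph.add_edges_from((e.source, e.target) for e in sorted(truth.network.edges))
    condensed = nx.condensation(graph)
    order = nx.lexicographical_topological_sort(condensed)
    return [sorted(condensed.nodes[i]["members"]) for i in order]


def simulate_expression(
    truth: SyntheticTruth,
    samples_per_condition: tuple[int, int] = (60, 60),
    mode: str = "binary",
    noise: float = 0.5,
    seed: int = 0,
) -> ExpressionDataset:
    """Draw a two-condition expression matrix from the planted network.

    Parentless genes are Bernoulli(0.5); each child is Bernoulli with
    P(1) = logistic(b0 + sum_p sign_c(p) * w * parent_p). In ``continuous``
    mode the latent binary state is emitted as Normal(0, noise) for the
    down state and Normal(2, noise) for the up state. Feedback edges are
    applied in one extra settle pass after the acyclic sweep.
    """
    if mode not in ("binary", "continuous"):
        raise ValueError(f"mode must be 'binary' or 'continuous', got {mode!r}")
    rng = np.random.default_rng(seed)
    blocks = _scc_generation_order(truth)
    genes = [g for block in blocks for g in block]
    in_edges: dict[str, list[TypedEdge]] = {g: [] for g in genes}
    for e in sorted(truth.network.edges):
        in_edges[e.target].append(e)
    frames = []
    sample_ids: list[str] = []
    conditions: dict[str, str] = {}
    for c, n in enumerate(samples_per_condition):
        state = pd.DataFrame(
            np.zeros((len(genes), n), dtype=np.int8), index=genes
        )
        for block in blocks:
            if len(block) == 1:
                g = block[0]
                state.loc[g] = _draw_gene(state, g, in_edges[g], truth, c, n, rng)
            else:
                # feedback core: initialise at the marginal, then one
                # settle pass given the current member states
                for g in block:
                    state.loc[g] = rng.integers(0, 2, size=n).astype(np.int8)
                for g in block:
                    state.loc[g] = _draw_gene(state, g, in_edges[g], truth, c, n, rng)
        ids = [f"c{c + 1}s{j:03d}" for j in range(n)]
        state.columns = ids
        sample_ids.extend(ids)
        conditions.update({s: f"cond{c + 1}" for s in ids})
        frames.append(state)
    latent = pd.concat(frames, axis=1)
    if mode == "binary":
        values = latent.astype(float)
    else:
        values = pd.DataFrame(
            np.where(latent.to_numpy() == 1, 2.0, 0.0)
            + rng.normal(0.0, noise, size=latent.shape),
            index=latent.index,
            columns=latent.columns,
        )
    return ExpressionDataset(values, truth.network.roles, conditions)


def _draw_gene(state, gene, edges, truth, condition, n, rng):
    if not edges:
        return rng.integers(0, 2, size=n).astype(np.int8)
    logit = np.full(n, truth.baselines[gene])
    for e in edges:
        logit = logit + truth.signs[e][condition] * truth.weight * state.loc[
            e.source
        ].to_numpy(float)
    prob = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random(n) < prob).astype(np.int8)


def generate_target_info(
    truth: SyntheticTruth,
    decoy_fraction: float = 0.5,
    seed: int = 0,
    n_decoys: int | None = None,
) -> tuple[list[TypedEdge], frozenset[TypedEdge]]:
    """True edges plus type-valid random decoys.

    The number of decoys is chosen so that decoys / total ~= decoy_fraction
    (exact up to rounding), unless ``n_decoys`` overrides it directly (the
    only way to obtain decoys for an empty true network, e.g. a pure-noise
    null study). Returns ``(edges, decoys)``: the shuffled-in decoy set is
    identified separately for downstream evaluation; the edge list itself
    carries no marker, like a real target database.
    """
    if not 0.0 <= decoy_fraction < 1.0:
        raise ValueError("decoy_fraction must be in [0, 1)")
    true_edges = sorted(truth.network.edges)
    if n_decoys is None:
        n_decoys = round(len(true_edges) * decoy_fraction / (1.0 - decoy_fraction))
    if n_decoys == 0:
        return list(true_edges), frozenset()
    roles = truth.network.roles
    existing = set(truth.network.edges)
    pool = [
        TypedEdge(s, t, edge_type_label(rs, rt))
        for s, rs in sorted(roles.items())
        for t, rt in sorted(roles.items())
        if s != t and rt in ALLOWED_TARGETS[rs]
    ]
    pool = [e for e in pool if e not in existing]
    if n_decoys > len(pool):
        raise ValueError(
            f"need {n_decoys} decoys but only {len(pool)} admissible non-edges exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_decoys, replace=False)
    decoys = frozenset(pool[i] for i in chosen)
    return sorted(existing | decoys), decoys
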