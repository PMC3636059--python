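"""Per-condition structure learning by exhaustive candidate averaging.

Candidate structures are generated by removing prior edges; because the
BDe score decomposes over families, each child's in-edges can be decided
independently: score all 2^p parent subsets of the child's candidate
parents, then for each candidate edge compare the average log-score of the
subsets containing it against the average over those that do not. The edge
is retained only when the with-edge average is strictly higher (ties are
conservative: absent). All other families' score terms are identical on
both sides of the comparison and cancel, which is why this per-child
enumeration reproduces the per-regulator candidate scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import BinaryExpressionDataset, Family, PriorNetwork, TypedEdge
from .prior import MAX_FAMILY_SIZE, families
from .scoring import BDeConfig, local_bde_score

__all__ = [
    "EdgeDecision",
    "enumerate_parent_subsets",
    "enumerate_candidate_structures",
    "family_subset_scores",
    "decide_edge",
    "decide_edge_structures",
    "learn_condition_network",
]


@dataclass(frozen=True)
class EdgeDecision:
    """Outcome of the averaging comparison for one candidate edge."""

    edge: TypedEdge
    avg_with: float
    avg_without: float

    @property
    def present(self) -> bool:
        return self.avg_with > self.avg_without


def enumerate_parent_subsets(family: Family) -> list[tuple[str, ...]]:
    """All 2^p parent subsets in deterministic binary-counting order.

    Bit i of the subset index selects the i-th parent in the family's
    lexicographic order, so subset 0 is empty and subset 2^p - 1 is the
    full candidate set.
    """
    parents = family.candidate_parents
    p = len(parents)
    if p > MAX_FAMILY_SIZE:
        raise ValueError(
            f"family of {family.child!r} has {p} parents, above cap {MAX_FAMILY_SIZE}"
        )
    return [
        tuple(parents[i] for i in range(p) if mask >> i & 1)
        for mask in range(1 << p)
    ]


def enumerate_candidate_structures(
    prior: PriorNetwork, cap: int = MAX_FAMILY_SIZE
) -> list[frozenset[TypedEdge]]:
    """All candidate structures reachable by removing prior edges.

    This is the regulator-centric view of candidate generation: every
    subset of the prior edge set is a candidate (2^|edges| of them, in
    binary-counting order over the sorted edges). Feasible only for small
    priors; the per-family route scales and reaches identical decisions.
    """
    edges = sorted(prior.edges)
    if len(edges) > cap:
        raise ValueError(
            f"{len(edges)} prior edges exceed the enumeration cap of {cap}; "
            "use the per-family route"
        )
    return [
        frozenset(e for i, e in enumerate(edges) if mask >> i & 1)
        for mask in range(1 << len(edges))
    ]


def decide_edge_structures(
    edge: TypedEdge, structure_scores: Mapping[frozenset[TypedEdge], float]
) -> EdgeDecision:
    """Average-score comparison over whole candidate structures.

    The with-edge average is the mean score of the candidates containing
    the edge; the without-edge average the mean over the rest. Equivalent
    to :func:`decide_edge` under score decomposability.
    """
    with_scores = [s for st, s in structure_scores.items() if edge in st]
    without_scores = [s for st, s in structure_scores.items() if edge not in st]
    if not with_scores or not without_scores:
        raise ValueError(f"candidate scores do not cover both sides for {edge}")
    return EdgeDecision(
        edge=edge,
        avg_with=float(np.mean(with_scores)),
        avg_without=float(np.mean(without_scores)),
    )


def family_subset_scores(
    family: Family,
    data: BinaryExpressionDataset,
    config: BDeConfig = BDeConfig(),
) -> dict[tuple[str, ...], float]:
    """Log BDe family score for every parent subset of *family*."""
    row = {g: i for i, g in enumerate(data.gene_ids)}
    for g in (family.child, *family.candidate_parents):
        if g not in row:
            raise ValueError(f"gene {g!r} absent from data")
    matrix = data.values.to_numpy(dtype=np.int64)
    child = matrix[row[family.child]]
    parent_rows = {p: matrix[row[p]] for p in family.candidate_parents}
    scores: dict[tuple[str, ...], float] = {}
    for subset in enumerate_parent_subsets(family):
        block = np.vstack([parent_rows[p] for p in subset]) if subset else None
        scores[subset] = local_bde_score(child, block, config).log_score
    return scores


def decide_edge(
    edge: TypedEdge, family_scores: Mapping[tuple[str, ...], float]
) -> EdgeDecision:
    """Average-score comparison for one in-edge of a family.

    ``avg_with`` is the arithmetic mean of the log-scores over the parent
    subsets containing the edge's source; ``avg_without`` over the
    complement. Both sides average 2^(p-1) candidates. Present iff
    ``avg_with > avg_without`` strictly.
    """
    with_scores = [s for subset, s in family_scores.items() if edge.source in subset]
    without_scores = [s for subset, s in family_scores.items() if edge.source not in subset]
    if not with_scores or not without_scores:
        raise ValueError(f"family scores do not cover both sides for {edge}")
    return EdgeDecision(
        edge=edge,
        avg_with=float(np.mean(with_scores)),
        avg_without=float(np.mean(without_scores)),
    )


def learn_condition_network(
    data: BinaryExpressionDataset,
    prior: PriorNetwork,
    config: BDeConfig = BDeConfig(),
) -> set[TypedEdge]:
    """Decide every prior edge on one condition's binary data.

    Returns the retained subset of the prior edge set. Deterministic given
    the data: iteration is over lexicographically sorted families and each
    decision depends only on its own family's data.
    """
    if data.n_samples < 1:
        raise ValueError("condition has no samples")
    learnt: set[TypedEdge] = set()
    in_edges: dict[str, list[TypedEdge]] = {}
    for e in prior.edges:
        in_edges.setdefault(e.target, []).append(e)
    for family in families(prior):
        scores = family_subset_scores(family, data, config)
        for edge in sorted(in_edges.get(family.child, [])):
            if decide_edge(edge, scores).present:
                learnt.add(edge)
    return learnt
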