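"""Initial search structure from target information.

Sequence-based target predictions (regulator -> target pairs) are filtered
to the differentially expressed genes and become the prior network: the
union of the five bipartite sub-structures that constrains the exhaustive
Bayesian-network search. The per-child decomposition into families (child +
candidate parent set) is the unit the score and the edge decisions operate
on.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .core import Family, GeneRole, PriorNetwork, TypedEdge

logger = logging.getLogger(__name__)

__all__ = ["MAX_FAMILY_SIZE", "build_prior_network", "families"]

#: Hard cap on candidate parents per child. Exhaustive subset enumeration is
#: feasible only because target information keeps in-degrees small; beyond
#: 2^16 subsets the contract is explicitly broken rather than silently slow.
MAX_FAMILY_SIZE = 16


def build_prior_network(
    edges: Iterable[TypedEdge],
    selected_genes: Iterable[str],
    roles: Mapping[str, GeneRole],
) -> PriorNetwork:
    """Restrict target edges to the selected genes and deduplicate.

    Only edges with *both* endpoints in ``selected_genes`` survive. The
    resulting network may be empty (a warning, not an error). Per-type edge
    counts are logged.
    """
    selected = set(selected_genes)
    if not selected:
        raise ValueError("selected_genes is empty")
    kept = {
        e for e in edges if e.source in selected and e.target in selected
    }
    node_ids = {g for e in kept for g in (e.source, e.target)} | (
        selected & set(roles)
    )
    network = PriorNetwork({g: roles[g] for g in node_ids}, kept)
    if not kept:
        logger.warning("prior network is empty after restricting to selected genes")
    logger.info("prior network edge types: %s", network.edge_type_counts())
    return network


def families(
    prior: PriorNetwork, include_parentless: bool = False
) -> list[Family]:
    """One family per child with in-degree >= 1 (parents lexicographic).

    The union of family (parent, child) pairs reconstructs the prior edge
    set exactly. With ``include_parentless`` every remaining node appears
    with an empty parent tuple (those families carry only the marginal
    score term).
    """
    fams = prior.families(include_parentless=include_parentless)
    for fam in fams:
        if len(fam.candidate_parents) > MAX_FAMILY_SIZE:
            raise ValueError(
                f"child {fam.child!r} has {len(fam.candidate_parents)} candidate "
                f"parents, above the cap of {MAX_FAMILY_SIZE}; raise the cap or "
                "pre-filter the target information"
            )
    return fams
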