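"""Bootstrap model averaging and binomial edge confidence.

Microarray condition groups are small, so single-pass structure learning
is noisy. Each condition is bootstrapped n times; learning an edge on one
resample is treated as a Bernoulli event with null probability 0.5 (present
or absent, no preference). Summing the events over all C conditions and n
bootstraps gives Q ~ Binomial(C*n, 0.5) under the null; edges whose exact
upper-tail p-value falls strictly below the threshold (default 0.05) enter
the integrated global network. Cycles may appear after integration — the
global network is a directed graph, not a Bayesian network.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np

from .core import (
    BinaryExpressionDataset,
    EdgeConfidence,
    GeneRole,
    GlobalNetwork,
    PriorNetwork,
    TypedEdge,
)
from .learning import learn_condition_network
from .scoring import BDeConfig

logger = logging.getLogger(__name__)

__all__ = [
    "bootstrap_resample",
    "count_edge_events",
    "binomial_pvalue",
    "integrate",
]


def bootstrap_resample(
    data: BinaryExpressionDataset, seed: int | np.random.Generator
) -> BinaryExpressionDataset:
    """Resample the dataset's samples with replacement (same count).

    Reproducible: an integer seed always yields the same resample. Column
    names are suffixed with the draw index to keep sample ids unique.
    """
    if data.n_samples < 1:
        raise ValueError("cannot resample a dataset with no samples")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.n_samples, size=data.n_samples)
    cols = [data.sample_ids[i] for i in idx]
    values = data.values.iloc[:, list(idx)]
    new_ids = [f"{c}#{k}" for k, c in enumerate(cols)]
    values = values.set_axis(new_ids, axis=1)
    conditions = (
        {nid: data.conditions[c] for nid, c in zip(new_ids, cols)}
        if data.conditions is not None
        else None
    )
    return BinaryExpressionDataset(values, data.roles, conditions)


def count_edge_events(
    prior: PriorNetwork,
    condition_data: Mapping[str, BinaryExpressionDataset],
    n_boot: int,
    config: BDeConfig = BDeConfig(),
    seed: int = 0,
) -> dict[TypedEdge, tuple[int, int]]:
    """Count, per prior edge, the bootstrap-condition runs that learn it.

    For every bootstrap b in 1..n_boot and condition c, the condition's
    samples are resampled and the structure relearnt; the event q = 1 iff
    the edge is in the learnt set. Returns edge -> (Q, trials) with
    trials = C * n_boot for every edge. One RNG stream per (bootstrap,
    condition) pair is derived from the master seed, so results do not
    depend on the edge set or on iteration order.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = sorted(condition_data)
    trials = len(labels) * n_boot
    counts: dict[TypedEdge, int] = {e: 0 for e in prior.edges}
    for b in range(n_boot):
        for ci, label in enumerate(labels):
            stream = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(b, ci))
            )
            resample = bootstrap_resample(condition_data[label], stream)
            learnt = learn_condition_network(resample, prior, config)
            for e in learnt:
                counts[e] += 1
    return {e: (q, trials) for e, q in counts.items()}


def binomial_pvalue(Q: int, trials: int) -> float:
    """Exact upper tail P(Binomial(trials, 1/2) >= Q).

    Computed with integer arithmetic (sum of binomial coefficients over
    2^trials), so the result is the correctly rounded double of the exact
    rational tail probability.
    """
    if not 0 <= Q <= trials:
        raise ValueError(f"Q={Q} outside [0, {trials}]")
    numerator = sum(math.comb(trials, k) for k in range(Q, trials + 1))
    return numerator / (1 << trials)


def integrate(
    edge_counts: Mapping[TypedEdge, tuple[int, int]],
    roles: Mapping[str, GeneRole],
    threshold: float = 0.05,
) -> GlobalNetwork:
    """Keep edges with exact binomial p strictly below *threshold*.

    Discarded edges are counted in the log. The surviving edges carry their
    EdgeConfidence (Q, trials, p) into the global network.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    kept: list[EdgeConfidence] = []
    dropped = 0
    for edge, (q, trials) in edge_counts.items():
        p = binomial_pvalue(q, trials)
        if p < threshold:
            kept.append(EdgeConfidence(edge=edge, Q=q, trials=trials, p_value=p))
        else:
            dropped += 1
    logger.info(
        "integration: %d edges significant at p<%g, %d discarded",
        len(kept),
        threshold,
        dropped,
    )
    return GlobalNetwork(roles, kept, threshold)
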