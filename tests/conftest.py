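import numpy as np
import pandas as pd
import pytest

from trireg.core import (
    BinaryExpressionDataset,
    ExpressionDataset,
    GeneRole,
    PriorNetwork,
    TypedEdge,
)


@pytest.fixture
def roles_small() -> dict[str, GeneRole]:
    return {
        "miR1": GeneRole.MIRNA,
        "miR2": GeneRole.MIRNA,
        "tf1": GeneRole.TF,
        "tf2": GeneRole.TF,
        "geneA": GeneRole.MRNA,
        "geneB": GeneRole.MRNA,
    }


@pytest.fixture
def binary_pair():
    """Two-gene binary dataset factory: child deterministically = parent."""

    def make(n_samples: int = 20, roles=None):
        roles = roles or {"tf1": GeneRole.TF, "geneA": GeneRole.MRNA}
        rng = np.random.default_rng(7)
        parent = rng.integers(0, 2, size=n_samples)
        values = pd.DataFrame(
            [parent, parent],
            index=["tf1", "geneA"],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        return BinaryExpressionDataset(values, roles)

    return make


@pytest.fixture
def tiny_expression(roles_small) -> ExpressionDataset:
    rng = np.random.default_rng(3)
    samples = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.normal(size=(6, 8)), index=list(roles_small), columns=samples
    )
    conditions = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
    return ExpressionDataset(values, roles_small, conditions)


@pytest.fixture
def simple_prior(roles_small) -> PriorNetwork:
    edges = [
        TypedEdge("miR1", "geneA", "MIRNA->MRNA"),
        TypedEdge("miR1", "tf1", "MIRNA->TF"),
        TypedEdge("tf1", "miR2", "TF->MIRNA"),
        TypedEdge("tf1", "tf2", "TF->TF"),
        TypedEdge("tf2", "geneB", "TF->MRNA"),
    ]
    return PriorNetwork(roles_small, edges)
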