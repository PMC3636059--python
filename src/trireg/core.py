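"""Core domain types for three-component regulatory networks.

The object model mirrors the biology: genes carry one of three roles
(miRNA, TF, mRNA), expression is a genes x samples matrix whose columns
are labelled by biological condition, and regulatory hypotheses are typed
directed edges restricted to the five admissible regulator->target
combinations (miRNA->mRNA, miRNA->TF, TF->miRNA, TF->TF, TF->mRNA).
mRNAs never regulate anything here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneRole",
    "ALLOWED_TARGETS",
    "EDGE_TYPES",
    "TypedEdge",
    "ExpressionDataset",
    "BinaryExpressionDataset",
    "PriorNetwork",
    "Family",
    "EdgeConfidence",
    "GlobalNetwork",
]


class GeneRole(enum.Enum):
    """Role of a gene node: miRNA, transcription factor, or mRNA."""

    MIRNA = "miRNA"
    TF = "TF"
    MRNA = "mRNA"

    @classmethod
    def parse(cls, text: str) -> "GeneRole":
        norm = text.strip().lower()
        for role in cls:
            if role.value.lower() == norm or role.name.lower() == norm:
                return role
        raise ValueError(f"unknown gene role: {text!r}")


#: Admissible regulator-role -> target-role pairs (the five edge types).
ALLOWED_TARGETS: dict[GeneRole, frozenset[GeneRole]] = {
    GeneRole.MIRNA: frozenset({GeneRole.TF, GeneRole.MRNA}),
    GeneRole.TF: frozenset({GeneRole.MIRNA, GeneRole.TF, GeneRole.MRNA}),
    GeneRole.MRNA: frozenset(),
}


def edge_type_label(source_role: GeneRole, target_role: GeneRole) -> str:
    """Canonical label such as ``"TF->MIRNA"`` for an admissible edge type."""
    if target_role not in ALLOWED_TARGETS[source_role]:
        raise ValueError(
            f"edge type {source_role.name}->{target_role.name} is not one of "
            "the five admissible regulator->target types"
        )
    return f"{source_role.name}->{target_role.name}"


#: The five admissible edge-type labels, in a fixed canonical order.
EDGE_TYPES: tuple[str, ...] = (
    "MIRNA->MRNA",
    "MIRNA->TF",
    "TF->MIRNA",
    "TF->TF",
    "TF->MRNA",
)


@dataclass(frozen=True, order=True)
class TypedEdge:
    """A typed directed regulatory edge.

    Invariants: ``source != target``; the type is one of the five admissible
    regulator->target combinations; an mRNA is never a source.
    """

    source: str
    target: str
    edge_type: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop edge on {self.source!r}")
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"invalid edge type {self.edge_type!r}")

    @classmethod
    def from_roles(
        cls, source: str, target: str, roles: Mapping[str, GeneRole]
    ) -> "TypedEdge":
        """Build an edge inferring its type from a gene->role table."""
        sr, tr = roles[source], roles[target]
        return cls(source, target, edge_type_label(sr, tr))

    @property
    def source_role(self) -> GeneRole:
        return GeneRole[self.edge_type.split("->")[0]]

    @property
    def target_role(self) -> GeneRole:
        return GeneRole[self.edge_type.split("->")[1]]


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


class ExpressionDataset:
    """Continuous genes x samples expression matrix with roles and conditions.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    roles
        Mapping gene id -> :class:`GeneRole`, covering every row.
    conditions
        Optional mapping sample id -> condition label, covering every column
        when given.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        roles: Mapping[str, GeneRole],
        conditions: Mapping[str, str] | None = None,
    ) -> None:
        _check_unique(values.index, "gene")
        _check_unique(values.columns, "sample")
        missing = [g for g in values.index if g not in roles]
        if missing:
            raise ValueError(f"genes without a role: {missing[:5]}")
        if conditions is not None:
            unlabelled = [s for s in values.columns if s not in conditions]
            if unlabelled:
                raise ValueError(f"samples without a condition: {unlabelled[:5]}")
        self.values = values.astype(float)
        self.roles: dict[str, GeneRole] = {g: roles[g] for g in values.index}
        self.conditions: dict[str, str] | None = (
            {s: conditions[s] for s in values.columns} if conditions is not None else None
        )

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def condition_labels(self) -> list[str]:
        """Distinct condition labels, sorted."""
        if self.conditions is None:
            raise ValueError("dataset has no condition annotation")
        return sorted(set(self.conditions.values()))

    def role_counts(self) -> dict[GeneRole, int]:
        out = {r: 0 for r in GeneRole}
        for role in self.roles.values():
            out[role] += 1
        return out

    # -- construction helpers ------------------------------------------------

    def with_conditions(self, conditions: Mapping[str, str]) -> "ExpressionDataset":
        return type(self)(self.values, self.roles, conditions)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        keep = [g for g in self.values.index if g in set(genes)]
        return type(self)(self.values.loc[keep], self.roles, self.conditions)

    @classmethod
    def concat(cls, parts: "Iterable[ExpressionDataset]") -> "ExpressionDataset":
        """Stack per-role blocks sharing the same sample columns."""
        parts = list(parts)
        values = pd.concat([p.values for p in parts], axis=0)
        roles: dict[str, GeneRole] = {}
        for p in parts:
            roles.update(p.roles)
        conditions = parts[0].conditions
        return cls(values, roles, conditions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.roles == other.roles
            and self.conditions == other.conditions
        )

    def __repr__(self) -> str:
        counts = self.role_counts()
        return (
            f"<{type(self).__name__} {self.n_genes} genes "
            f"(K={counts[GeneRole.MIRNA]} miRNA, I={counts[GeneRole.TF]} TF, "
            f"J={counts[GeneRole.MRNA]} mRNA) x {self.n_samples} samples>"
        )


class BinaryExpressionDataset(ExpressionDataset):
    """Discretised expression: 1 = up-regulation, 0 = down-regulation."""

    def __init__(self, values, roles, conditions=None) -> None:
        arr = np.asarray(values, dtype=float)
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("binary dataset must contain only 0/1 values")
        super().__init__(values, roles, conditions)
        self.values = self.values.astype(np.int8)


@dataclass(frozen=True)
class Family:
    """A child node with its candidate parents (its prior in-neighbourhood).

    The parent order is lexicographic so that subset enumeration is
    deterministic.
    """

    child: str
    candidate_parents: tuple[str, ...]

    def __post_init__(self) -> None:
        if tuple(sorted(self.candidate_parents)) != self.candidate_parents:
            raise ValueError("candidate_parents must be sorted lexicographically")
        if self.child in self.candidate_parents:
            raise ValueError("child cannot be its own parent")


class PriorNetwork:
    """The initial search structure: typed edges among role-tagged nodes.

    Duplicate edges are collapsed; all invariants of :class:`TypedEdge`
    (five types, no self-loops, mRNA never a source) are enforced on entry.
    """

    def __init__(self, roles: Mapping[str, GeneRole], edges: Iterable[TypedEdge]) -> None:
        self.roles: dict[str, GeneRole] = dict(roles)
        edge_set = frozenset(edges)
        for e in edge_set:
            for endpoint in (e.source, e.target):
                if endpoint not in self.roles:
                    raise ValueError(f"edge endpoint {endpoint!r} has no role")
            if edge_type_label(self.roles[e.source], self.roles[e.target]) != e.edge_type:
                raise ValueError(f"edge {e} inconsistent with node roles")
        self.edges: frozenset[TypedEdge] = edge_set

    @property
    def nodes(self) -> list[str]:
        return sorted(self.roles)

    def edge_type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TYPES}
        for e in self.edges:
            counts[e.edge_type] += 1
        return counts

    def in_edges(self, child: str) -> list[TypedEdge]:
        return sorted(e for e in self.edges if e.target == child)

    def families(self, include_parentless: bool = False) -> list[Family]:
        """Decompose into child-with-candidate-parents families."""
        parents: dict[str, list[str]] = {}
        for e in self.edges:
            parents.setdefault(e.target, []).append(e.source)
        fams = [
            Family(child, tuple(sorted(ps))) for child, ps in parents.items()
        ]
        if include_parentless:
            orphan = set(self.roles) - set(parents)
            fams.extend(Family(g, ()) for g in orphan)
        return sorted(fams, key=lambda f: f.child)

    def __len__(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:
        return f"<PriorNetwork {len(self.roles)} nodes, {len(self.edges)} edges>"


@dataclass(frozen=True)
class EdgeConfidence:
    """Bootstrap support for one edge under the binomial confidence model.

    ``Q`` counts the bootstrap-condition runs in which the edge was learnt;
    ``trials = C * n_boot``. Under the null the edge is learnt by chance with
    probability 0.5, so ``p_value`` is the upper tail of Binomial(trials, 0.5)
    at Q.
    """

    edge: TypedEdge
    Q: int
    trials: int
    p_value: float
    null_p: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.Q <= self.trials:
            raise ValueError(f"Q={self.Q} outside [0, trials={self.trials}]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


class GlobalNetwork:
    """The integrated significant-edge network.

    Cycles are permitted: integrating per-condition structures can produce
    feedback pairs (e.g. a TF repressing a miRNA that silences the TF), so
    the result is a directed graph, not a Bayesian network.
    """

    def __init__(
        self,
        roles: Mapping[str, GeneRole],
        confidences: Iterable[EdgeConfidence],
        threshold: float = 0.05,
    ) -> None:
        self.roles = dict(roles)
        self.threshold = float(threshold)
        conf = {c.edge: c for c in confidences}
        for c in conf.values():
            if not c.p_value < threshold:
                raise ValueError(
                    f"edge {c.edge} has p={c.p_value} >= threshold {threshold}"
                )
        self.confidences: dict[TypedEdge, EdgeConfidence] = conf

    @property
    def edges(self) -> frozenset[TypedEdge]:
        return frozenset(self.confidences)

    @property
    def nodes(self) -> list[str]:
        incident: set[str] = set()
        for e in self.confidences:
            incident.add(e.source)
            incident.add(e.target)
        return sorted(incident)

    def to_frame(self) -> pd.DataFrame:
        """Edge table sorted by (source, target): the canonical TSV layout."""
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "edge_type": e.edge_type,
                "Q": c.Q,
                "trials": c.trials,
                "p_value": c.p_value,
            }
            for e, c in self.confidences.items()
        ]
        frame = pd.DataFrame(
            rows, columns=["source", "target", "edge_type", "Q", "trials", "p_value"]
        )
        return frame.sort_values(["source", "target"], ignore_index=True)

    def __len__(self) -> int:
        return len(self.confidences)

    def __repr__(self) -> str:
        return (
            f"<GlobalNetwork {len(self.nodes)} nodes, {len(self)} edges, "
            f"p<{self.threshold}>"
        )
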