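"""Model/Results interface over the full learning pipeline.

:class:`RegulatoryNetworkModel` holds the data (continuous expression with
condition labels plus a target edge list) and a :class:`RunConfig`;
``fit(seed)`` runs differential-expression filtering, discretisation,
condition-wise splitting, bootstrapped per-condition structure learning,
and binomial integration, returning a :class:`RegulatoryNetworkResults`
carrying the global network, per-edge bootstrap confidences, stage
diagnostics, and a ``summary()`` table. Interplay extraction and motif
significance hang off the results object.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as tio
from .bootstrap import binomial_pvalue, count_edge_events, integrate
from .core import (
    BinaryExpressionDataset,
    ExpressionDataset,
    GeneRole,
    GlobalNetwork,
    PriorNetwork,
    TypedEdge,
)
from .motifs import MotifReport, extract_interplay, motif_significance
from .preprocess import (
    DEFAULT_DE_THRESHOLDS,
    differential_expression,
    discretize,
    select_de_genes,
    split_by_condition,
)
from .prior import build_prior_network
from .scoring import BDeConfig

__all__ = ["RunConfig", "RegulatoryNetworkModel", "RegulatoryNetworkResults"]


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline.

    de_thresholds
        Role-specific adjusted-p cut-offs for the differential-expression
        filter (strict ``<``).
    bde_alpha
        Equivalent sample size of the BDeu score.
    n_boot
        Bootstrap iterations per condition; with C conditions every edge
        has ``trials = C * n_boot``.
    edge_p_threshold
        Binomial-confidence cut-off for admitting an edge to the global
        network (strict ``<``).
    motif_n_random, motif_swap_factor
        Null-model size and edge-switching intensity for FFL significance.
    """

    de_thresholds: dict[GeneRole, float] | None = field(
        default_factory=lambda: dict(DEFAULT_DE_THRESHOLDS)
    )
    bde_alpha: float = 1.0
    n_boot: int = 100
    edge_p_threshold: float = 0.05
    motif_n_random: int = 1000
    motif_swap_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for role, alpha in (self.de_thresholds or {}).items():
            if not 0.0 < alpha < 1.0:
                raise ValueError(f"DE threshold for {role} outside (0,1): {alpha}")
        if not 0.0 < self.edge_p_threshold < 1.0:
            raise ValueError("edge_p_threshold must be in (0,1)")
        for name in ("n_boot", "motif_n_random", "motif_swap_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        valid = {
            "de_thresholds",
            "bde_alpha",
            "n_boot",
            "edge_p_threshold",
            "motif_n_random",
            "motif_swap_factor",
            "seed",
        }
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(
                f"invalid config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        kwargs = dict(raw)
        if kwargs.get("de_thresholds") is not None:
            kwargs["de_thresholds"] = {
                GeneRole.parse(k): float(v) for k, v in kwargs["de_thresholds"].items()
            }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        if self.de_thresholds is not None:
            out["de_thresholds"] = {r.value: a for r, a in self.de_thresholds.items()}
        return out


class RegulatoryNetworkModel:
    """Three-component regulatory network learner.

    Parameters
    ----------
    expression
        Continuous expression with gene roles and sample condition labels
        (exactly two conditions for the differential-expression stage).
    target_edges
        Sequence-predicted regulator->target edges (the prior knowledge).
    config
        Pipeline configuration; defaults are the standard study settings.
    """

    def __init__(
        self,
        expression: ExpressionDataset,
        target_edges: list[TypedEdge],
        config: RunConfig | None = None,
    ) -> None:
        if expression.conditions is None:
            raise ValueError("expression dataset needs condition labels")
        self.expression = expression
        self.target_edges = list(target_edges)
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        mirna_path: str | Path,
        tf_path: str | Path,
        mrna_path: str | Path,
        conditions_path: str | Path,
        targets_path: str | Path,
        config: RunConfig | None = None,
    ) -> "RegulatoryNetworkModel":
        """Assemble a model from the TSV exchange files."""
        parts = [
            tio.read_expression_table(mirna_path, GeneRole.MIRNA),
            tio.read_expression_table(tf_path, GeneRole.TF),
            tio.read_expression_table(mrna_path, GeneRole.MRNA),
        ]
        conditions = tio.read_condition_map(conditions_path)
        data = ExpressionDataset.concat(parts).with_conditions(conditions)
        edges, _ = tio.read_target_edges(targets_path, data.roles)
        return cls(data, edges, config)

    def fit(self, seed: int | None = None) -> "RegulatoryNetworkResults":
        """Run the full pipeline and return the fitted results."""
        cfg = self.config
        master_seed = cfg.seed if seed is None else seed
        if cfg.de_thresholds is None:
            # data already gene-filtered upstream: keep everything
            de = None
            selected = set(self.expression.gene_ids)
        else:
            de = differential_expression(self.expression)
            selected = select_de_genes(de, cfg.de_thresholds)
        prior = build_prior_network(self.target_edges, selected, self.expression.roles)
        working = self.expression.subset_genes(selected | set(prior.nodes))
        # expression that is already 0/1 (e.g. pre-discretised or simulated
        # in binary mode) is used as-is; the median rule is for continuous
        # platform data
        if np.isin(working.values.to_numpy(), (0.0, 1.0)).all():
            binary = BinaryExpressionDataset(
                working.values, working.roles, working.conditions
            )
        else:
            binary = discretize(working)
        per_condition = split_by_condition(binary)
        bde = BDeConfig(alpha=cfg.bde_alpha)
        counts = count_edge_events(
            prior, per_condition, cfg.n_boot, bde, seed=master_seed
        )
        network = integrate(counts, self.expression.roles, cfg.edge_p_threshold)
        return RegulatoryNetworkResults(
            model=self,
            seed=master_seed,
            de_results=de,
            selected_genes=frozenset(selected),
            prior=prior,
            edge_counts=counts,
            global_network=network,
        )


class RegulatoryNetworkResults:
    """Fitted pipeline output: global network, confidences, diagnostics."""

    def __init__(
        self,
        model: RegulatoryNetworkModel,
        seed: int,
        de_results: pd.DataFrame,
        selected_genes: frozenset[str],
        prior: PriorNetwork,
        edge_counts: dict[TypedEdge, tuple[int, int]],
        global_network: GlobalNetwork,
    ) -> None:
        self.model = model
        self.seed = seed
        self.de_results = de_results
        self.selected_genes = selected_genes
        self.prior = prior
        self.edge_counts = edge_counts
        self.global_network = global_network

    # -- derived tables ------------------------------------------------------

    def confidence_frame(self) -> pd.DataFrame:
        """Per-prior-edge bootstrap support: Q, trials, exact binomial p."""
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "edge_type": e.edge_type,
                "Q": q,
                "trials": trials,
                "p_value": binomial_pvalue(q, trials),
                "significant": binomial_pvalue(q, trials)
                < self.model.config.edge_p_threshold,
            }
            for e, (q, trials) in self.edge_counts.items()
        ]
        return pd.DataFrame(rows).sort_values(["source", "target"], ignore_index=True)

    def interplay(self) -> GlobalNetwork:
        """The miRNA-TF interplay subnetwork of the global network."""
        return extract_interplay(self.global_network)

    def motif_report(
        self,
        n_random: int | None = None,
        swap_factor: int | None = None,
        seed: int | None = None,
    ) -> MotifReport:
        """FFL enrichment of the global network against the null model."""
        cfg = self.model.config
        return motif_significance(
            self.global_network,
            n_random=cfg.motif_n_random if n_random is None else n_random,
            swap_factor=cfg.motif_swap_factor if swap_factor is None else swap_factor,
            seed=self.seed if seed is None else seed,
        )

    def save_network(self, path: str | Path, fmt: str = "TSV") -> None:
        tio.write_network(self.global_network, fmt, path)

    def stage_counts(self) -> dict[str, int]:
        counts = self.model.expression.role_counts()
        sel_by_role = {
            role: sum(
                1 for g in self.selected_genes
                if self.model.expression.roles.get(g) is role
            )
            for role in GeneRole
        }
        return {
            "genes_total": self.model.expression.n_genes,
            "samples": self.model.expression.n_samples,
            "selected_mirna": sel_by_role[GeneRole.MIRNA],
            "selected_tf": sel_by_role[GeneRole.TF],
            "selected_mrna": sel_by_role[GeneRole.MRNA],
            "prior_edges": len(self.prior),
            "significant_edges": len(self.global_network),
        }

    def summary(self) -> str:
        """Human-readable run summary (counts per stage, top edges)."""
        cfg = self.model.config
        buf = _io.StringIO()
        counts = self.stage_counts()
        buf.write("Regulatory network learning results\n")
        buf.write("=" * 51 + "\n")
        for key, val in counts.items():
            buf.write(f"{key:<24}{val}\n")
        buf.write(
            f"{'trials per edge':<24}{len(set(self.model.expression.conditions.values())) * cfg.n_boot}\n"
        )
        buf.write(f"{'edge p threshold':<24}{cfg.edge_p_threshold}\n")
        buf.write(f"{'seed':<24}{self.seed}\n")
        frame = self.global_network.to_frame()
        if len(frame):
            buf.write("-" * 51 + "\n")
            buf.write("strongest edges (by Q):\n")
            top = frame.sort_values(["Q", "source", "target"], ascending=[False, True, True]).head(10)
            buf.write(top.to_string(index=False))
            buf.write("\n")
        return buf.getvalue()

    def plot_q_histogram(self, ax=None):
        """Histogram of bootstrap support Q over all prior edges."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        qs = [q for q, _ in self.edge_counts.values()]
        trials = max((t for _, t in self.edge_counts.values()), default=0)
        ax.hist(qs, bins=np.arange(0, trials + 2) - 0.5, color="steelblue")
        ax.set_xlabel("bootstrap support Q")
        ax.set_ylabel("prior edges")
        return ax
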