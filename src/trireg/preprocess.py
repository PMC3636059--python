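"""Differential-expression filtering, discretisation, condition splitting.

The filtering stage keeps, per role, the genes that differ between the two
biological conditions (Welch two-sample t-test, Benjamini–Hochberg
correction within each role, strict ``adj_p < alpha`` with role-specific
defaults: 0.01 for miRNAs, 0.1 for TFs and mRNAs). Expression from
heterogeneous platforms is then made comparable by discretising each
sample (array) at its own median: a value strictly above the column median
becomes 1 (up-regulation), otherwise 0. Finally samples are partitioned by
condition label for the condition-wise structure learning.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BinaryExpressionDataset, ExpressionDataset, GeneRole

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DE_THRESHOLDS",
    "differential_expression",
    "select_de_genes",
    "discretize",
    "split_by_condition",
]

#: Role-specific adjusted-p cut-offs for the differential-expression filter.
DEFAULT_DE_THRESHOLDS: dict[GeneRole, float] = {
    GeneRole.MIRNA: 0.01,
    GeneRole.TF: 0.1,
    GeneRole.MRNA: 0.1,
}


def differential_expression(
    data: ExpressionDataset,
    conditions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group Welch t-test per gene, BH-adjusted within each role.

    Returns a DataFrame indexed by gene with columns ``role``, ``statistic``,
    ``p_value`` and ``adj_p``. Requires exactly two conditions with at least
    two samples each. Genes with zero variance across all samples are
    dropped with a warning before testing (their statistic is undefined);
    genes constant within both groups get statistic 0 and p=1 when the group
    means agree, and p=0 otherwise.
    """
    cond = conditions if conditions is not None else data.conditions
    if cond is None:
        raise ValueError("no condition annotation supplied")
    labels = sorted(set(cond[s] for s in data.sample_ids))
    if len(labels) != 2:
        raise ValueError(f"differential expression needs exactly 2 conditions, got {len(labels)}")
    groups = [
        [s for s in data.sample_ids if cond[s] == lab] for lab in labels
    ]
    for lab, members in zip(labels, groups):
        if len(members) < 2:
            raise ValueError(f"condition {lab!r} has {len(members)} samples; need >= 2")

    values = data.values
    overall_var = values.var(axis=1, ddof=0)
    flat = overall_var == 0
    if flat.any():
        logger.warning(
            "dropping %d zero-variance genes before differential expression", int(flat.sum())
        )
        values = values.loc[~flat]

    a = values[groups[0]].to_numpy(float)
    b = values[groups[1]].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, pval = stats.ttest_ind(a, b, axis=1, equal_var=False)
    stat = np.asarray(stat, float)
    pval = np.asarray(pval, float)

    # Both groups internally constant: Welch's denominator is 0 and scipy
    # returns nan. Equal means -> no evidence (p=1); different means ->
    # perfectly separated (p=0).
    degenerate = np.isnan(pval)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        stat[degenerate & equal_means] = 0.0
        pval[degenerate & equal_means] = 1.0
        sep = degenerate & ~equal_means
        stat[sep] = np.sign(a.mean(axis=1) - b.mean(axis=1))[sep] * np.inf
        pval[sep] = 0.0
        if (degenerate & equal_means).any():
            logger.warning(
                "%d genes constant within both groups with equal means; p set to 1",
                int((degenerate & equal_means).sum()),
            )

    result = pd.DataFrame(
        {
            "role": [data.roles[g].value for g in values.index],
            "statistic": stat,
            "p_value": pval,
        },
        index=values.index,
    )
    result["adj_p"] = np.nan
    for role in GeneRole:
        mask = result["role"] == role.value
        if mask.any():
            result.loc[mask, "adj_p"] = multipletests(
                result.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    return result


def select_de_genes(
    results: pd.DataFrame,
    thresholds: Mapping[GeneRole, float] | None = None,
) -> set[str]:
    """Genes whose BH-adjusted p is strictly below the role's threshold."""
    thr = dict(DEFAULT_DE_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    for role, alpha in thr.items():
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"threshold for {role} must be in (0,1), got {alpha}")
    selected: set[str] = set()
    for gene, row in results.iterrows():
        if row["adj_p"] < thr[GeneRole.parse(row["role"])]:
            selected.add(str(gene))
    return selected


def discretize(data: ExpressionDataset) -> BinaryExpressionDataset:
    """Binarise each sample at its own median (strictly above -> 1).

    The cut-off is per array: sample j's column median. Ties with the median
    map to 0, so discretisation is invariant under strictly monotone
    per-column transforms of the raw values.
    """
    if data.n_genes == 0:
        raise ValueError("cannot discretise a dataset with no genes")
    medians = data.values.median(axis=0)
    binary = (data.values > medians).astype(np.int8)
    return BinaryExpressionDataset(binary, data.roles, data.conditions)


def split_by_condition(
    data: BinaryExpressionDataset,
) -> dict[str, BinaryExpressionDataset]:
    """Partition the sample columns by condition label (sorted labels)."""
    if data.conditions is None:
        raise ValueError("dataset has no condition annotation")
    out: dict[str, BinaryExpressionDataset] = {}
    for label in data.condition_labels():
        cols = [s for s in data.sample_ids if data.conditions[s] == label]
        out[label] = BinaryExpressionDataset(
            data.values[cols], data.roles, {s: label for s in cols}
        )
    return out
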