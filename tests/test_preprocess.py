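import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trireg.core import BinaryExpressionDataset, ExpressionDataset, GeneRole
from trireg.preprocess import (
    DEFAULT_DE_THRESHOLDS,
    differential_expression,
    discretize,
    select_de_genes,
    split_by_condition,
)


def _dataset(rows: dict[str, list[float]], conditions: dict[str, str], role=GeneRole.MRNA):
    samples = list(conditions)
    values = pd.DataFrame(rows, index=samples).T
    values.columns = samples
    return ExpressionDataset(values, {g: role for g in rows}, conditions)


def _two_group_conditions(n_a: int, n_b: int) -> dict[str, str]:
    cond = {f"a{i}": "A" for i in range(n_a)}
    cond.update({f"b{i}": "B" for i in range(n_b)})
    return cond


class TestDifferentialExpression:
    def test_separated_groups_highly_significant(self):
        cond = _two_group_conditions(3, 3)
        data = _dataset({"g1": [0.0, 0.1, -0.1, 5.0, 5.1, 4.9]}, cond)
        res = differential_expression(data)
        # independent check against the closed-form Welch t
        t_ref, p_ref = stats.ttest_ind(
            [0.0, 0.1, -0.1], [5.0, 5.1, 4.9], equal_var=False
        )
        assert res.loc["g1", "p_value"] == pytest.approx(p_ref, rel=1e-12)
        assert res.loc["g1", "p_value"] < 1e-4

    def test_identical_groups_give_zero_statistic_p_one(self):
        cond = _two_group_conditions(3, 3)
        data = _dataset({"g1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, cond)
        res = differential_expression(data)
        assert res.loc["g1", "statistic"] == 0.0
        assert res.loc["g1", "p_value"] == 1.0

    def test_constant_within_groups_equal_means_p_one(self):
        cond = _two_group_conditions(2, 2)
        data = _dataset(
            {"g1": [2.0, 2.0, 2.0, 2.0], "g2": [1.0, 2.0, 3.0, 4.0]}, cond
        )
        res = differential_expression(data)
        # g1 has zero overall variance: dropped entirely
        assert "g1" not in res.index

    def test_requires_two_samples_per_group(self):
        cond = {"a0": "A", "b0": "B", "b1": "B"}
        data = _dataset({"g1": [1.0, 2.0, 3.0]}, cond)
        with pytest.raises(ValueError, match=">= 2"):
            differential_expression(data)

    def test_requires_exactly_two_conditions(self):
        cond = {"a0": "A", "a1": "A", "b0": "B", "b1": "B", "c0": "C", "c1": "C"}
        data = _dataset({"g1": [1.0, 2, 3, 4, 5, 6]}, cond)
        with pytest.raises(ValueError, match="exactly 2"):
            differential_expression(data)


def _bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Independent step-up BH: min over the tail of p*m/rank, clipped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBenjaminiHochberg:
    def test_textbook_vector(self):
        cond = _two_group_conditions(3, 3)
        # four genes engineered to give distinct raw p; check the BH
        # transform itself on the oracle instead of the raw values
        raw = np.array([0.01, 0.02, 0.03, 0.04])
        assert _bh_oracle(raw) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(
        pvals=st.lists(
            st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=40
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_statsmodels_matches_step_up_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        arr = np.asarray(pvals)
        adj = multipletests(arr, method="fdr_bh")[1]
        assert adj == pytest.approx(_bh_oracle(arr), abs=1e-12)


class TestSelection:
    def _results(self, rows):
        return pd.DataFrame(rows).set_index("gene")

    def test_threshold_is_strict(self):
        res = self._results(
            [
                {"gene": "g1", "role": "mRNA", "adj_p": 0.1},
                {"gene": "g2", "role": "mRNA", "adj_p": 0.0999},
            ]
        )
        assert select_de_genes(res) == {"g2"}

    def test_role_specific_defaults(self):
        res = self._results(
            [
                {"gene": "m1", "role": "miRNA", "adj_p": 0.005},
                {"gene": "m2", "role": "miRNA", "adj_p": 0.05},
                {"gene": "t1", "role": "TF", "adj_p": 0.05},
            ]
        )
        assert select_de_genes(res) == {"m1", "t1"}

    def test_all_insignificant_empty(self):
        res = self._results([{"gene": "g", "role": "mRNA", "adj_p": 1.0}])
        assert select_de_genes(res) == set()

    def test_invalid_threshold_rejected(self):
        res = self._results([{"gene": "g", "role": "mRNA", "adj_p": 0.5}])
        with pytest.raises(ValueError):
            select_de_genes(res, {GeneRole.MRNA: 1.5})


class TestDiscretize:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([1, 2, 3, 4, 5], [0, 0, 0, 1, 1]),  # odd length: median element -> 0
            ([7, 7, 7], [0, 0, 0]),  # constant column
            ([1, 2, 3, 4], [0, 0, 1, 1]),  # even length: midpoint median 2.5
        ],
    )
    def test_median_cutoff_per_sample(self, column, expected):
        genes = [f"g{i}" for i in range(len(column))]
        values = pd.DataFrame({"s1": column}, index=genes)
        data = ExpressionDataset(values, {g: GeneRole.MRNA for g in genes})
        out = discretize(data)
        assert out.values["s1"].tolist() == expected

    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000),
            min_size=2,
            max_size=25,
            unique=True,
        ).map(lambda ints: [v / 7.0 for v in ints])
    )
    @settings(max_examples=60, deadline=None)
    def test_distinct_column_has_floor_half_ones_and_monotone_invariance(self, col):
        genes = [f"g{i}" for i in range(len(col))]
        values = pd.DataFrame({"s1": col}, index=genes)
        data = ExpressionDataset(values, {g: GeneRole.MRNA for g in genes})
        out = discretize(data)
        assert int(out.values["s1"].sum()) == len(col) // 2
        # strictly monotone transform leaves the discretisation unchanged
        transformed = ExpressionDataset(
            np.exp(values / 50.0), {g: GeneRole.MRNA for g in genes}
        )
        assert discretize(transformed).values.equals(out.values)


class TestSplit:
    def test_study_design_partition(self):
        cond = {f"e{i}": "epithelial" for i in range(11)}
        cond.update({f"m{i}": "mesenchymal" for i in range(36)})
        values = pd.DataFrame(
            np.random.default_rng(0).integers(0, 2, size=(3, 47)),
            index=["g1", "g2", "g3"],
            columns=list(cond),
        )
        data = BinaryExpressionDataset(
            values, {g: GeneRole.MRNA for g in values.index}, cond
        )
        parts = split_by_condition(data)
        assert parts["epithelial"].n_samples == 11
        assert parts["mesenchymal"].n_samples == 36
        # partition property: sample columns exactly recovered
        recovered = sorted(
            s for p in parts.values() for s in p.sample_ids
        )
        assert recovered == sorted(data.sample_ids)
        for p in parts.values():
            assert p.gene_ids == data.gene_ids

    def test_single_condition_is_identity(self):
        values = pd.DataFrame([[0, 1]], index=["g1"], columns=["s1", "s2"])
        data = BinaryExpressionDataset(
            values, {"g1": GeneRole.MRNA}, {"s1": "X", "s2": "X"}
        )
        parts = split_by_condition(data)
        assert list(parts) == ["X"]
        assert parts["X"].values.equals(data.values)
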