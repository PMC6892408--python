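"""Genomics threshold filters against brute-force and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mgmorph as mg


def bh_step_up_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


class TestBHAdjust:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 300))
            assert np.allclose(mg.bh_adjust(p), bh_step_up_oracle(p))

    def test_hand_evaluated_example(self):
        # step-up on (0.01, 0.02, 0.03, 0.04): every adjusted value is 0.04
        assert np.allclose(mg.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_equal_p_unchanged(self):
        assert np.allclose(mg.bh_adjust([0.2] * 7), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mg.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_bounds_and_monotonicity(self, p):
        adjusted = mg.bh_adjust(p)
        assert (adjusted >= np.asarray(p) - 1e-12).all()
        assert (adjusted <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adjusted[order]) >= -1e-12).all()  # order-preserving


class TestDegFilter:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "mean_tpm", "fold_change", "p", "fdr"]
        )

    def test_joint_criterion_and_direction(self):
        table = self._table(
            [
                ("up_ok", 5.0, 1.4, 1e-4, 0.04),
                ("low_tpm", 3.9, 2.0, 1e-6, 0.001),
                ("down_ok", 10.0, 0.70, 1e-4, 0.01),
                ("weak_fc", 10.0, 1.1, 1e-4, 0.01),
                ("high_fdr", 10.0, 2.0, 0.04, 0.20),
                ("tpm_at_bound", 4.0, 2.0, 1e-6, 0.001),  # "greater than four"
            ]
        )
        up, down = mg.deg_filter(table)
        assert up["gene_id"].tolist() == ["up_ok"]
        assert down["gene_id"].tolist() == ["down_ok"]

    def test_symmetric_down_threshold_is_reciprocal(self):
        # 1/1.3 ~ 0.769: FC 0.75 passes symmetric reading, fails the 0.7 one
        table = self._table([("g", 10.0, 0.75, 1e-4, 0.01)])
        _, down = mg.deg_filter(table)
        assert down["gene_id"].tolist() == ["g"]
        _, down_linear = mg.deg_filter(
            table, mg.FilterCriteria(symmetric_down=False)
        )
        assert down_linear.empty

    def test_missing_fdr_computed_from_p(self):
        table = self._table([("a", 10.0, 2.0, 0.001, np.nan),
                             ("b", 10.0, 2.0, 0.9, np.nan)])
        up, _ = mg.deg_filter(table)
        assert up["gene_id"].tolist() == ["a"]

    def test_filter_idempotent(self):
        table = mg.generate_gene_stat_table(n_genes=800, n_true_de=60, seed=1)
        table["fdr"] = mg.bh_adjust(table["p"])
        up, down = mg.deg_filter(table)
        up2, down2 = mg.deg_filter(up)
        assert up2["gene_id"].tolist() == up["gene_id"].tolist()
        assert down2.empty
        _, down3 = mg.deg_filter(down)
        assert down3["gene_id"].tolist() == down["gene_id"].tolist()

    def test_matches_brute_force_row_scan(self):
        table = mg.generate_gene_stat_table(n_genes=1000, n_true_de=80, seed=2)
        table["fdr"] = mg.bh_adjust(table["p"])
        up, down = mg.deg_filter(table)
        expected_up, expected_down = set(), set()
        for _, row in table.iterrows():
            if row.mean_tpm > 4.0 and row.fdr < 0.05:
                if row.fold_change >= 1.3:
                    expected_up.add(row.gene_id)
                elif row.fold_change <= 1 / 1.3:
                    expected_down.add(row.gene_id)
        assert set(up["gene_id"]) == expected_up
        assert set(down["gene_id"]) == expected_down


class TestTopLists:
    def _tables(self, gene_lists):
        tables = {}
        for name, genes in gene_lists.items():
            tables[name] = pd.DataFrame(
                {
                    "gene_id": genes,
                    "mean_tpm": 10.0,
                    "fold_change": 2.0,
                    "p": np.linspace(1e-8, 1e-6, len(genes)),
                    "fdr": 0.001,
                }
            )
        return tables

    def test_disjoint_lists_union_sums(self):
        tables = self._tables(
            {"t1": [f"a{i}" for i in range(5)],
             "t2": [f"b{i}" for i in range(5)],
             "t3": [f"c{i}" for i in range(5)]}
        )
        per, union = mg.top_deg_lists(tables, k=5)
        assert all(len(v) == 5 for v in per.values())
        assert len(union) == 15

    def test_identical_lists_collapse(self):
        genes = [f"g{i}" for i in range(5)]
        tables = self._tables({"t1": genes, "t2": genes, "t3": genes})
        _, union = mg.top_deg_lists(tables, k=5)
        assert union == genes

    def test_sorted_by_p_with_gene_id_ties(self):
        table = pd.DataFrame(
            {
                "gene_id": ["z", "a", "m"],
                "mean_tpm": 10.0,
                "fold_change": 2.0,
                "p": [1e-6, 1e-6, 1e-8],
                "fdr": 0.001,
            }
        )
        per, _ = mg.top_deg_lists({"t": table}, k=3)
        assert per["t"] == ["m", "a", "z"]

    def test_fewer_than_k_warns_and_takes_all(self):
        tables = self._tables({"t": ["g1", "g2"]})
        with pytest.warns(UserWarning, match="only 2"):
            per, union = mg.top_deg_lists(tables, k=10)
        assert per["t"] == ["g1", "g2"]


class TestSetOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y", "z"}, {"y", "z", "w"}, (1, 2, 1)),
            ({"a", "b"}, {"c"}, (2, 0, 1)),
            ({"a"}, {"a", "b", "c"}, (0, 1, 2)),
        ],
    )
    def test_partition_counts(self, a, b, expected):
        assert mg.set_overlap(a, b) == expected


class TestTopVariableGenes:
    def test_ranks_by_variance(self):
        matrix = pd.DataFrame(
            {
                "s1": [0.0, 0.0, 0.0],
                "s2": [1.0, 2.0, 3.0],
            },
            index=["low", "mid", "high"],
        )
        assert mg.top_variable_genes(matrix, k=2) == ["high", "mid"]

    def test_constant_gene_never_beats_variable_gene(self):
        matrix = pd.DataFrame(
            {"s1": [5.0, 0.0], "s2": [5.0, 0.1]}, index=["flat", "wiggle"]
        )
        assert mg.top_variable_genes(matrix, k=1) == ["wiggle"]

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(
            rng.normal(size=(20, 6)), index=[f"g{i}" for i in range(20)]
        )
        shuffled = matrix[matrix.columns[::-1]]
        assert mg.top_variable_genes(matrix, 5) == mg.top_variable_genes(shuffled, 5)


class TestChipPeakFilter:
    def test_window_reads_and_significance(self):
        peaks = pd.DataFrame(
            {
                "peak_id": ["good", "far", "shallow", "weak_fc"],
                "tss_distance": [-800, 1500, 0, 1000],
                "reads_WT": [5, 10, 3, 20],
                "reads_KO": [1, 10, 3, 18],
                "fold_change": [5.0, 3.0, 4.0, 1.2],
                "idr": [0.01, 0.01, 0.01, 0.01],
            }
        )
        retained, significant = mg.chip_peak_filter(peaks)
        assert retained["peak_id"].tolist() == ["good", "weak_fc"]
        assert significant["peak_id"].tolist() == ["good"]

    def test_window_inclusive_at_1000bp(self):
        peaks = pd.DataFrame(
            {
                "peak_id": ["edge"],
                "tss_distance": [-1000],
                "reads_WT": [4],
                "reads_KO": [0],
                "fold_change": [0.4],
                "idr": [0.04],
            }
        )
        retained, significant = mg.chip_peak_filter(peaks)
        assert len(retained) == 1 and len(significant) == 1

    def test_filter_idempotent(self):
        peaks = mg.generate_peak_table(n_peaks=500, n_true=20, seed=4)
        retained, _ = mg.chip_peak_filter(peaks)
        retained2, _ = mg.chip_peak_filter(retained)
        assert retained2["peak_id"].tolist() == retained["peak_id"].tolist()


class TestQpcr:
    def test_equal_ct_normalises_to_unit_wt_mean(self):
        ct = [20.0, 21.0, 22.0, 23.0]
        groups = ["WT", "WT", "KO", "KO"]
        rel = mg.qpcr_relative_expression(ct, ct, groups)
        assert np.allclose(rel, 1.0)
        assert rel[np.array(groups) == "WT"].mean() == pytest.approx(1.0)

    def test_one_cycle_higher_halves_expression(self):
        rel = mg.qpcr_relative_expression(
            ct_gene=[20.0, 21.0], ct_reference=[20.0, 20.0], group_labels=["WT", "KO"]
        )
        assert rel.iloc[1] == pytest.approx(0.5)

    def test_one_cycle_lower_doubles_expression(self):
        rel = mg.qpcr_relative_expression(
            ct_gene=[20.0, 19.0], ct_reference=[20.0, 20.0], group_labels=["WT", "KO"]
        )
        assert rel.iloc[1] == pytest.approx(2.0)

    def test_missing_ct_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="missing Ct"):
            rel = mg.qpcr_relative_expression(
                [20.0, np.nan, 21.0], [20.0, 20.0, 20.0], ["WT", "WT", "KO"]
            )
        assert list(rel.index) == [0, 2]
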