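"""Descriptive summaries, Kruskal-Wallis machinery, correlations,
stratification and paired deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import chromstab as cs
from chromstab.errors import ConfigurationError, InputError

from conftest import table_from_values


class TestChromosomeSummary:
    def test_degenerate_distribution(self):
        table = table_from_values({"1": [4.0] * 5, "X": [4.0] * 3})
        for s in cs.chromosome_summary(table):
            assert s.mean == s.median == s.ci_low == s.ci_high == 4.0

    def test_pooled_autosome_row_is_gene_weighted(self):
        table = table_from_values({"1": [1.0, 2.0], "2": [10.0] * 6, "X": [5.0]})
        rows = {s.chromosome: s for s in cs.chromosome_summary(table)}
        per_chrom = [(rows["1"].mean, 2), (rows["2"].mean, 6)]
        expected = sum(m * n for m, n in per_chrom) / sum(n for _, n in per_chrom)
        assert rows["A"].mean == pytest.approx(expected)
        assert rows["A"].n == 8

    def test_empty_chromosomes_omitted_not_zero_filled(self):
        table = table_from_values({"1": [1.0, 2.0], "X": [3.0]})
        labels = [s.chromosome for s in cs.chromosome_summary(table)]
        assert labels == ["1", "A", "X"]

    def test_all_values_absent_is_input_error(self):
        table = cs.GeneTable(pd.DataFrame(
            {"gene_id": ["a"], "chromosome": ["1"]}))
        with pytest.raises(InputError):
            cs.chromosome_summary(table, "half_life_h")

    def test_ci_orders_and_contains_mean(self, rng):
        vals = rng.lognormal(2.0, 0.7, 40).tolist()
        table = table_from_values({"1": vals, "X": [1.0, 2.0, 3.0]})
        for s in cs.chromosome_summary(table):
            assert s.ci_low <= s.mean <= s.ci_high

    def test_bootstrap_ci_close_to_t_ci(self, rng):
        vals = rng.lognormal(2.0, 0.5, 200).tolist()
        table = table_from_values({"1": vals, "X": vals})
        t_ci = cs.chromosome_summary(table, ci_method="t")[0]
        b_ci = cs.chromosome_summary(table, ci_method="bootstrap", rng=rng)[0]
        assert b_ci.ci_low == pytest.approx(t_ci.ci_low, abs=0.3)
        assert b_ci.ci_high == pytest.approx(t_ci.ci_high, abs=0.3)


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        res = cs.kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_rank_formula(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 3*7
        res = cs.kruskal_wallis({"lo": [1, 2, 3], "hi": [4, 5, 6]})
        assert res.statistic == pytest.approx(12 / 42 * 87 - 21)
        assert res.statistic == pytest.approx(3.857142857, abs=1e-6)

    def test_matches_scipy_with_ties(self, rng):
        g1 = rng.integers(0, 5, 20).astype(float)
        g2 = rng.integers(0, 5, 25).astype(float)
        res = cs.kruskal_wallis({"a": g1, "b": g2})
        stat, p = sps.kruskal(g1, g2)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize(
        "groups", [{"a": [1.0]}, {"a": [1.0], "b": [np.nan]},
                   {"a": [1.0], "b": [2.0]}]
    )
    def test_contract_violations(self, groups):
        with pytest.raises(InputError):
            cs.kruskal_wallis(groups)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=30, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        half = len(values) // 2
        if half < 1 or len(values) - half < 1:
            return
        groups = {"a": values[:half], "b": values[half:]}
        logged = {k: np.log(v) for k, v in groups.items()}
        assert cs.kruskal_wallis(groups).statistic == pytest.approx(
            cs.kruskal_wallis(logged).statistic)

    def test_null_calibration_p_uniform(self):
        # 24 groups from one distribution: p should be U(0,1)
        rng = np.random.default_rng(42)
        pvals = [
            cs.kruskal_wallis(
                {str(g): rng.normal(size=10) for g in range(24)}
            ).p_value
            for _ in range(500)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestPairwiseTests:
    def test_identical_groups_all_corrected_p_one(self):
        table = table_from_values({"1": [1, 2, 3], "2": [1, 2, 3], "X": [1, 2, 3]})
        mat = cs.pairwise_chromosome_tests(table)
        assert (mat.values == 1.0).all()

    def test_correction_is_monotone_and_symmetric(self, rng):
        table = table_from_values(
            {c: rng.lognormal(2, 0.5, 30).tolist() for c in ["1", "2", "3", "X"]})
        corrected = cs.pairwise_chromosome_tests(table, correction="bonferroni")
        assert np.allclose(corrected.values, corrected.values.T)
        assert (np.diag(corrected.values) == 1.0).all()
        for a in corrected.index:
            for b in corrected.columns:
                if a == b:
                    continue
                raw = cs.kruskal_wallis(
                    {a: table.values_for("half_life_h", [a]),
                     b: table.values_for("half_life_h", [b])}).p_value
                assert corrected.loc[a, b] >= raw - 1e-12

    def test_holm_never_exceeds_bonferroni(self, rng):
        table = table_from_values(
            {c: rng.lognormal(2, 0.5, 25).tolist() for c in ["1", "2", "X"]})
        bonf = cs.pairwise_chromosome_tests(table, correction="bonferroni")
        holm = cs.pairwise_chromosome_tests(table, correction="holm")
        assert (holm.values <= bonf.values + 1e-12).all()

    def test_unknown_correction_is_config_error(self):
        table = table_from_values({"1": [1, 2], "X": [3, 4]})
        with pytest.raises(ConfigurationError):
            cs.pairwise_chromosome_tests(table, correction="fdr_by_magic")


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        n = 10
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(2 * n)],
            "chromosome": ["1"] * n + ["X"] * n,
            "half_life_h": list(range(n)) * 2,
            "rpkm": list(range(n)) + list(range(n, 0, -1)),
        })
        rho = cs.spearman_by_group(cs.GeneTable(df), "half_life_h", "rpkm")
        assert rho["A"] == pytest.approx(1.0)
        assert rho["X"] == pytest.approx(-1.0)

    def test_constant_input_reported_absent_not_zero(self):
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(6)],
            "chromosome": ["1", "1", "1", "X", "X", "X"],
            "half_life_h": [1.0, 2.0, 3.0] * 2,
            "rpkm": [5.0, 5.0, 5.0, 1.0, 2.0, 3.0],
        })
        rho = cs.spearman_by_group(cs.GeneTable(df), "half_life_h", "rpkm")
        assert rho["A"] is None
        assert rho["X"] == pytest.approx(1.0)

    def test_too_few_pairs_is_input_error(self):
        df = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"],
            "chromosome": ["1", "1", "1", "X"],
            "half_life_h": [1.0, 2.0, 3.0, 1.0],
            "rpkm": [1.0, 2.0, 3.0, 1.0],
        })
        with pytest.raises(InputError):
            cs.spearman_by_group(cs.GeneTable(df), "half_life_h", "rpkm")


class TestStratifyHousekeeping:
    @staticmethod
    def _table(hk_map):
        values = {"1": [2.0, 4.0, 6.0, 8.0], "X": [3.0, 6.0, 9.0, 12.0]}
        return table_from_values(values, is_housekeeping=hk_map)

    def test_all_housekeeping_boundary(self):
        hk = {f"{c}.g{i}": True for c in ("1", "X") for i in range(4)}
        res = cs.stratify_housekeeping(self._table(hk))
        assert ("A", False) not in res.cells
        assert res.count_ratio["A"] is None

    def test_balanced_flags_give_unit_count_ratio(self):
        hk = {f"{c}.g{i}": i % 2 == 0 for c in ("1", "X") for i in range(4)}
        res = cs.stratify_housekeeping(self._table(hk))
        assert res.count_ratio["A"] == pytest.approx(1.0)
        assert res.count_ratio["X"] == pytest.approx(1.0)

    def test_x_effect_visible_in_both_strata(self):
        params = cs.SyntheticParams(
            seed=21, genes_per_chromosome={"1": 2000, "X": 2000},
            halflife_cap_h=None)
        table, _ = cs.generate_gene_table(params)
        res = cs.stratify_housekeeping(table)
        for flag in (True, False):
            assert res.cells[("X", flag)].mean > res.cells[("A", flag)].mean

    def test_missing_flags_excluded_with_count(self):
        hk = {f"{c}.g{i}": (None if (c, i) == ("1", 0) else True)
              for c in ("1", "X") for i in range(4)}
        res = cs.stratify_housekeeping(self._table(hk))
        assert res.n_flag_missing == 1
        assert res.cells[("A", True)].n == 3


class TestPairedDelta:
    def test_identity_pair_all_deltas_zero(self):
        table = table_from_values({"1": [2.0, 3.0], "X": [4.0]})
        pair = pd.DataFrame({"gene_id": table.gene_ids,
                             "control": [2.0, 3.0, 4.0],
                             "treatment": [2.0, 3.0, 4.0]})
        delta = cs.paired_condition_delta(pair, table)
        assert (delta["mean_delta"] == 0.0).all()

    def test_uniform_shift(self):
        table = table_from_values({"1": [2.0, 3.0], "X": [4.0]})
        pair = pd.DataFrame({"gene_id": table.gene_ids,
                             "control": [2.0, 3.0, 4.0],
                             "treatment": [4.0, 5.0, 6.0]})
        delta = cs.paired_condition_delta(pair, table)
        assert (delta["mean_delta"] == 2.0).all()

    def test_only_doubly_measured_genes_used(self):
        table = table_from_values({"1": [2.0, 3.0], "X": [4.0]})
        pair = pd.DataFrame({"gene_id": table.gene_ids,
                             "control": [2.0, np.nan, 4.0],
                             "treatment": [4.0, 5.0, 6.0]})
        delta = cs.paired_condition_delta(pair, table).set_index("chromosome")
        assert delta.loc["1", "n"] == 1
        assert delta.loc["A", "n"] == 1

    def test_empty_pairing_is_input_error(self):
        table = table_from_values({"1": [2.0]})
        pair = pd.DataFrame({"gene_id": ["nope"], "control": [1.0],
                             "treatment": [2.0]})
        with pytest.raises(InputError):
            cs.paired_condition_delta(pair, table)


class TestXaaRatio:
    def test_equal_means_unit_ratio(self):
        table = table_from_values({"1": [3.0, 5.0], "X": [4.0]})
        assert cs.xaa_ratio(table) == pytest.approx(1.0)

    def test_doubled_x(self):
        table = table_from_values({"1": [3.0, 5.0], "X": [8.0]})
        assert cs.xaa_ratio(table) == pytest.approx(2.0)

    def test_zero_autosomal_mean_rejected(self):
        table = table_from_values({"1": [0.0, 0.0], "X": [1.0]})
        with pytest.raises(InputError):
            cs.xaa_ratio(table)

    def test_random_relabelling_destroys_the_x_effect(self):
        # permutation safety: once chromosome labels are shuffled the
        # planted stability effect must vanish
        params = cs.SyntheticParams(seed=13, halflife_cap_h=None)
        table, _ = cs.generate_gene_table(params)
        rng = np.random.default_rng(99)
        ratios = []
        for _ in range(10):
            shuffled = table.df.copy()
            shuffled["chromosome"] = rng.permutation(shuffled["chromosome"].values)
            ratios.append(cs.xaa_ratio(cs.GeneTable(shuffled)))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)
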