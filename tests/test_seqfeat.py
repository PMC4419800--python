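"""GC/GC3 content, CDS validation, the 1..6-mer word matrix with its
brute-force oracle, UV-scaled PCA and poly(A) merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import chromstab as cs
from chromstab.errors import InputError

from conftest import table_from_values

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        # ATGNNC: N excluded from numerator and denominator -> 2 GC / 4 bases
        [("ATGC", 0.5), ("GGCC", 1.0), ("ATGNNC", 0.5), ("AATT", 0.0)],
    )
    def test_values(self, seq, expected):
        assert cs.gc_content(seq) == pytest.approx(expected)

    def test_all_n_reported_absent(self):
        assert cs.gc_content("NNNN") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            cs.gc_content("")

    @given(dna)
    def test_invariant_under_reverse_complement(self, seq):
        assert cs.gc_content(seq) == pytest.approx(
            cs.gc_content(cs.reverse_complement(seq)))


class TestGc3Content:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGGCGTTT", 2 / 3),  # thirds G, G, T
            ("ATG", 1.0),
            ("AAATTTCCC", 1 / 3),  # thirds A, T, C
            ("ATAGCTTTA", 0.0),    # thirds all A/T
        ],
    )
    def test_values(self, seq, expected):
        assert cs.gc3_content(seq) == pytest.approx(expected)

    def test_partial_codon_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="partial codon"):
            assert cs.gc3_content("ATGG") == pytest.approx(1.0)

    def test_no_complete_codon_is_input_error(self):
        with pytest.raises(InputError):
            cs.gc3_content("AT")

    def test_n_thirds_excluded(self):
        assert cs.gc3_content("AANAAG") == pytest.approx(1.0)


class TestFilterCds:
    def test_59nt_with_start_rejected_too_short(self):
        rec = cs.SeqRecord("a", "ATG" + "A" * 56)
        valid, rejected = cs.filter_cds([rec])
        assert not valid
        assert rejected[0].reject_reason == "too_short"

    def test_60nt_with_start_kept(self):
        rec = cs.SeqRecord("a", "ATG" + "A" * 57)
        valid, rejected = cs.filter_cds([rec])
        assert valid and not rejected

    def test_no_start_codon_rejected(self):
        rec = cs.SeqRecord("a", "GTG" + "A" * 87)
        _, rejected = cs.filter_cds([rec])
        assert rejected[0].reject_reason == "no_start_codon"

    def test_too_short_takes_precedence(self):
        rec = cs.SeqRecord("a", "GTGAAA")
        _, rejected = cs.filter_cds([rec])
        assert rejected[0].reject_reason == "too_short"

    def test_partition_and_idempotence(self, rng):
        recs = [
            cs.SeqRecord(f"s{i}",
                         ("ATG" if rng.random() < 0.7 else "CCC")
                         + "ACGT" * int(rng.integers(10, 40)))
            for i in range(50)
        ]
        valid, rejected = cs.filter_cds(recs)
        assert len(valid) + len(rejected) == len(recs)
        again_valid, again_rejected = cs.filter_cds([v.record for v in valid])
        assert len(again_valid) == len(valid) and not again_rejected


def brute_force_counts(seqs, k):
    """Independent oracle: count word occurrences by scanning substrings."""
    counts = {"".join(w): 0 for w in itertools.product("ACGT", repeat=k)}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if "N" not in word:
                counts[word] += 1
    return counts


class TestKmerMatrix:
    def test_hand_counted_normalization(self):
        km = cs.kmer_word_matrix(
            {"X": [cs.SeqRecord("u", "AAAA", "X")]}, k_max=2)
        assert km.frame.loc["X", "A"] == pytest.approx(1.0)   # 4 / 4
        assert km.frame.loc["X", "AA"] == pytest.approx(3 / 4)
        assert km.frame.loc["X", "C"] == 0.0

    def test_column_count_is_5460(self):
        km = cs.kmer_word_matrix(
            {"1": [cs.SeqRecord("u", "ACGTACGTAC", "1")]}, k_max=6)
        assert km.frame.shape[1] == 4 + 16 + 64 + 256 + 1024 + 4096 == 5460

    def test_matches_brute_force_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(8)]
        km = cs.kmer_word_matrix(
            {"1": [cs.SeqRecord(f"u{i}", s, "1") for i, s in enumerate(seqs)]},
            k_max=4)
        for k in range(1, 5):
            oracle = brute_force_counts(seqs, k)
            for word, n in oracle.items():
                assert km.counts.loc["1", word] == n

    def test_n_windows_skipped(self):
        km = cs.kmer_word_matrix(
            {"1": [cs.SeqRecord("u", "ACNGT", "1")]}, k_max=2)
        # dimers: AC, CN, NG, GT -> only AC and GT count
        assert km.counts.loc["1"][4:].sum() == 2
        assert km.counts.loc["1", "AC"] == 1 and km.counts.loc["1", "GT"] == 1

    def test_words_never_span_sequence_boundaries(self):
        km = cs.kmer_word_matrix(
            {"1": [cs.SeqRecord("a", "AA", "1"), cs.SeqRecord("b", "AA", "1")]},
            k_max=2)
        assert km.counts.loc["1", "AA"] == 2  # not 3: no window across records

    def test_counts_sum_invariant(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), int(n)))
                for n in rng.integers(10, 50, 6)]
        km = cs.kmer_word_matrix(
            {"1": [cs.SeqRecord(f"u{i}", s, "1") for i, s in enumerate(seqs)]},
            k_max=3)
        for k in range(1, 4):
            words = [w for w in km.counts.columns if len(w) == k]
            expected = sum(max(0, len(s) - k + 1) for s in seqs)
            assert km.counts.loc["1", words].sum() == expected

    def test_short_sequences_rejected(self):
        with pytest.raises(InputError, match="length"):
            cs.kmer_word_matrix({"1": [cs.SeqRecord("u", "ACG", "1")]}, k_max=6)


class TestUvScalePca:
    @staticmethod
    def _matrix(X, cols=None):
        cols = cols or [f"w{j}" for j in range(X.shape[1])]
        frame = pd.DataFrame(X, index=[f"chr{i}" for i in range(len(X))],
                             columns=cols)
        return frame

    def test_rank_one_matrix_pc1_explains_everything(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer([1.0, 2.0, 3.5, 0.5, 1.5], v)
        res = cs.uv_scale_pca(self._matrix(X), n_components=2)
        assert res.explained_variance_pct[0] > 99.9

    def test_scores_invariant_to_positive_column_scaling(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 10))
        r1 = cs.uv_scale_pca(self._matrix(X), 2)
        X2 = X.copy()
        X2[:, 3] *= 50.0
        r2 = cs.uv_scale_pca(self._matrix(X2), 2)
        np.testing.assert_allclose(r1.scores.values, r2.scores.values,
                                   atol=1e-10)

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(5, 20))
        b = rng.normal(1.0, 0.1, size=(5, 20))
        res = cs.uv_scale_pca(self._matrix(np.vstack([a, b])), 2)
        pc1 = res.scores["PC1"].values
        assert (pc1[:5].max() < pc1[5:].min()) or (pc1[5:].max() < pc1[:5].min())

    def test_remaining_variance_convention(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 12))
        res = cs.uv_scale_pca(self._matrix(X), 3)
        pct = np.array(res.explained_variance_pct)
        assert res.explained_remaining_pct[0] == pytest.approx(pct[0])
        assert res.explained_remaining_pct[1] == pytest.approx(
            100 * pct[1] / (100 - pct[0]))

    def test_fractions_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 30))
        res = cs.uv_scale_pca(self._matrix(X), n_components=4)
        assert res.r2_cumulative == pytest.approx(1.0)

    def test_zero_variance_columns_dropped(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 6))
        X[:, 2] = 7.0
        res = cs.uv_scale_pca(self._matrix(X), 2)
        assert res.n_dropped_columns == 1
        assert "w2" not in res.loadings.index

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            cs.uv_scale_pca(self._matrix(np.ones((1, 4))), 1)


class TestMergePolya:
    def test_disjoint_gene_sets_rejected(self):
        table = table_from_values({"1": [5.0]})
        polya = pd.DataFrame({"gene_id": ["other"], "polya_len": [70.0]})
        with pytest.raises(InputError):
            cs.merge_polya(table, polya)

    def test_constant_tail_means(self):
        table = table_from_values({"1": [5.0, 6.0], "X": [7.0]})
        polya = pd.DataFrame({"gene_id": table.gene_ids,
                              "polya_len": [72.0] * 3})
        res = cs.merge_polya(table, polya)
        assert all(s.mean == pytest.approx(72.0) for s in res.summaries)
        assert res.spearman_rho is None  # constant tails: undefined

    def test_incomplete_entries_discarded_and_counted(self):
        table = table_from_values({"1": [5.0, 6.0, None], "X": [7.0]})
        polya = pd.DataFrame({"gene_id": table.gene_ids,
                              "polya_len": [70.0, None, 75.0, 72.0]})
        res = cs.merge_polya(table, polya)
        assert res.n_discarded == 2
        assert len(res.merged) == 2

    def test_independent_tails_uncorrelated(self):
        params = cs.SyntheticParams(
            seed=6, genes_per_chromosome={"1": 2800, "X": 200})
        table, _ = cs.generate_gene_table(params)
        rng = np.random.default_rng(8)
        polya = pd.DataFrame({
            "gene_id": table.gene_ids,
            "polya_len": rng.normal(72, 8, len(table)),
        })
        res = cs.merge_polya(table, polya)
        assert abs(res.spearman_rho) < 0.05
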