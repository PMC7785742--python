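"""Gene/cell filtering, informative-gene selection and the six input transforms."""

import math

import numpy as np
import pytest
from scipy.stats import rankdata

from scamine import (
    GeneAnnotation,
    annotate_and_filter_genes,
    filter_cells_by_detection,
    normalize_counts,
    select_informative_genes,
    tmm_factor,
)

from conftest import make_counts


class TestAnnotateAndFilterGenes:
    ann = GeneAnnotation(
        {
            "ENSG_A": ("ACTB", "protein_coding", "7"),
            "ENSG_B": ("RPS6", "protein_coding", "9"),
            "ENSG_C": ("XIST", "lncRNA", "X"),
            "ENSG_D": ("MT-CO1", "protein_coding", "MT"),
            "ENSG_E": ("MRPL2", "protein_coding", "6"),
        }
    )

    def test_biotype_ribo_mito_rules(self):
        counts = make_counts(np.arange(10).reshape(5, 2))
        counts.gene_ids = ["ENSG_A", "ENSG_B", "ENSG_C", "ENSG_D", "ENSG_E"]
        out = annotate_and_filter_genes(counts, self.ann)
        assert out.gene_ids == ["ACTB"]

    def test_duplicate_symbols_suffix_disambiguated(self):
        ann = GeneAnnotation(
            {
                "ENSG_1": ("DUP", "protein_coding", "1"),
                "ENSG_2": ("DUP", "protein_coding", "1"),
            }
        )
        counts = make_counts([[1, 2], [3, 4]])
        counts.gene_ids = ["ENSG_1", "ENSG_2"]
        out = annotate_and_filter_genes(counts, ann)
        assert out.gene_ids == ["DUP", "DUP.1"]
        assert out.values.tolist() == [[1, 2], [3, 4]]

    def test_unannotated_ids_dropped_and_empty_result_rejected(self):
        counts = make_counts([[1, 2]])
        counts.gene_ids = ["ENSG_UNKNOWN"]
        with pytest.raises(ValueError, match="no genes survive"):
            annotate_and_filter_genes(counts, self.ann)


class TestFilterCellsByDetection:
    def test_detection_counting_at_three_umi(self):
        # cells: [3,3,0] kept, [9,2,0] removed, [3,3,3] kept (min_genes=2)
        counts = make_counts(np.array([[3, 9, 3], [3, 2, 3], [0, 0, 3]]))
        out = filter_cells_by_detection(counts, min_genes=2, min_umi=3)
        assert out.cell_ids == ["c0", "c2"]
        assert out.gene_ids == counts.gene_ids

    def test_zero_threshold_keeps_everything(self):
        counts = make_counts(np.zeros((3, 4)))
        out = filter_cells_by_detection(counts, min_genes=0)
        assert out.cell_ids == counts.cell_ids

    def test_all_zero_cell_removed_and_total_removal_is_error(self):
        counts = make_counts(np.array([[0, 5], [0, 5]]))
        assert filter_cells_by_detection(counts, min_genes=1).cell_ids == ["c1"]
        with pytest.raises(ValueError):
            filter_cells_by_detection(make_counts(np.zeros((2, 2))), min_genes=1)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        counts = make_counts(rng.poisson(2, size=(30, 20)))
        once = filter_cells_by_detection(counts, min_genes=5)
        twice = filter_cells_by_detection(once, min_genes=5)
        assert once.cell_ids == twice.cell_ids
        assert np.array_equal(once.values, twice.values)


class TestSelectInformativeGenes:
    def test_two_stage_ranking_hand_example(self):
        # dispersions (var/mean, ddof=1): gA=8, gB=0, gC~3.07, gD~5.33, gE=0
        # totals: gA=8, gC=9, gD=12
        values = np.array(
            [
                [0, 0, 0, 8],    # gA
                [3, 3, 3, 3],    # gB
                [0, 4, 0, 5],    # gC
                [1, 1, 1, 9],    # gD
                [2, 2, 2, 2],    # gE
            ]
        )
        counts = make_counts(values)
        out = select_informative_genes(counts, n_dispersed=3, n_expressed=2)
        assert out.gene_ids == ["g2", "g3"]  # gC and gD, original order kept

    def test_identity_when_thresholds_cover_all(self):
        counts = make_counts(np.random.default_rng(1).poisson(3, (6, 5)))
        out = select_informative_genes(counts, n_dispersed=6, n_expressed=6)
        assert out.gene_ids == counts.gene_ids

    def test_constant_zero_gene_ranks_last(self):
        values = np.array([[0, 0, 0], [1, 5, 9], [2, 2, 8]])
        out = select_informative_genes(make_counts(values), n_dispersed=2, n_expressed=2)
        assert "g0" not in out.gene_ids

    def test_fewer_genes_than_requested_keeps_all_with_warning(self):
        counts = make_counts(np.random.default_rng(2).poisson(3, (4, 5)))
        out = select_informative_genes(counts, n_dispersed=10, n_expressed=10)
        assert out.gene_ids == counts.gene_ids


class TestNormalizations:
    def test_log10_pseudocount(self):
        out = normalize_counts(make_counts([[0], [9], [99]]), "log10")
        assert out.values[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert out.layer_tag == "log10"

    def test_clr_hand_example_and_zero_sum(self):
        # cell [0,3,8]: ln((x+1)/geomean(1,4,9)), geomean = 36**(1/3)
        out = normalize_counts(make_counts([[0], [3], [8]]), "clr")
        np.testing.assert_allclose(
            out.values[:, 0], [-1.1945, 0.1918, 1.0027], atol=5e-5
        )
        assert abs(out.values[:, 0].sum()) < 1e-9

    def test_clr_rows_sum_to_zero_on_random_data(self):
        counts = make_counts(np.random.default_rng(3).poisson(4, (40, 15)) + 0.0)
        out = normalize_counts(counts, "clr")
        np.testing.assert_allclose(out.values.sum(axis=0), 0.0, atol=1e-9)

    def test_sum_equalizes_totals_to_median(self):
        counts = make_counts(np.array([[4, 10], [6, 20]]))  # totals 10, 30
        out = normalize_counts(counts, "sum")
        np.testing.assert_allclose(out.values.sum(axis=0), [20.0, 20.0], atol=1e-9)

    def test_fq_equalizes_sorted_vectors(self):
        rng = np.random.default_rng(4)
        # tie-free values per cell so rank mapping is exact
        values = np.array([rng.permutation(20) * 1.0 + 1 for _ in range(6)]).T
        out = normalize_counts(make_counts(values), "fq")
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, sorted_cols.shape[1]):
            np.testing.assert_array_equal(sorted_cols[:, 0], sorted_cols[:, j])

    def test_tmm_identical_cells_have_unit_factor(self):
        col = np.array([5.0, 8.0, 1.0, 12.0])
        counts = make_counts(np.column_stack([col, col]))
        out = normalize_counts(counts, "tmm")
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], rtol=1e-12)
        assert tmm_factor(col, col) == 1.0

    def test_tmm_matches_independent_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_genes = rng.integers(40, 120)
            obs = rng.gamma(2.0, 3.0, n_genes).round(3)
            ref = rng.gamma(2.0, 3.0, n_genes).round(3)
            expected = _tmm_brute_force(obs, ref)
            assert math.isclose(tmm_factor(obs, ref), expected, rel_tol=1e-6)

    def test_rle_rescales_by_median_ratio_size_factor(self):
        rng = np.random.default_rng(6)
        base = rng.gamma(3.0, 4.0, 50)
        factors = np.array([1.0, 2.0, 0.5])
        counts = make_counts(np.column_stack([base * f for f in factors]))
        out = normalize_counts(counts, "rle")
        for j in range(1, 3):
            np.testing.assert_allclose(out.values[:, j], out.values[:, 0], rtol=1e-9)

    def test_unknown_method_and_zero_cell_errors(self):
        counts = make_counts([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="unknown normalization"):
            normalize_counts(counts, "cpm")
        with pytest.raises(ValueError, match="c1"):
            normalize_counts(counts, "clr")

    @pytest.mark.parametrize("method", ["log10", "clr", "fq", "sum", "tmm", "rle"])
    def test_cell_permutation_equivariance(self, method):
        rng = np.random.default_rng(7)
        values = rng.poisson(5, (30, 8)) + 1.0
        perm = rng.permutation(8)
        direct = normalize_counts(make_counts(values), method).values[:, perm]
        permuted = normalize_counts(make_counts(values[:, perm]), method).values
        np.testing.assert_allclose(direct, permuted, rtol=1e-12)


def _tmm_brute_force(obs, ref, logratio_trim=0.30, abs_expr_trim=0.05):
    """Literal transliteration of the weighted trimmed mean of M-values."""
    n_o, n_r = obs.sum(), ref.sum()
    m_vals, a_vals, weights = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m_vals.append(math.log2((o / n_o) / (r / n_r)))
            a_vals.append(0.5 * math.log2((o / n_o) * (r / n_r)))
            weights.append((n_o - o) / (n_o * o) + (n_r - r) / (n_r * r))
    n = len(m_vals)
    if n == 0 or all(abs(m - m_vals[0]) < 1e-15 for m in m_vals):
        return 1.0
    lo_m = math.floor(n * logratio_trim) + 1
    lo_a = math.floor(n * abs_expr_trim) + 1
    rm = rankdata(m_vals)
    ra = rankdata(a_vals)
    num = den = 0.0
    for i in range(n):
        if lo_m <= rm[i] <= n + 1 - lo_m and lo_a <= ra[i] <= n + 1 - lo_a:
            num += m_vals[i] / weights[i]
            den += 1.0 / weights[i]
    if den == 0:
        return 1.0
    return 2.0 ** (num / den)
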