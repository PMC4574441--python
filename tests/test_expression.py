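"""Expression profiling: Nalimov filtering, fold changes, collapse, aggregation."""

import numpy as np
import pandas as pd
import pytest

from nucpos.expression import (
    ExpressionMatrix,
    bac_expression,
    collapse_to_gene,
    fold_change,
    nalimov_critical,
    nalimov_filter,
    nalimov_statistic,
    neighborhood_expression,
    select_significant,
    volcano_table,
)
from nucpos.synthetic import SyntheticConfig, generate_expression


class TestNalimov:
    # classical printed critical values (three decimals)
    published = {
        (3, 0.05): 1.409, (4, 0.05): 1.645, (5, 0.05): 1.757, (6, 0.05): 1.814,
        (7, 0.05): 1.848, (8, 0.05): 1.870, (9, 0.05): 1.885, (10, 0.05): 1.895,
        (5, 0.01): 1.918, (5, 0.001): 1.982,
    }

    def test_critical_values_reproduce_published_table(self):
        for (n, alpha), expected in self.published.items():
            # printed tables truncate at the third decimal, hence 1e-3 slack
            assert nalimov_critical(n, alpha) == pytest.approx(expected, abs=1e-3)

    def test_hand_evaluated_statistic(self):
        """(1,1,1,1,10): mean 2.8, s 4.0249 -> q = 2.000 for the extreme value."""
        q, idx = nalimov_statistic(np.array([1, 1, 1, 1, 10.0]))
        assert q == pytest.approx(2.0, abs=1e-12)
        assert idx == 4

    def test_hand_example_excluded_at_p_001(self):
        kept, excluded = nalimov_filter([1, 1, 1, 1, 10.0], alpha=0.001)
        assert list(excluded) == [4]
        np.testing.assert_array_equal(kept, [1, 1, 1, 1])

    def test_constant_values_kept_degenerate(self, caplog):
        with caplog.at_level("INFO", logger="nucpos.expression"):
            kept, excluded = nalimov_filter([2.0, 2.0, 2.0, 2.0])
        assert excluded.size == 0 and kept.size == 4

    def test_too_few_values_kept_untested(self):
        kept, excluded = nalimov_filter([1.0, 9.0])
        assert excluded.size == 0 and kept.size == 2

    def test_single_pass_removes_at_most_one(self):
        kept, excluded = nalimov_filter([0.0, 0.0, 0.0, 50.0, -50.0], alpha=0.05)
        assert excluded.size <= 1

    def test_generator_planted_outliers_are_flagged(self):
        """Default-magnitude planted outliers exceed the alpha=0.001 critical value."""
        cfg = SyntheticConfig(rng_seed=31, n_genes=30, n_probes_per_gene=1,
                              outlier_rate=0.5)
        matrix, truth = generate_expression(cfg)
        assert len(truth) > 10
        flagged = 0
        for _, row in truth.iterrows():
            reps = matrix.replicates(row["condition"]).loc[row["probe_id"]].to_numpy()
            _, excluded = nalimov_filter(reps, alpha=0.001)
            flagged += list(excluded) == [int(row["replicate"])]
        assert flagged / len(truth) >= 0.95


def _toy_matrix():
    values = pd.DataFrame(
        {
            "a_r0": [5.0, 5.0], "a_r1": [5.1, 5.0], "a_r2": [4.9, 5.0],
            "b_r0": [7.0, 5.0], "b_r1": [7.1, 5.0], "b_r2": [6.9, 5.0],
        },
        index=["p1", "p2"],
    )
    conditions = pd.Series({c: c.split("_")[0] for c in values.columns})
    probes = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g1", "g2"]})
    return ExpressionMatrix(values, conditions, probes)


class TestFoldChange:
    def test_identical_means_give_unity(self):
        fc = fold_change(_toy_matrix(), "a", "b")
        assert fc.loc["p2", "fold_change"] == pytest.approx(1.0)

    def test_reciprocal_pair_property(self):
        m = _toy_matrix()
        ab = fold_change(m, "a", "b")["fold_change"]
        ba = fold_change(m, "b", "a")["fold_change"]
        np.testing.assert_allclose(ab * ba, 1.0, rtol=1e-12)

    def test_absent_condition_raises(self):
        with pytest.raises(KeyError):
            fold_change(_toy_matrix(), "a", "zz")

    def test_zero_noise_recovers_planted_log2fc_exactly(self):
        cfg = SyntheticConfig(rng_seed=1, n_genes=5, noise_sd=0.0, outlier_rate=0.0,
                              planted_log2fc={"gene_002": 1.5, "gene_004": -2.25})
        matrix, _ = generate_expression(cfg)
        fc = fold_change(matrix, "myoblast", "myotube")
        genes = collapse_to_gene(fc, matrix.probe_map)
        assert genes.loc["gene_002", "log2fc"] == pytest.approx(1.5, abs=1e-6)
        assert genes.loc["gene_004", "log2fc"] == pytest.approx(-2.25, abs=1e-6)
        assert genes.loc["gene_000", "fold_change"] == pytest.approx(1.0, abs=1e-9)

    def test_eleven_fold_plant_recovered_within_band(self):
        cfg = SyntheticConfig(rng_seed=8, n_genes=6, noise_sd=0.1,
                              planted_log2fc={"gene_000": np.log2(11.0)})
        matrix, _ = generate_expression(cfg)
        fc = fold_change(matrix, "myoblast", "myotube")
        genes = collapse_to_gene(fc, matrix.probe_map)
        assert 9.0 <= genes.loc["gene_000", "fold_change"] <= 13.0

    def test_selection_monotone_in_threshold(self):
        cfg = SyntheticConfig(rng_seed=3, n_genes=20,
                              planted_log2fc={"gene_000": 3.0, "gene_001": 1.0})
        matrix, _ = generate_expression(cfg)
        fc = fold_change(matrix, "myoblast", "myotube")
        n_selected = [
            select_significant(fc, p_threshold=t)["selected"].sum()
            for t in (1e-2, 1e-4, 4e-6, 1e-8)
        ]
        assert all(a >= b for a, b in zip(n_selected, n_selected[1:]))

    def test_selection_flags_only_tiny_p(self):
        cfg = SyntheticConfig(rng_seed=13, n_genes=12, noise_sd=0.05,
                              planted_log2fc={"gene_000": 3.5})
        matrix, _ = generate_expression(cfg)
        records = select_significant(fold_change(matrix, "myoblast", "myotube"))
        assert records["selected"].equals(records["t_p"] <= 4e-6)
        assert records.loc["gene_000_p0", "selected"]


class TestCollapseToGene:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["probe_id", "log2fc", "t_p"]).set_index("probe_id")
        df["fold_change"] = 2.0 ** df["log2fc"]
        return df

    def test_keeps_maximally_regulated_probe(self):
        records = self._records([("pA", 0.5, 0.01), ("pB", -2.0, 0.5)])
        probe_map = pd.DataFrame({"probe_id": ["pA", "pB"], "gene_id": ["g", "g"]})
        out = collapse_to_gene(records, probe_map)
        assert out.loc["g", "log2fc"] == -2.0

    def test_single_probe_identity(self):
        records = self._records([("pA", 0.7, 0.2)])
        probe_map = pd.DataFrame({"probe_id": ["pA"], "gene_id": ["g"]})
        assert collapse_to_gene(records, probe_map).loc["g", "log2fc"] == 0.7

    def test_tie_prefers_smaller_p_then_lexicographic(self):
        records = self._records([("pB", 1.0, 0.05), ("pA", -1.0, 0.01)])
        probe_map = pd.DataFrame({"probe_id": ["pA", "pB"], "gene_id": ["g", "g"]})
        assert collapse_to_gene(records, probe_map).loc["g", "probe_id"] == "pA"
        records = self._records([("pB", 1.0, 0.05), ("pA", -1.0, 0.05)])
        assert collapse_to_gene(records, probe_map).loc["g", "probe_id"] == "pA"


class TestGenomicAggregation:
    def _genes(self):
        return pd.DataFrame(
            {"chrom": "chr1", "start": [100_000, 150_000, 400_000],
             "end": [110_000, 160_000, 410_000], "value": [2.0, 4.0, 8.0]},
            index=["gA", "gB", "gC"],
        )

    def test_fully_contained_genes_average_unweighted(self):
        value, table = bac_expression(self._genes(), ("chr1", 90_000, 200_000))
        assert value == pytest.approx(3.0)
        assert (table["gene_overlap_fraction"] == 1.0).all()

    def test_partial_overlap_weighted_by_gene_fraction(self):
        # gA is 10 kb long; 4 kb overlap -> weight 0.4
        value, table = bac_expression(self._genes(), ("chr1", 106_000, 140_000))
        assert table.set_index("gene_id").loc["gA", "gene_overlap_fraction"] == pytest.approx(0.4)
        assert value == pytest.approx(0.4 * 2.0)

    def test_bac_with_no_genes_missing(self):
        value, table = bac_expression(self._genes(), ("chr1", 900_000, 1_000_000))
        assert np.isnan(value) and table.empty

    def test_neighborhood_window_arithmetic(self):
        genes = pd.DataFrame(
            {"chrom": "chr1", "start": [4_995_000, 4_100_000, 6_100_000],
             "end": [5_005_000, 4_110_000, 6_110_000], "value": [1.0, 3.0, 99.0]},
            index=["center", "inside", "outside"],
        )
        # center midpoint 5,000,000; window [4,000,000, 6,000,000)
        assert neighborhood_expression(genes, "center", 1_000_000) == pytest.approx(2.0)

    def test_neighborhood_single_gene(self):
        genes = self._genes()
        assert neighborhood_expression(genes, "gC", 1_000) == pytest.approx(8.0)


class TestVolcano:
    def test_neg_log10_mapping(self):
        records = pd.DataFrame({"fold_change": [2.0, 3.0], "t_p": [0.01, 1.0]})
        out = volcano_table(records)
        assert out["neg_log10_p"].tolist() == pytest.approx([2.0, 0.0])

    def test_zero_p_clamped(self, caplog):
        records = pd.DataFrame({"fold_change": [2.0], "t_p": [0.0]})
        with caplog.at_level("INFO", logger="nucpos.expression"):
            out = volcano_table(records)
        assert np.isfinite(out["neg_log10_p"]).all()

    def test_planted_significant_gene_above_threshold_line(self):
        cfg = SyntheticConfig(rng_seed=21, n_genes=8, noise_sd=0.05,
                              planted_log2fc={"gene_003": 3.0})
        matrix, _ = generate_expression(cfg)
        genes = collapse_to_gene(fold_change(matrix, "myoblast", "myotube"), matrix.probe_map)
        out = volcano_table(genes)
        assert out.loc["gene_003", "neg_log10_p"] > -np.log10(4e-6)


class TestExpressionMatrixValidation:
    def test_single_replicate_condition_rejected(self):
        values = pd.DataFrame({"a_r0": [1.0], "a_r1": [1.0], "b_r0": [1.0]}, index=["p"])
        conditions = pd.Series({"a_r0": "a", "a_r1": "a", "b_r0": "b"})
        with pytest.raises(ValueError, match="fewer than 2"):
            ExpressionMatrix(values, conditions)

    def test_unmapped_sample_rejected(self):
        values = pd.DataFrame({"a_r0": [1.0], "a_r1": [1.0]}, index=["p"])
        with pytest.raises(ValueError, match="without a condition"):
            ExpressionMatrix(values, pd.Series({"a_r0": "a"}))
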