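import numpy as np
import pytest

from humgut import (
    FeatureTable,
    TaxonomyMap,
    filter_by_taxon,
    group_mean_ceiling,
    rarefy,
    read_feature_table,
    to_presence_absence,
    write_feature_table,
)
from humgut.feature_tables import read_taxonomy, write_taxonomy


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        t = FeatureTable(["s1", "s2"], ["a", "b"], [[1, 0], [3, 2]])
        p = tmp_path / "t.tsv"
        write_feature_table(t, p)
        assert read_feature_table(p) == t

    def test_tsv_direct_read(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\ta\tb\ns1\t1\t0\ns2\t3\t2\n")
        t = read_feature_table(p)
        assert t.sample_ids == ("s1", "s2")
        assert t.asv_ids == ("a", "b")
        assert np.array_equal(t.counts, [[1, 0], [3, 2]])

    def test_non_integer_count_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\ta\tb\ns1\t1.5\t0\ns2\t3\t2\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_feature_table(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\ta\ta\ns1\t1\t0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_feature_table(p)
        p.write_text("sample_id\ta\tb\ns1\t1\t0\ns1\t3\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_feature_table(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            FeatureTable(["s1"], ["a"], [[-1]])

    def test_biom_json_read(self, tmp_path):
        import json

        obj = {
            "id": "x", "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table", "generated_by": "test", "date": "2000-01-01",
            "matrix_type": "sparse", "matrix_element_type": "int",
            "shape": [2, 2],
            "rows": [{"id": "a", "metadata": None}, {"id": "b", "metadata": None}],
            "columns": [{"id": "s1", "metadata": None}, {"id": "s2", "metadata": None}],
            "data": [[0, 0, 1], [1, 0, 3], [1, 1, 2]],
        }
        p = tmp_path / "t.biom"
        p.write_text(json.dumps(obj))
        t = read_feature_table(p, format="biom-json")
        assert t.sample_ids == ("s1", "s2")
        assert t.asv_ids == ("a", "b")
        assert np.array_equal(t.counts, [[1, 3], [0, 2]])

    def test_taxonomy_round_trip(self, tmp_path, toy_taxonomy):
        p = tmp_path / "tax.tsv"
        write_taxonomy(toy_taxonomy, ["a1", "a2"], p)
        tax = read_taxonomy(p)
        assert tax.at_rank("a1", "genus") == "Clostridium sensu stricto 1"
        assert tax.at_rank("a2", "phylum") == "Bacteroidota"


class TestRarefy:
    def test_row_sums_equal_depth(self, rng):
        counts = rng.integers(0, 50, size=(6, 30))
        counts[0] *= 10  # ensure at least one deep sample
        t = FeatureTable([f"s{i}" for i in range(6)], [f"a{j}" for j in range(30)], counts)
        depth = int(t.sample_totals().min())
        out, dropped = rarefy(t, depth, seed=1)
        assert dropped == []
        assert (out.sample_totals() == depth).all()

    def test_sample_at_exact_depth_unchanged(self):
        t = FeatureTable(["s"], ["a", "b", "c"], [[4, 0, 6]])
        out, _ = rarefy(t, 10, seed=0)
        assert np.array_equal(out.counts, t.counts)

    def test_shallow_samples_dropped_and_reported(self):
        t = FeatureTable(["deep", "shallow"], ["a", "b"], [[50, 50], [1, 1]])
        out, dropped = rarefy(t, 10, seed=0)
        assert dropped == ["shallow"]
        assert out.sample_ids == ("deep",)

    def test_all_samples_below_depth_errors(self):
        t = FeatureTable(["s1", "s2"], ["a"], [[3], [4]])
        with pytest.raises(ValueError, match="no samples at requested depth"):
            rarefy(t, 100, seed=0)

    def test_deterministic_given_seed(self):
        t = FeatureTable(["s"], [f"a{j}" for j in range(20)], [list(range(20))])
        a, _ = rarefy(t, 50, seed=42)
        b, _ = rarefy(t, 50, seed=42)
        assert a == b

    def test_zero_columns_retained(self):
        t = FeatureTable(["s"], ["a", "b"], [[100, 0]])
        out, _ = rarefy(t, 10, seed=0)
        assert out.asv_ids == ("a", "b")

    def test_hypergeometric_marginal_expectation(self):
        # mean subsampled count over many seeds ~ depth * count / total
        counts = np.array([10, 30, 60])
        t = FeatureTable(["s"], ["a", "b", "c"], [counts])
        depth, total, n_rep = 20, 100, 1000
        draws = np.array([rarefy(t, depth, seed=k)[0].counts[0] for k in range(n_rep)])
        expected = depth * counts / total
        # hypergeometric variance per ASV
        p = counts / total
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 3 * se)


class TestPresenceAbsence:
    def test_definition(self):
        t = FeatureTable(["s1", "s2"], ["a", "b"], [[0, 5], [2, 0]])
        out = to_presence_absence(t)
        assert np.array_equal(out.counts, [[0, 1], [1, 0]])

    def test_all_zero_row_unchanged_and_idempotent(self):
        t = FeatureTable(["s1", "s2"], ["a", "b"], [[0, 0], [9, 1]])
        once = to_presence_absence(t)
        assert np.array_equal(once.counts[0], [0, 0])
        assert to_presence_absence(once) == once


class TestGroupMeanCeiling:
    def test_ceiling_of_mean(self):
        t = FeatureTable(["s1", "s2"], ["a"], [[1], [2]])
        out = group_mean_ceiling(t, {"s1": "g", "s2": "g"})
        assert np.array_equal(out.counts, [[2]])  # mean 1.5 -> ceil 2

    def test_singleton_groups_are_identity(self, rng):
        counts = rng.integers(0, 9, size=(4, 6))
        t = FeatureTable([f"s{i}" for i in range(4)], [f"a{j}" for j in range(6)], counts)
        out = group_mean_ceiling(t, {s: s for s in t.sample_ids})
        assert np.array_equal(out.counts, t.counts)

    def test_all_zero_group_stays_zero(self):
        t = FeatureTable(["s1", "s2"], ["a"], [[0], [0]])
        out = group_mean_ceiling(t, {"s1": "g", "s2": "g"})
        assert out.counts[0, 0] == 0

    def test_unlabelled_sample_errors(self):
        t = FeatureTable(["s1", "s2"], ["a"], [[1], [2]])
        with pytest.raises(ValueError, match="without a group label"):
            group_mean_ceiling(t, {"s1": "g"})

    def test_orphan_grouping_entry_errors(self):
        t = FeatureTable(["s1"], ["a"], [[1]])
        with pytest.raises(ValueError, match="absent from table"):
            group_mean_ceiling(t, {"s1": "g", "ghost": "g2"})


class TestFilterByTaxon:
    def test_exact_rank_match(self, toy_table, toy_taxonomy):
        out = filter_by_taxon(toy_table, toy_taxonomy, "genus", "Bacteroides")
        assert out.asv_ids == ("a2",)
        assert np.array_equal(out.counts[:, 0], toy_table.counts[:, 1])

    def test_match_is_exact_not_substring(self, toy_table, toy_taxonomy):
        # 'Clostridium sensu stricto 1' must not swallow '... 13'
        out = filter_by_taxon(
            toy_table, toy_taxonomy, "genus", "Clostridium sensu stricto 1"
        )
        assert out.asv_ids == ("a1",)

    def test_case_and_whitespace_insensitive(self, toy_table, toy_taxonomy):
        out = filter_by_taxon(toy_table, toy_taxonomy, "domain", "  archaea ")
        assert out.asv_ids == ("a3",)

    def test_no_match_gives_zero_columns(self, toy_table, toy_taxonomy):
        out = filter_by_taxon(toy_table, toy_taxonomy, "genus", "Lactobacillus")
        assert out.asv_ids == ()
        assert out.shape == (6, 0)

    def test_unknown_rank_errors(self, toy_table, toy_taxonomy):
        with pytest.raises(ValueError, match="unknown rank"):
            filter_by_taxon(toy_table, toy_taxonomy, "kingdom", "Bacteria")

    def test_missing_taxonomy_means_no_match(self, toy_table):
        out = filter_by_taxon(toy_table, TaxonomyMap({}), "genus", "Bacteroides")
        assert out.asv_ids == ()
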