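import numpy as np
import pytest

from bodysize_assembly.data_model import (
    CountTable,
    FormatError,
    TaxonMap,
    filter_dominant_groups,
    rarefy,
    read_count_table,
    read_metadata,
    write_count_table,
)


class TestCountTableIO:
    def test_tsv_parse_row_sums(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\toA\toB\ns1\t1\t2\ns2\t3\t4\n")
        t = read_count_table(p)
        assert t.sample_ids == ["s1", "s2"]
        assert t.row_sums.tolist() == [3, 7]

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\toA\toB\ns1\t1\t-2\n")
        with pytest.raises(FormatError, match="oB"):
            read_count_table(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\toA\toB\ns1\t1\tx\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_count_table(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            CountTable(["s1", "s1"], ["o1"], np.array([[1], [2]]))

    def test_round_trip_identity(self, tmp_path, rng):
        counts = rng.integers(0, 50, size=(3, 5))
        counts[:, 2] = 0  # empty OTU column must survive the round trip
        t = CountTable([f"s{i}" for i in range(3)], [f"o{i}" for i in range(5)], counts)
        p = tmp_path / "rt.tsv"
        write_count_table(t, p)
        back = read_count_table(p)
        assert back.sample_ids == t.sample_ids
        assert back.otu_ids == t.otu_ids
        assert np.array_equal(back.counts, t.counts)

    def test_unwritable_path_raises(self, tiny_table, tmp_path):
        with pytest.raises(OSError):
            write_count_table(tiny_table, tmp_path / "nope" / "x.tsv")

    def test_biom_classic_text(self, tmp_path):
        p = tmp_path / "t.biom.txt"
        p.write_text(
            "# Constructed from biom file\n"
            "#OTU ID\ts1\ts2\noA\t1\t3\noB\t2\t4\n"
        )
        t = read_count_table(p, dialect="biom-text")
        assert t.sample_ids == ["s1", "s2"]
        assert t.otu_ids == ["oA", "oB"]
        assert t.row_sums.tolist() == [3, 7]


class TestMetadata:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,latitude,longitude,pH\ns1,10,20,6.5\ns2,11,21,7.0\ns3,12,22,7.5\n")
        recs = read_metadata(p)
        assert len(recs) == 3
        assert recs[0].env == {"pH": 6.5}

    def test_latitude_out_of_range(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,latitude,longitude\ns1,95,20\n")
        with pytest.raises(FormatError, match="latitude"):
            read_metadata(p)

    def test_text_column_ignored_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,latitude,longitude,site_name\ns1,10,20,alpha\ns2,11,21,beta\n")
        with caplog.at_level("WARNING"):
            recs = read_metadata(p)
        assert recs[0].env == {}
        assert any("site_name" in r.message for r in caplog.records)

    def test_missing_coordinates(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,pH\ns1,6.5\n")
        with pytest.raises(FormatError, match="latitude"):
            read_metadata(p)


class TestRarefy:
    def test_single_otu_forced(self):
        t = CountTable(["s1"], ["a", "b", "c"], np.array([[10, 0, 0]]))
        out = rarefy(t, 5, seed=0)
        assert out.counts.tolist() == [[5, 0, 0]]

    def test_depth_conserved_and_no_invention(self, rng):
        counts = rng.integers(0, 30, size=(4, 6)) + 1
        t = CountTable([f"s{i}" for i in range(4)], [f"o{i}" for i in range(6)], counts)
        out = rarefy(t, 20, seed=7)
        assert (out.row_sums == 20).all()
        assert (out.counts[counts == 0] == 0).all()
        assert (out.counts <= counts).all()

    def test_deterministic_given_seed(self, rng):
        counts = rng.integers(1, 40, size=(3, 8))
        t = CountTable([f"s{i}" for i in range(3)], [f"o{i}" for i in range(8)], counts)
        a = rarefy(t, 15, seed=3)
        b = rarefy(t, 15, seed=3)
        assert np.array_equal(a.counts, b.counts)

    def test_undersampled_error_names_samples(self):
        t = CountTable(["ok", "low"], ["a", "b"], np.array([[10, 10], [1, 1]]))
        with pytest.raises(ValueError, match="low"):
            rarefy(t, 10, seed=0)

    def test_expected_proportions_preserved(self):
        # hypergeometric subsampling is unbiased: mean rarefied proportion
        # over many seeds matches the original proportion within 3 SE
        counts = np.array([[60, 30, 10]])
        t = CountTable(["s1"], ["a", "b", "c"], counts)
        depth, n_seeds = 40, 1000
        draws = np.array([rarefy(t, depth, seed=s).counts[0] for s in range(n_seeds)])
        props = draws / depth
        expected = counts[0] / counts.sum()
        se = props.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        assert (np.abs(props.mean(axis=0) - expected) <= 3 * se + 1e-12).all()


class TestDominantGroupFilter:
    def _table_two_groups(self):
        # group A in 8/10 samples at ~2% pooled; group B in 7/10 at ~5%
        n = 10
        counts = np.zeros((n, 3), dtype=int)
        counts[:, 0] = 100  # background group C, everywhere
        counts[:8, 1] = 3   # A: presence 8/10, pooled 24/1109 ~ 2.2%
        counts[:7, 2] = 8   # B: presence 7/10, pooled 56/1080 ~ 5%
        t = CountTable([f"s{i}" for i in range(n)], ["c1", "a1", "b1"], counts)
        taxa = TaxonMap({"c1": "C", "a1": "A", "b1": "B"})
        return t, taxa

    def test_presence_threshold_drops_group(self):
        t, taxa = self._table_two_groups()
        kept = [g for g, _ in filter_dominant_groups(t, taxa)]
        assert "A" in kept and "B" not in kept  # B fails 80% presence

    def test_abundance_threshold(self):
        counts = np.array([[995, 5], [995, 5]])  # group B pooled 0.5%
        t = CountTable(["s1", "s2"], ["a1", "b1"], counts)
        taxa = TaxonMap({"a1": "A", "b1": "B"})
        kept = [g for g, _ in filter_dominant_groups(t, taxa)]
        assert kept == ["A"]

    def test_group_present_everywhere_at_10pct_included(self):
        counts = np.array([[90, 10], [90, 10], [90, 10]])
        t = CountTable(["s1", "s2", "s3"], ["a1", "b1"], counts)
        taxa = TaxonMap({"a1": "A", "b1": "B"})
        kept = dict(filter_dominant_groups(t, taxa))
        assert set(kept) == {"A", "B"}
        assert kept["B"].otu_ids == ["b1"]
        assert kept["B"].n_samples == 3

    def test_subsets_partition_otus(self, rng):
        counts = rng.integers(0, 20, size=(5, 9)) + 1
        otus = [f"o{i}" for i in range(9)]
        t = CountTable([f"s{i}" for i in range(5)], otus, counts)
        taxa = TaxonMap({o: f"G{i % 3}" for i, o in enumerate(otus)})
        subsets = filter_dominant_groups(t, taxa, min_rel_abund=0.0, min_presence=0.0)
        seen: list[str] = []
        for _, sub in subsets:
            seen.extend(sub.otu_ids)
        assert len(seen) == len(set(seen))
        assert set(seen) <= set(otus)

    def test_unmapped_otu_error(self, tiny_table):
        taxa = TaxonMap({"o1": "A"})
        with pytest.raises(KeyError, match="o2"):
            filter_dominant_groups(tiny_table, taxa)
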