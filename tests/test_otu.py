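import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grainscape import (OtuTable, abundance_threshold, aggregate_by_rank,
                        read_otu_table, remove_rare_otus, subsample,
                        write_otu_table)
from grainscape.otu import OtuTableError


class TestTableValidation:
    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[1, 2]], index=["s"], columns=["o", "o"])
        with pytest.raises(OtuTableError, match="duplicate OTU"):
            OtuTable(df)

    def test_rejects_negative_counts_with_cell_address(self):
        df = pd.DataFrame([[1, -1]], index=["s1"], columns=["oA", "oB"])
        with pytest.raises(OtuTableError, match=r"'s1'.*'oB'"):
            OtuTable(df)

    def test_rejects_empty_table(self):
        with pytest.raises(OtuTableError, match="at least one sample"):
            OtuTable(pd.DataFrame(columns=["o1"]))


class TestIO:
    def test_round_trip(self, small_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_otu_table(small_table, path)
        assert read_otu_table(path) == small_table

    def test_malformed_cell_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\totu_1\totu_2\ns1\t3\t-1\n")
        with pytest.raises(OtuTableError, match=r"'s1'.*'otu_2'"):
            read_otu_table(path)

    def test_mothur_shared_dialect_equals_plain(self, small_table, tmp_path):
        plain = tmp_path / "plain.tsv"
        write_otu_table(small_table, plain)
        shared = tmp_path / "t.shared"
        lines = ["label\tGroup\tnumOtus\t" + "\t".join(small_table.otu_ids)]
        for sid in small_table.sample_ids:
            row = small_table.sample(sid)
            lines.append(f"0.03\t{sid}\t{small_table.n_otus}\t" + "\t".join(map(str, row)))
        shared.write_text("\n".join(lines) + "\n")
        assert read_otu_table(shared).data.equals(read_otu_table(plain).data)


class TestRareOtuFilter:
    def test_singletons_and_doubletons_removed(self):
        # dataset-wide totals a:1, b:2, c:3 -> only c survives the <3 rule
        table = OtuTable(pd.DataFrame([[1, 2, 3]], index=["s"], columns=["a", "b", "c"]))
        assert remove_rare_otus(table).otu_ids == ["c"]

    def test_min_total_one_is_identity(self, small_table):
        assert remove_rare_otus(small_table, min_total=1) == small_table

    def test_matches_bruteforce_on_random_table(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 4, size=(6, 100))
        table = OtuTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(6)],
                                      columns=[f"o{j}" for j in range(100)]))
        expected = [f"o{j}" for j in range(100) if counts[:, j].sum() >= 3]
        assert remove_rare_otus(table).otu_ids == expected

    def test_idempotent_and_counts_unaltered(self, small_table):
        once = remove_rare_otus(small_table)
        twice = remove_rare_otus(once)
        assert once == twice
        assert once.data.equals(small_table.data[once.otu_ids])

    def test_rejects_min_total_below_one(self, small_table):
        with pytest.raises(OtuTableError):
            remove_rare_otus(small_table, min_total=0)


class TestSubsample:
    def test_full_depth_is_identity(self, small_table):
        # sampling all reads without replacement returns the original counts
        sub = subsample(small_table, depth=10, seed=0)
        assert sub == small_table

    def test_row_sums_equal_depth(self):
        rng = np.random.default_rng(7)
        table = OtuTable(pd.DataFrame(rng.integers(0, 50, (4, 30)),
                                      index=list("wxyz"),
                                      columns=[f"o{j}" for j in range(30)]))
        sub = subsample(table, depth=int(table.depths().min()), seed=1)
        assert (sub.depths() == table.depths().min()).all()

    def test_excess_depth_names_sample(self, small_table):
        with pytest.raises(OtuTableError, match="'s1'"):
            subsample(small_table, depth=11)

    def test_seeded_determinism(self, small_table):
        a = subsample(small_table, depth=5, seed=9)
        b = subsample(small_table, depth=5, seed=9)
        assert a == b

    def test_hypergeometric_mean(self):
        # repeated rarefaction of one sample: per-OTU mean -> depth * count/total
        counts = np.array([50, 30, 12, 8])
        table = OtuTable(pd.DataFrame([counts], index=["s"], columns=list("abcd")))
        rng = np.random.default_rng(0)
        depth, reps = 40, 2000
        draws = np.vstack([
            subsample(table, depth, seed=rng, keep_zeros=True).counts[0]
            for _ in range(reps)
        ])
        expected = depth * counts / counts.sum()
        n_tot = counts.sum()
        p = counts / n_tot
        var = depth * p * (1 - p) * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 5 * se)


class TestAbundanceThreshold:
    def test_zero_threshold_is_identity(self, small_table):
        assert abundance_threshold(small_table, 0.0) == small_table

    def test_strict_inequality_at_exact_permille(self):
        # 1 read of 1000 is exactly 1 permille -> not > 1 permille -> zeroed
        table = OtuTable(pd.DataFrame([[1, 999]], index=["s"], columns=["lo", "hi"]))
        out = abundance_threshold(table, 1.0)
        assert out.otu_ids == ["hi"]

    def test_point1_permille_at_study_depth(self):
        # at depth 44901, counts of 4 (0.089 permille) drop, 5 (0.111) survive
        row = {"four": 4, "five": 5, "rest": 44892}
        table = OtuTable(pd.DataFrame([row], index=["g1"]))
        out = abundance_threshold(table, 0.1)
        assert set(out.otu_ids) == {"five", "rest"}


class TestAggregateByRank:
    def test_single_family_collapses_to_row_sums(self, small_table, taxonomy):
        tax_one = type(taxonomy)({o: ("Bacteria", "P", "C", "O", "F") for o in small_table.otu_ids})
        agg = aggregate_by_rank(small_table, tax_one, "family")
        assert agg.n_otus == 1
        assert (agg.counts[:, 0] == small_table.depths().to_numpy()).all()

    def test_two_family_split_matches_hand_sums(self, small_table, taxonomy):
        agg = aggregate_by_rank(small_table, taxonomy, "family")
        # FamX = otu_a + otu_b, FamY = otu_c + otu_d
        assert agg.data.loc["s1", "FamX"] == 6 and agg.data.loc["s1", "FamY"] == 4
        assert agg.data.loc["s3", "FamX"] == 3 and agg.data.loc["s3", "FamY"] == 7

    def test_grand_total_conserved_and_unmapped_warn(self, small_table, taxonomy):
        del taxonomy.lineages["otu_d"]
        with pytest.warns(UserWarning, match="unclassified"):
            agg = aggregate_by_rank(small_table, taxonomy, "family")
        assert agg.counts.sum() == small_table.counts.sum()
        assert "unclassified" in agg.otu_ids

    def test_partial_lineage_buckets_under_parent(self, small_table, taxonomy):
        taxonomy.lineages["otu_d"] = ("Bacteria", "P2")
        agg = aggregate_by_rank(small_table, taxonomy, "family")
        assert "unclassified_P2" in agg.otu_ids


@given(st.lists(st.integers(0, 30), min_size=2, max_size=20).filter(lambda c: sum(c) >= 3))
@settings(max_examples=50, deadline=None)
def test_filter_never_alters_retained_counts(counts):
    table = OtuTable(pd.DataFrame([counts], index=["s"],
                                  columns=[f"o{i}" for i in range(len(counts))]))
    out = remove_rare_otus(table)
    assert out.data.equals(table.data[out.otu_ids])
    assert remove_rare_otus(out) == out


@given(st.lists(st.integers(0, 20), min_size=2, max_size=15).filter(lambda c: sum(c) >= 5),
       st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_subsample_rows_always_sum_to_depth(counts, seed):
    table = OtuTable(pd.DataFrame([counts], index=["s"],
                                  columns=[f"o{i}" for i in range(len(counts))]))
    sub = subsample(table, depth=5, seed=seed, keep_zeros=True)
    assert sub.depths().iloc[0] == 5
    assert (sub.counts <= table.counts).all()
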