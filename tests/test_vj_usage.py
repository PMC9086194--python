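"""Rearrangement parsing, usage matrices and repertoire summaries."""

import numpy as np
import pandas as pd
import pytest

from repsel.vj_usage import (
    ClonotypeTable,
    RearrangementFormatError,
    compute_vj_usage,
    log2_usage_ratio,
    read_airr_rearrangements,
    summarize_repertoire,
)


def write_tsv(path, rows, columns=("v_call", "j_call", "duplicate_count")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
    return path


class TestReadRearrangements:
    def test_alleles_stay_distinct_clonotypes_but_share_gene_pair(self, tmp_path):
        p = write_tsv(tmp_path / "s.tsv", [
            ("TRBV19*01", "TRBJ2-1*01", 3),
            ("TRBV19*02", "TRBJ2-1*01", 2),
        ])
        t = read_airr_rearrangements(p)
        assert t.n_unique_clonotypes == 2
        assert t.clonal_count == 5
        assert t.vj_pairs() == {"TRBV19/TRBJ2-1": 2}

    def test_single_row_single_clonotype(self, tmp_path):
        p = write_tsv(tmp_path / "s.tsv", [("TRBV19*01", "TRBJ2-1*01", 5)])
        t = read_airr_rearrangements(p)
        assert t.n_unique_clonotypes == 1
        assert t.clonal_count == 5

    def test_ten_row_fixture_matches_hand_count(self, tmp_path):
        # hand-countable: 3 distinct VJ gene pairs, 5 distinct clonotypes
        rows = [
            ("TRBV19*01", "TRBJ2-1*01", 1),
            ("TRBV19*01", "TRBJ2-1*01", 2),   # duplicate row, same clonotype
            ("TRBV19*02", "TRBJ2-1*01", 1),
            ("TRBV20-1*01", "TRBJ1-2*01", 4),
            ("TRBV20-1*01", "TRBJ1-2*01", 1),
            ("TRBV20-1*02", "TRBJ1-2*01", 2),
            ("TRBV5-1*01", "TRBJ2-7*01", 3),
            ("TRBV5-1*01", "TRBJ2-7*01", 1),
            ("TRBV5-1*01", "TRBJ2-7*01", 1),
            ("TRBV19*01", "TRBJ2-1*01", 1),
        ]
        t = read_airr_rearrangements(write_tsv(tmp_path / "s.tsv", rows))
        assert t.n_unique_clonotypes == 5
        assert t.clonal_count == 17
        assert t.vj_pairs() == {
            "TRBV19/TRBJ2-1": 2,
            "TRBV20-1/TRBJ1-2": 2,
            "TRBV5-1/TRBJ2-7": 1,
        }

    def test_ambiguous_multi_gene_call_takes_first(self, tmp_path):
        p = write_tsv(tmp_path / "s.tsv", [("TRBV6-2*01,TRBV6-3*01", "TRBJ1-1*01", 1)])
        t = read_airr_rearrangements(p)
        assert t.vj_pairs() == {"TRBV6-2/TRBJ1-1": 1}

    def test_missing_column_and_empty_file_errors(self, tmp_path):
        p = write_tsv(tmp_path / "bad.tsv", [("TRBV1*01", 1)], columns=("v_call", "duplicate_count"))
        with pytest.raises(RearrangementFormatError, match="j_call"):
            read_airr_rearrangements(p)
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(RearrangementFormatError):
            read_airr_rearrangements(empty)

    def test_dialect_map_for_legacy_columns(self, tmp_path):
        p = write_tsv(tmp_path / "s.tsv", [("TRBV1*01", "TRBJ1-1*01", 7)],
                      columns=("vGene", "jGene", "reads"))
        t = read_airr_rearrangements(
            p, dialect={"v_call": "vGene", "j_call": "jGene", "count": "reads"}
        )
        assert t.clonal_count == 7


class TestUsage:
    def table(self, sid, pairs):
        return ClonotypeTable(sid, [(v, j, 1) for v, j in pairs])

    def test_fraction_of_unique_clonotypes(self):
        t = self.table("a", [("TRBV19", "TRBJ2-1"), ("TRBV19", "TRBJ2-1"),
                             ("TRBV5-1", "TRBJ1-2"), ("TRBV6-4", "TRBJ2-7")])
        m = compute_vj_usage([t])
        assert m.to_frame().loc["a", "TRBV19/TRBJ2-1"] == pytest.approx(0.5)

    def test_single_pair_sample_is_one_hot(self):
        t1 = self.table("a", [("V1", "J1")] * 3)
        t2 = self.table("b", [("V2", "J2"), ("V1", "J1")])
        m = compute_vj_usage([t1, t2]).to_frame()
        assert m.loc["a", "V1/J1"] == 1.0
        assert m.loc["a", "V2/J2"] == 0.0

    def test_three_sample_fixture_matches_hand_fractions(self):
        tables = [
            self.table("s1", [("V1", "J1"), ("V1", "J1"), ("V2", "J1"), ("V2", "J2")]),
            self.table("s2", [("V1", "J1"), ("V2", "J2")]),
            self.table("s3", [("V2", "J1"), ("V2", "J1"), ("V2", "J1")]),
        ]
        m = compute_vj_usage(tables).to_frame()
        expected = pd.DataFrame(
            [[0.5, 0.25, 0.25], [0.5, 0.0, 0.5], [0.0, 1.0, 0.0]],
            index=["s1", "s2", "s3"], columns=["V1/J1", "V2/J1", "V2/J2"],
        )
        pd.testing.assert_frame_equal(m, expected)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_invariant_to_record_order_and_read_splitting(self, tmp_path):
        rows = [("V1*01", "J1*01", 4), ("V2*01", "J1*01", 2)]
        split = [("V2*01", "J1*01", 1), ("V1*01", "J1*01", 3),
                 ("V1*01", "J1*01", 1), ("V2*01", "J1*01", 1)]
        a = read_airr_rearrangements(write_tsv(tmp_path / "a.tsv", rows), sample_id="s")
        b = read_airr_rearrangements(write_tsv(tmp_path / "b.tsv", split), sample_id="s")
        assert a.records == b.records
        np.testing.assert_allclose(
            compute_vj_usage([a]).values, compute_vj_usage([b]).values
        )

    def test_no_resolvable_pairs_errors(self):
        t = ClonotypeTable("bad", [(None, "J1", 1)])
        with pytest.raises(ValueError, match="bad"):
            compute_vj_usage([t])


class TestLog2Ratio:
    def test_identical_matrices_give_zero(self):
        t = [ClonotypeTable("a", [("V1", "J1", 1), ("V2", "J2", 1)]),
             ClonotypeTable("b", [("V1", "J1", 2), ("V2", "J1", 1)])]
        m = compute_vj_usage(t)
        r = log2_usage_ratio(m, m)
        assert r.mode == "log2_ratio"
        np.testing.assert_allclose(r.values, 0.0)

    def test_doubling_gives_about_one(self):
        from repsel.vj_usage import UsageMatrix
        post = UsageMatrix(["s"], ["V1/J1"], np.array([[0.8]]))
        base = UsageMatrix(["s"], ["V1/J1"], np.array([[0.4]]))
        r = log2_usage_ratio(post, base, pseudocount=1e-6)
        assert r.values[0, 0] == pytest.approx(1.0, abs=1e-4)

    def test_zero_over_zero_is_exactly_zero(self):
        from repsel.vj_usage import UsageMatrix
        # V2/J1 is unused at both timepoints (explicit 0 post, imputed 0 baseline)
        post = UsageMatrix(["s"], ["V1/J1", "V2/J1"], np.array([[1.0, 0.0]]))
        base = UsageMatrix(["s"], ["V1/J1"], np.array([[1.0]]))
        r = log2_usage_ratio(post, base, pseudocount=0.01).to_frame()
        assert r.loc["s", "V2/J1"] == 0.0

    def test_sample_mismatch_errors(self):
        from repsel.vj_usage import UsageMatrix
        a = UsageMatrix(["s1"], ["V1/J1"], np.array([[1.0]]))
        b = UsageMatrix(["s2"], ["V1/J1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="sample"):
            log2_usage_ratio(a, b)


class TestSummary:
    def test_single_sample_degenerate_range(self):
        t = ClonotypeTable("a", [("V1", "J1", 2), ("V2", "J1", 3)])
        s = summarize_repertoire([t])
        assert s.loc["all", "median_unique_clonotypes"] == 2
        assert s.loc["all", "min_clonal_counts"] == s.loc["all", "max_clonal_counts"] == 5

    def test_median_and_range_layout(self):
        # clonotype counts {589, 9431, 35065} -> median 9431, range [589, 35065]
        tables = []
        for sid, n_clones in (("a", 589), ("b", 9431), ("c", 35065)):
            recs = [(f"V{i % 7}", f"J{i % 3}", 1) for i in range(n_clones)]
            tables.append(ClonotypeTable(sid, recs))
        s = summarize_repertoire(tables)
        assert s.loc["all", "median_unique_clonotypes"] == 9431
        assert s.loc["all", "min_unique_clonotypes"] == 589
        assert s.loc["all", "max_unique_clonotypes"] == 35065
        assert s.loc["all", "unique_clonotypes"] == "9431 [589, 35065]"

    def test_five_samples_match_sort_oracle(self, rng):
        sizes = rng.integers(5, 40, size=5)
        tables = [
            ClonotypeTable(f"s{i}", [(f"V{k % 4}", f"J{k % 2}", int(rng.integers(1, 9)))
                                     for k in range(sz)])
            for i, sz in enumerate(sizes)
        ]
        s = summarize_repertoire(tables)
        uniq = sorted(t.n_unique_clonotypes for t in tables)
        assert s.loc["all", "median_unique_clonotypes"] == uniq[2]
        depths = sorted(t.clonal_count for t in tables)
        assert s.loc["all", "min_clonal_counts"] == depths[0]
        assert s.loc["all", "max_clonal_counts"] == depths[-1]

    def test_grouped_summary(self):
        tables = [ClonotypeTable("a", [("V1", "J1", 1)]),
                  ClonotypeTable("b", [("V1", "J1", 1), ("V2", "J1", 1)])]
        s = summarize_repertoire(tables, groups={"a": "case", "b": "control"})
        assert set(s.index) == {"case", "control"}
        assert s.loc["case", "n_samples"] == 1
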