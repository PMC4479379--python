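import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from generich import (
    CountTableError,
    CountVector,
    ExpressionMatrix,
    FrequencySpectrum,
    RichnessEstimate,
    collapse_libraries,
    is_complete,
    library_counts,
    read_count_table,
    read_spectrum_table,
    spectrum_from_counts,
    write_report,
)
from oracles import tally_spectrum

TSV_3x2 = "gene\tlibA\tlibB\ng1\t2\t0\ng2\t0\t3\ng3\t1\t1\n"


class TestCountVector:
    def test_totals(self):
        cv = CountVector(("a", "b", "c"), [1, 2, 3])
        assert (cv.N, cv.g) == (6, 3)

    @pytest.mark.parametrize(
        "ids,counts",
        [(("a", "b"), [1, 0]), (("a", "a"), [1, 2]), (("a",), [1, 2])],
    )
    def test_invariant_violations_raise(self, ids, counts):
        with pytest.raises(ValueError):
            CountVector(ids, counts)


class TestReadCountTable:
    def test_parses_matrix_and_library_names(self, write_table):
        m = read_count_table(write_table(TSV_3x2))
        assert m.libraries == ("libA", "libB")
        assert m.gene_ids == ("g1", "g2", "g3")
        assert m.counts.tolist() == [[2, 0], [0, 3], [1, 1]]

    def test_non_integer_count_rejected_with_line(self, write_table):
        path = write_table("gene\tlib\ng1\t2\ng2\t3.7\n")
        with pytest.raises(CountTableError, match="line 3.*non-integer count"):
            read_count_table(path)

    def test_empty_file(self, write_table):
        with pytest.raises(CountTableError, match="no data rows"):
            read_count_table(write_table(""))

    def test_header_only(self, write_table):
        with pytest.raises(CountTableError, match="no data rows"):
            read_count_table(write_table("gene\tlib\n"))

    def test_duplicate_gene_id(self, write_table):
        path = write_table("gene\tlib\ng1\t2\ng1\t3\n")
        with pytest.raises(CountTableError, match="duplicate gene id"):
            read_count_table(path)

    def test_negative_count(self, write_table):
        path = write_table("gene\tlib\ng1\t-2\n")
        with pytest.raises(CountTableError, match="negative"):
            read_count_table(path)

    def test_csv_delimiter_autodetected(self, write_table):
        path = write_table("gene,lib\ng1,5\n", name="counts.csv")
        m = read_count_table(path)
        assert m.counts.tolist() == [[5]]

    def test_parse_write_reparse_idempotent(self, write_table, tmp_path):
        m = read_count_table(write_table(TSV_3x2))
        out = tmp_path / "rt.tsv"
        pd.DataFrame(m.counts, index=list(m.gene_ids), columns=list(m.libraries)).to_csv(
            out, sep="\t", index_label="gene"
        )
        m2 = read_count_table(out)
        assert m2.gene_ids == m.gene_ids
        assert m2.libraries == m.libraries
        assert np.array_equal(m2.counts, m.counts)


class TestCollapseAndSlice:
    def test_collapse_row_sums(self):
        m = ExpressionMatrix(("a", "b"), ("x", "y"), [[2, 0], [0, 3]])
        cv = collapse_libraries(m)
        assert cv.counts.tolist() == [2, 3] and (cv.g, cv.N) == (2, 5)

    def test_collapse_drops_zero_total_genes(self):
        m = ExpressionMatrix(("a", "b"), ("x", "y"), [[0, 0], [1, 2]])
        cv = collapse_libraries(m)
        assert cv.gene_ids == ("b",) and cv.counts.tolist() == [3]

    def test_collapse_single_library_identity(self):
        m = ExpressionMatrix(("a", "b", "c"), ("x",), [[2], [0], [1]])
        assert collapse_libraries(m).counts.tolist() == [2, 1]

    def test_library_counts_filters_zeros(self):
        m = ExpressionMatrix(("a", "b", "c"), ("x",), [[2], [0], [1]])
        cv = library_counts(m, "x")
        assert cv.counts.tolist() == [2, 1] and cv.g == 2 and cv.N == 3

    def test_library_counts_matches_collapse_for_one_library(self):
        m = ExpressionMatrix(("a", "b", "c"), ("x",), [[2], [0], [1]])
        assert library_counts(m, "x").counts.tolist() == collapse_libraries(m).counts.tolist()

    def test_unknown_library(self):
        m = ExpressionMatrix(("a",), ("x",), [[1]])
        with pytest.raises(KeyError):
            library_counts(m, "nope")

    def test_all_zero_library(self):
        m = ExpressionMatrix(("a",), ("x", "y"), [[0, 1]])
        with pytest.raises(ValueError, match="no detected genes"):
            library_counts(m, "x")

    def test_collapse_dominates_each_library(self, rng):
        counts = rng.integers(0, 20, size=(30, 4))
        counts[rng.random(30) < 0.3] = 0
        keep = counts.sum(axis=1) >= 0
        m = ExpressionMatrix(tuple(f"g{i}" for i in range(30)), tuple("wxyz"), counts)
        total = collapse_libraries(m)
        per_lib = []
        for lib in m.libraries:
            try:
                per_lib.append(library_counts(m, lib))
            except ValueError:
                continue
        assert all(total.g >= cv.g for cv in per_lib)
        assert total.N == sum(int(counts[:, j].sum()) for j in range(4))


class TestSpectrum:
    def test_direct_tally(self):
        spec = spectrum_from_counts(CountVector(tuple("abcde"), [1, 1, 2, 3, 3]))
        assert spec.f == {1: 2, 2: 1, 3: 2}
        assert (spec.N, spec.g) == (10, 5)

    def test_singleton_vector(self):
        spec = spectrum_from_counts(CountVector(("a",), [5]))
        assert spec.f == {5: 1} and spec[4] == 0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=40), min_size=1, max_size=60))
    def test_matches_recount_oracle_and_accounting(self, counts):
        ids = tuple(f"g{i}" for i in range(len(counts)))
        cv = CountVector(ids, counts)
        spec = spectrum_from_counts(cv)
        assert spec.f == tally_spectrum(counts)
        assert sum(r * fr for r, fr in spec.f.items()) == cv.N
        assert sum(spec.f.values()) == cv.g

    def test_rejects_bad_classes(self):
        with pytest.raises(ValueError):
            FrequencySpectrum({0: 3})
        with pytest.raises(ValueError):
            FrequencySpectrum({2: -1})

    @pytest.mark.parametrize(
        "f,expected", [({2: 7}, True), ({1: 3, 2: 5}, False), ({2: 100, 3: 40, 7: 2}, True)]
    )
    def test_is_complete_rule(self, f, expected):
        assert is_complete(FrequencySpectrum(f)) is expected


class TestSpectrumTable:
    def test_round_trip(self, write_table):
        path = write_table("r\tf_r\n1\t3\n2\t9\n6\t439\n", name="spec.tsv")
        spec = read_spectrum_table(path)
        assert spec.f == {1: 3, 2: 9, 6: 439}

    def test_duplicate_class_rejected(self, write_table):
        with pytest.raises(CountTableError, match="duplicate"):
            read_spectrum_table(write_table("1\t3\n1\t4\n", name="spec.tsv"))


class TestWriteReport:
    EST = RichnessEstimate("h6", 1613.2, 20998, 371_000_000, se=52.0,
                           ci_lower=1511.08, ci_upper=1714.92)

    def test_single_row_with_header(self, tmp_path):
        out = tmp_path / "report.tsv"
        write_report([("sampleA", self.EST)], out)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split("\t")[:4] == ["sample", "N", "g", "f0_hat"]

    def test_csv_and_tsv_agree(self, tmp_path):
        a, b = tmp_path / "r.tsv", tmp_path / "r.csv"
        write_report([("s", self.EST)], a)
        write_report([("s", self.EST)], b)
        assert pd.read_csv(a, sep="\t").equals(pd.read_csv(b))

    def test_round_trip_to_reported_precision(self, tmp_path):
        out = tmp_path / "report.tsv"
        write_report([("s", self.EST)], out, digits=2)
        row = pd.read_csv(out, sep="\t").iloc[0]
        assert row["f0_hat"] == round(self.EST.f0_hat, 2)
        assert row["ci_lower"] == round(self.EST.ci_lower, 2)

    def test_integer_rounding_matches_published_convention(self, tmp_path):
        out = tmp_path / "report.tsv"
        write_report([("s", self.EST)], out, digits=0)
        row = pd.read_csv(out, sep="\t").iloc[0]
        assert (row["ci_lower"], row["ci_upper"]) == (1511, 1715)

    def test_missing_values_written_as_na(self, tmp_path):
        est = RichnessEstimate("h6", math.nan, 10, 100, degenerate=True)
        out = tmp_path / "report.tsv"
        df = write_report([("s", est)], out)
        assert df.iloc[0]["f0_hat"] == "NA" and df.iloc[0]["flags"] == "degenerate"
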