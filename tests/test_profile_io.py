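"""Tests for coverage readers, window extraction and size classification."""

import numpy as np
import pandas as pd
import pytest

from nucphase.profile_io import (
    ANCHOR_INDEX,
    CoverageParseError,
    PlusOneAnnotation,
    ProfileSet,
    WINDOW_LENGTH,
    classify_gene_size,
    extract_windows,
    read_coverage,
    read_factor_table,
    read_plus_one_annotations,
    write_profile_set_bedgraph,
    _DenseCoverage,
)
from nucphase.synthetic import two_archetype_config, generate_profiles


class TestBedGraphReader:
    def test_constant_interval(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t5\t2.0\n")
        cov = read_coverage(path)
        assert np.array_equal(cov.values("chr1", 0, 5), [2, 2, 2, 2, 2])

    def test_gaps_return_zero(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t2\t4\t1.5\nchr1\t8\t10\t3.0\n")
        cov = read_coverage(path)
        assert np.array_equal(
            cov.values("chr1", 0, 10), [0, 0, 1.5, 1.5, 0, 0, 0, 0, 3, 3]
        )

    def test_query_length_always_matches(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t5\t2.0\n")
        cov = read_coverage(path)
        assert len(cov.values("chr1", 3, 20)) == 17

    def test_unknown_chromosome_raises(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t5\t2.0\n")
        with pytest.raises(KeyError):
            read_coverage(path).values("chrX", 0, 5)

    def test_malformed_line_names_location(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t5\t2.0\nchr1\tfoo\t6\t1.0\n")
        with pytest.raises(CoverageParseError, match=":2"):
            read_coverage(path)


class TestWiggleReader:
    def test_fixed_step(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("fixedStep chrom=chr1 start=3 step=1\n1.0\n2.0\n3.0\n")
        cov = read_coverage(path)
        # wig start is 1-based: value 1.0 lands at 0-based position 2
        assert np.array_equal(cov.values("chr1", 0, 5), [0, 0, 1, 2, 3])

    def test_variable_step_with_span(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("variableStep chrom=chr2 span=2\n1\t5.0\n5\t7.0\n")
        cov = read_coverage(path)
        assert np.array_equal(cov.values("chr2", 0, 6), [5, 5, 0, 0, 7, 7])

    def test_data_before_header_rejected(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("1.0\n")
        with pytest.raises(CoverageParseError):
            read_coverage(path)


class TestExtractWindows:
    @staticmethod
    def _ramp_coverage(length=20000):
        return _DenseCoverage({"chr1": np.arange(length, dtype=float)})

    def test_watson_window_coordinates(self):
        cov = self._ramp_coverage()
        ann = [PlusOneAnnotation("g1", "chr1", 10000, "+", 1500)]
        ps = extract_windows(cov, ann)
        assert np.array_equal(ps.values[0], np.arange(9800, 11000))
        assert ps.values[0][ANCHOR_INDEX] == 10000

    def test_crick_window_coordinates(self):
        cov = self._ramp_coverage()
        ann = [PlusOneAnnotation("g1", "chr1", 10000, "-", 1500)]
        ps = extract_windows(cov, ann)
        assert np.array_equal(ps.values[0], np.arange(9001, 10201)[::-1])
        assert ps.values[0][ANCHOR_INDEX] == 10000

    def test_constant_coverage_identical_for_both_strands(self):
        cov = _DenseCoverage({"chr1": np.full(20000, 3.0)})
        ann = [
            PlusOneAnnotation("w", "chr1", 10000, "+", 1500),
            PlusOneAnnotation("c", "chr1", 10000, "-", 1500),
        ]
        ps = extract_windows(cov, ann)
        assert (ps.values == 3.0).all()

    def test_strand_symmetric_coverage_gives_mirrored_windows(self):
        rng = np.random.default_rng(0)
        half = rng.random(10000)
        arr = np.concatenate([half, half[::-1]])  # palindromic around 10000
        cov = _DenseCoverage({"chr1": arr})
        # mirror of position P on the palindrome is 2*10000 - 1 - P
        watson = extract_windows(cov, [PlusOneAnnotation("w", "chr1", 5000, "+", 1500)])
        crick = extract_windows(cov, [PlusOneAnnotation("c", "chr1", 14999, "-", 1500)])
        assert np.allclose(watson.values[0], crick.values[0])

    def test_out_of_bounds_genes_skipped_with_warning(self, caplog):
        import logging

        cov = self._ramp_coverage(5000)
        ann = [
            PlusOneAnnotation("edge", "chr1", 100, "+", 1500),   # start < 0
            PlusOneAnnotation("far", "chr1", 10**6, "+", 1500),  # beyond end
            PlusOneAnnotation("ok", "chr1", 2000, "+", 1500),
        ]
        with caplog.at_level(logging.WARNING):
            ps = extract_windows(cov, ann)
        assert ps.gene_ids == ["ok"]
        assert any("skipped 2 genes" in r.message for r in caplog.records)

    def test_all_windows_out_of_bounds_raises(self):
        cov = self._ramp_coverage(1000)
        with pytest.raises(ValueError):
            extract_windows(cov, [PlusOneAnnotation("edge", "chr1", 100, "+", 1500)])

    def test_row_order_follows_annotation_order(self):
        cov = self._ramp_coverage()
        ann = [
            PlusOneAnnotation("b", "chr1", 12000, "+", 1500),
            PlusOneAnnotation("a", "chr1", 10000, "+", 1500),
        ]
        ps = extract_windows(cov, ann)
        assert ps.gene_ids == ["b", "a"]
        assert ps.values[1][ANCHOR_INDEX] == 10000

    def test_one_based_flag_shifts_by_one(self):
        cov = self._ramp_coverage()
        zero = extract_windows(cov, [PlusOneAnnotation("g", "chr1", 9999, "+", 1500)])
        one = extract_windows(
            cov, [PlusOneAnnotation("g", "chr1", 10000, "+", 1500)], one_based=True
        )
        assert np.array_equal(zero.values, one.values)


class TestBigWigReader:
    def test_write_and_read_bigwig(self, tmp_path):
        import pyBigWig

        path = str(tmp_path / "a.bw")
        bw = pyBigWig.open(path, "w")
        bw.addHeader([("chr1", 3000)])
        bw.addEntries(["chr1"], [100], ends=[200], values=[2.5])
        bw.close()
        cov = read_coverage(path)
        assert cov.chrom_length("chr1") == 3000
        vals = cov.values("chr1", 95, 105)
        assert np.array_equal(vals, [0] * 5 + [2.5] * 5)
        # uncovered region inside the chromosome returns zeros, not NaN
        assert np.array_equal(cov.values("chr1", 500, 505), np.zeros(5))
        with pytest.raises(KeyError):
            cov.values("chrX", 0, 10)


class TestRoundTrip:
    def test_synthetic_profiles_roundtrip_through_bedgraph(self, tmp_path):
        profiles, _, _ = generate_profiles(two_archetype_config(n_genes=5, seed=3))
        bg = tmp_path / "synth.bedgraph"
        ann_path = tmp_path / "synth.plus_one.tsv"
        write_profile_set_bedgraph(profiles, bg, ann_path)
        cov = read_coverage(bg)
        ann = read_plus_one_annotations(ann_path)
        back = extract_windows(cov, ann)
        assert back.gene_ids == profiles.gene_ids
        assert np.allclose(back.values, profiles.values, atol=1e-9)


class TestSizeClasses:
    @pytest.mark.parametrize(
        "length,size_class,very_large",
        [
            (1000, "small", False),
            (1001, "large", False),
            (2999, "large", False),
            (3000, "large", True),
            (300, "small", False),
        ],
    )
    def test_boundaries(self, length, size_class, very_large):
        df = classify_gene_size([length])
        assert df["size_class"].iloc[0] == size_class
        assert bool(df["very_large"].iloc[0]) is very_large

    def test_profile_set_subset_keeps_alignment(self):
        profiles, _, lengths = generate_profiles(two_archetype_config(n_genes=30, seed=2))
        sub = profiles.subset(lengths > 1000)
        assert sub.n_genes == int((lengths > 1000).sum())
        assert (sub.gene_lengths > 1000).all()


class TestFactorTable:
    def test_toy_table_parses_numeric_and_categorical(self, tmp_path):
        path = tmp_path / "factors.tsv"
        path.write_text(
            "gene_id\tpolii\torientation\ng1\t1.5\ttandem\ng2\t2.5\tdivergent\ng3\t0.5\ttandem\n"
        )
        table = read_factor_table(path)
        assert len(table) == 3
        assert pd.api.types.is_float_dtype(table["polii"])
        assert table["orientation"].tolist() == ["tandem", "divergent", "tandem"]

    def test_missing_value_retained_as_missing(self, tmp_path):
        path = tmp_path / "factors.tsv"
        path.write_text("gene_id\tpolii\ng1\t1.5\ng2\t\ng3\t0.5\n")
        table = read_factor_table(path)
        assert table["polii"].isna().sum() == 1
        assert len(table) == 3

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "factors.tsv"
        path.write_text("gene_id\tpolii\ng1\t1.5\ng1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_factor_table(path)

    def test_stray_nonnumeric_cell_names_gene(self, tmp_path):
        path = tmp_path / "factors.tsv"
        path.write_text("gene_id\tpolii\ng1\t1.5\ng2\toops\ng3\t2.0\n")
        with pytest.raises(ValueError, match="g2"):
            read_factor_table(path)


class TestProfileSetValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ProfileSet(values=-np.ones((2, WINDOW_LENGTH)), gene_ids=["a", "b"])

    def test_short_gene_warns_but_constructs(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            PlusOneAnnotation("tiny", "chr1", 500, "+", 150)
        assert any("300 bp minimum" in r.message for r in caplog.records)
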