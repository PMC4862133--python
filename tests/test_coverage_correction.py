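"""Depth accumulation, reference coverage and the coverage-based correction."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tecensus.annotation_io import TEAnnotation
from tecensus.coverage_correction import (
    CoverageTrack,
    ReferenceCoverage,
    corrected_mass,
    correction_factors,
    depth_track,
    genome_fraction,
    mean_feature_coverage,
    read_depth_tsv,
    write_depth_tsv,
)
from tecensus.datasets import load_buzzatii_te_mass


def write_sam(path, lengths, reads):
    """reads: (scaffold, start, cigar, flag, mapq) tuples."""
    names = sorted(lengths)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": n, "LN": lengths[n]} for n in names]}
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, (scaf, start, cigar, flag, mapq) in enumerate(reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"r{i}"
            seg.flag = flag
            if scaf is not None:
                seg.reference_id = names.index(scaf)
                seg.reference_start = start
                seg.cigarstring = cigar
            seg.mapping_quality = mapq
            out.write(seg)


def te(scaffold, start, end, family="FamA", superfamily="Gypsy", order="LTR"):
    return TEAnnotation(scaffold, start, end, "+", family, superfamily, order, 500)


class TestDepthTrack:
    def test_no_alignments_gives_zero_track(self, tmp_path):
        sam = tmp_path / "empty.sam"
        write_sam(sam, {"s1": 30}, [])
        summary = depth_track(sam, {"s1": 30})
        assert summary.tracks["s1"].depth.sum() == 0

    def test_two_overlapping_reads(self, tmp_path):
        sam = tmp_path / "two.sam"
        write_sam(sam, {"s1": 30}, [("s1", 0, "10M", 0, 60), ("s1", 5, "10M", 0, 60)])
        depth = depth_track(sam, {"s1": 30}).tracks["s1"].depth
        assert list(depth[:15]) == [1] * 5 + [2] * 5 + [1] * 5
        assert depth[15:].sum() == 0

    def test_deletion_and_insertion_cigar_handling(self, tmp_path):
        # 5M3D5M: bases at [0,5) and [8,13); insertions add nothing
        sam = tmp_path / "cigar.sam"
        write_sam(sam, {"s1": 30}, [("s1", 0, "5M3D5M", 0, 60), ("s1", 20, "3M2I3M", 0, 60)])
        depth = depth_track(sam, {"s1": 30}).tracks["s1"].depth
        assert list(np.nonzero(depth)[0]) == list(range(0, 5)) + list(range(8, 13)) + list(range(20, 26))

    def test_unmapped_and_secondary_skipped(self, tmp_path):
        sam = tmp_path / "skip.sam"
        write_sam(
            sam,
            {"s1": 30},
            [
                (None, 0, None, 4, 0),  # unmapped
                ("s1", 0, "10M", 256, 60),  # secondary
                ("s1", 0, "10M", 0, 60),
            ],
        )
        summary = depth_track(sam, {"s1": 30})
        assert summary.n_unmapped == 1 and summary.n_filtered == 1 and summary.n_used == 1
        assert summary.tracks["s1"].depth.max() == 1

    def test_scaffold_absent_from_length_table_errors(self, tmp_path):
        sam = tmp_path / "bad.sam"
        write_sam(sam, {"s1": 30}, [("s1", 0, "10M", 0, 60)])
        with pytest.raises(ValueError, match="length table"):
            depth_track(sam, {"other": 30})

    def test_depth_tsv_round_trip(self, tmp_path):
        tracks = {"s1": CoverageTrack("s1", np.array([0, 3, 3, 0, 1]))}
        path = tmp_path / "depth.tsv"
        write_depth_tsv(tracks, path)
        back = read_depth_tsv(path, {"s1": 5})
        assert (back.tracks["s1"].depth == tracks["s1"].depth).all()


class TestReferenceCoverage:
    def test_uniform_depth_returns_that_depth(self):
        tracks = {"s1": CoverageTrack("s1", np.full(100, 7))}
        ref = mean_feature_coverage(tracks, [("s1", 10, 60)])
        assert ref.value == 7.0 and ref.source == "gene_intervals"

    def test_length_weighted_mean(self):
        tracks = {
            "s1": CoverageTrack("s1", np.full(100, 10)),
            "s2": CoverageTrack("s2", np.full(300, 20)),
        }
        ref = mean_feature_coverage(tracks, [("s1", 0, 100), ("s2", 0, 300)])
        assert ref.value == pytest.approx(17.5)

    def test_zero_coverage_and_zero_length_refused(self):
        tracks = {"s1": CoverageTrack("s1", np.zeros(50))}
        with pytest.raises(ValueError, match="zero coverage"):
            mean_feature_coverage(tracks, [("s1", 0, 50)])
        with pytest.raises(ValueError, match="feature length"):
            mean_feature_coverage(tracks, [])
        with pytest.raises(ValueError):
            ReferenceCoverage(0.0, "external_scalar")


class TestCorrectedMass:
    def test_depth_equal_to_reference_gives_factor_one(self):
        tracks = {"s1": CoverageTrack("s1", np.full(1000, 22))}
        table = corrected_mass(tracks, [te("s1", 100, 300)], ReferenceCoverage(22, "external_scalar"))
        total = table[table.level == "total"].iloc[0]
        assert total.corrected_bp == pytest.approx(total.annotated_bp)
        assert total.factor == pytest.approx(1.0)

    def test_doubled_depth_doubles_the_mass(self):
        depth = np.full(1000, 10)
        depth[100:200] = 20
        tracks = {"s1": CoverageTrack("s1", depth)}
        table = corrected_mass(tracks, [te("s1", 100, 200)], ReferenceCoverage(10, "external_scalar"))
        row = table[table.level == "superfamily"].iloc[0]
        assert row.corrected_bp == pytest.approx(200.0)
        assert row.factor == pytest.approx(2.0)

    def test_scalar_reproduction_path(self):
        # total read mass over TEs divided by the mean gene coverage
        assert 403.3e6 / 22.37 == pytest.approx(18.0e6, rel=0.005)

    def test_order_rows_sum_to_total(self):
        rng = np.random.default_rng(1)
        tracks = {"s1": CoverageTrack("s1", rng.integers(0, 40, size=5000))}
        annotations = [
            te("s1", 0, 500),
            te("s1", 1000, 1700, family="FamB", superfamily="Jockey", order="LINE"),
            te("s1", 3000, 3100, family="FamC", superfamily="hAT", order="TIR"),
        ]
        table = corrected_mass(tracks, annotations, ReferenceCoverage(20, "external_scalar"))
        orders = table[table.level == "order"]
        total = table[table.level == "total"].iloc[0]
        assert orders.corrected_bp.sum() == pytest.approx(total.corrected_bp)
        assert orders.read_mass_bp.sum() == total.read_mass_bp

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(2, 9))
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 30, size=2000)
        annotations = [te("s1", 200, 900)]
        t1 = corrected_mass(
            {"s1": CoverageTrack("s1", base)}, annotations, ReferenceCoverage(10, "external_scalar")
        )
        t2 = corrected_mass(
            {"s1": CoverageTrack("s1", base * k)}, annotations,
            ReferenceCoverage(10 * k, "external_scalar"),
        )
        assert t1.corrected_bp.iloc[0] == pytest.approx(t2.corrected_bp.iloc[0])


class TestFactorsAndFractions:
    def test_published_correction_factors_reproduce(self):
        df = load_buzzatii_te_mass()
        ltr = df[df.order == "LTR"]
        assert correction_factors(
            [ltr.st1_kb.sum()], [ltr.st1_corrected_kb.sum()]
        )[0] == pytest.approx(1.98, abs=0.01)
        r2 = df[df.superfamily == "R2"]
        assert correction_factors(r2.st1_kb, r2.st1_corrected_kb)[0] == pytest.approx(6.24, abs=0.01)
        p = df[df.superfamily == "P"]
        assert correction_factors(p.j19_kb, p.j19_corrected_kb)[0] == pytest.approx(3.3, abs=0.01)

    def test_identical_columns_give_unit_factors(self):
        out = correction_factors([10, 20, 30], [10, 20, 30])
        assert (out == 1.0).all()

    def test_zero_annotated_flagged_as_nan(self):
        out = correction_factors([0.0, 5.0], [3.0, 5.0])
        assert np.isnan(out[0]) and out[1] == 1.0

    def test_genome_fraction_variants(self):
        df = load_buzzatii_te_mass()
        annotated = df.st1_kb.sum()
        corrected = df.st1_corrected_kb.sum()
        assembly = annotated / 0.0843  # assembly size implied by the 8.43 % census
        assert genome_fraction(corrected, assembly, "gaps") == pytest.approx(11.16, abs=0.01)
        j19 = genome_fraction(df.j19_corrected_kb.sum(), 153_440.896, "gaps")
        assert j19 == pytest.approx(7.59, abs=0.01)
        inflate = genome_fraction(corrected, assembly, "inflate", annotated_bp=annotated)
        assert inflate < genome_fraction(corrected, assembly, "gaps")
        assert genome_fraction(0.0, assembly, "gaps") == 0.0
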