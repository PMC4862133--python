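"""Window tiling, lifting, region partitioning and distribution comparison."""

import numpy as np
import pytest

from tecensus.annotation_io import TEAnnotation
from tecensus.window_density import (
    CENTRAL_DISTAL,
    DOT_REGION,
    PROXIMAL,
    ChromosomeMap,
    ScaffoldPlacement,
    WindowDensity,
    ks_compare,
    ks_matrix,
    make_windows,
    partition_regions,
    region_stats,
    te_bp_per_window,
)

from .oracles import ks_statistic, lift_interval, per_base_window_te_bp


def simple_map(length=100_000, chrom="2", orientation="forward"):
    return ChromosomeMap([ScaffoldPlacement("s1", chrom, 0, orientation, length)])


def te(scaffold, start, end, family="FamA"):
    return TEAnnotation(scaffold, start, end, "+", family, "Gypsy", "LTR", 500)


class TestMakeWindows:
    def test_exact_tiling(self):
        wins = make_windows(simple_map(100_000), 50_000)
        assert [(w.start, w.end) for w in wins] == [(0, 50_000), (50_000, 100_000)]

    def test_partial_window_only_in_plot_mode(self):
        full = make_windows(simple_map(120_000), 50_000, include_partial=False)
        assert len(full) == 2 and all(w.is_full for w in full)
        plot = make_windows(simple_map(120_000), 50_000, include_partial=True)
        assert len(plot) == 3
        assert (plot[-1].start, plot[-1].end, plot[-1].is_full) == (100_000, 120_000, False)

    def test_empty_map_and_bad_width(self):
        assert make_windows(ChromosomeMap([]), 50_000) == []
        with pytest.raises(ValueError):
            make_windows(simple_map(), 0)


class TestTeBpPerWindow:
    def test_no_annotations_gives_zero_density(self):
        wins = te_bp_per_window(make_windows(simple_map(), 50_000), [], simple_map())
        assert all(w.te_bp == 0 and w.density == 0 for w in wins)

    def test_boundary_spanning_annotation_split(self):
        cmap = simple_map(100_000)
        wins = te_bp_per_window(
            make_windows(cmap, 50_000), [te("s1", 45_000, 55_000)], cmap
        )
        assert [w.te_bp for w in wins] == [5_000, 5_000]

    def test_full_window_reaches_density_one(self):
        cmap = simple_map(100_000)
        wins = te_bp_per_window(
            make_windows(cmap, 50_000), [te("s1", 0, 50_000)], cmap
        )
        assert wins[0].density == 1.0

    def test_unmapped_scaffold_skipped(self, caplog):
        cmap = simple_map(100_000)
        with caplog.at_level("INFO", logger="tecensus.window_density"):
            wins = te_bp_per_window(
                make_windows(cmap, 50_000), [te("other", 0, 10)], cmap
            )
        assert sum(w.te_bp for w in wins) == 0

    def test_orientation_flip_consistency(self):
        fwd = simple_map(100_000, orientation="forward")
        rev = simple_map(100_000, orientation="reverse")
        a = te("s1", 10_000, 20_000)
        flipped = te("s1", 80_000, 90_000)
        wins_f = te_bp_per_window(make_windows(fwd, 50_000), [a], fwd)
        wins_r = te_bp_per_window(make_windows(rev, 50_000), [flipped], rev)
        assert [w.te_bp for w in wins_f] == [w.te_bp for w in wins_r]

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            lengths = rng.integers(3, 8, size=2) * 50
            cmap = ChromosomeMap(
                [
                    ScaffoldPlacement(
                        f"s{i}", "2", i,
                        "reverse" if rng.random() < 0.5 else "forward",
                        int(lengths[i]),
                    )
                    for i in range(2)
                ]
            )
            annotations = []
            for _ in range(rng.integers(0, 6)):
                i = int(rng.integers(2))
                s = int(rng.integers(0, lengths[i] - 10))
                annotations.append(te(f"s{i}", s, s + int(rng.integers(1, 10))))
            wins = make_windows(cmap, 50, include_partial=True)
            got = [w.te_bp for w in te_bp_per_window(wins, annotations, cmap)]
            offsets = {"s0": 0, "s1": int(lengths[0])}
            orient = {p.scaffold_id: p.orientation for p in cmap.placements}
            lifted = [
                ("2",) + lift_interval(
                    int(lengths[int(a.scaffold_id[1])]),
                    offsets[a.scaffold_id],
                    orient[a.scaffold_id],
                    a.start, a.end,
                )
                for a in annotations
            ]
            expected = per_base_window_te_bp(
                [(w.chromosome, w.start, w.end) for w in wins], lifted
            )
            assert got == expected

    def test_conservation_across_full_and_partial_windows(self):
        cmap = simple_map(123_456)
        rng = np.random.default_rng(3)
        annotations = []
        pos = 0
        for _ in range(40):
            pos += int(rng.integers(100, 2500))
            end = pos + int(rng.integers(50, 500))
            if end >= 123_456:
                break
            annotations.append(te("s1", pos, end))
            pos = end
        wins = te_bp_per_window(
            make_windows(cmap, 50_000, include_partial=True), annotations, cmap
        )
        assert sum(w.te_bp for w in wins) == sum(a.length for a in annotations)


class TestRegions:
    def test_ten_mb_chromosome_has_sixty_proximal_windows(self):
        cmap = simple_map(10_000_000)
        wins = make_windows(cmap, 50_000)
        regions = partition_regions(wins, cmap)
        assert regions.count(PROXIMAL) == 60
        assert regions.count(CENTRAL_DISTAL) == len(wins) - 60

    def test_dot_chromosome_is_one_region(self):
        cmap = simple_map(1_000_000, chrom="6")
        wins = make_windows(cmap, 50_000)
        assert set(partition_regions(wins, cmap)) == {DOT_REGION}

    def test_short_chromosome_entirely_proximal_with_warning(self):
        cmap = simple_map(2_000_000, chrom="4")
        wins = make_windows(cmap, 50_000)
        with pytest.warns(UserWarning, match="shorter"):
            regions = partition_regions(wins, cmap)
        assert set(regions) == {PROXIMAL}


class TestRegionStats:
    def test_constant_density_gives_zero_sd(self):
        wins = [WindowDensity("2", i * 50, (i + 1) * 50, te_bp=25) for i in range(4)]
        out = region_stats(wins, [PROXIMAL] * 4)
        row = out[(out.chromosome == "2") & (out.region == PROXIMAL)].iloc[0]
        assert row.mean_pct == pytest.approx(50.0)
        assert row.sd_pct == pytest.approx(0.0)
        assert row.n_windows == 4

    def test_two_window_mean_and_sample_sd(self):
        wins = [
            WindowDensity("2", 0, 100, te_bp=20),
            WindowDensity("2", 100, 200, te_bp=40),
        ]
        out = region_stats(wins, [CENTRAL_DISTAL] * 2)
        row = out[(out.chromosome == "2") & (out.region == CENTRAL_DISTAL)].iloc[0]
        assert row.mean_pct == pytest.approx(30.0)
        assert row.sd_pct == pytest.approx(14.14, abs=0.01)  # sample sd, n-1

    def test_partial_windows_excluded_from_statistics(self):
        wins = [
            WindowDensity("2", 0, 100, te_bp=10),
            WindowDensity("2", 100, 150, te_bp=50, is_full=False),
        ]
        out = region_stats(wins, [CENTRAL_DISTAL] * 2)
        row = out[(out.chromosome == "2") & (out.region == CENTRAL_DISTAL)].iloc[0]
        assert row.n_windows == 1 and row.mean_pct == pytest.approx(10.0)


class TestKS:
    def test_identical_samples_give_zero_d(self):
        res = ks_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.statistic == 0.0

    def test_fully_separated_samples_give_d_one(self):
        res = ks_compare([0, 0, 0], [1, 1, 1])
        assert res.statistic == 1.0

    def test_small_samples_refused(self):
        with pytest.raises(ValueError):
            ks_compare([1.0], [0.5, 0.6])

    def test_d_matches_ecdf_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.2, size=8)
            res = ks_compare(a, b)
            assert res.statistic == pytest.approx(ks_statistic(list(a), list(b)))

    def test_matrix_has_all_pairs_and_holm_column(self):
        rng = np.random.default_rng(9)
        samples = {k: rng.normal(size=10) for k in "XYZ"}
        df = ks_matrix(samples)
        assert len(df) == 3
        assert (df.p_holm >= df.p - 1e-12).all()
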