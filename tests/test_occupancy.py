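import numpy as np
import pytest

from cfdnafoot import (
    CnvSegment,
    compute_occupancy,
    gc_content,
    normalize_track,
    region_cnv_overlap,
    tile_genome,
)
from cfdnafoot.occupancy import (
    genome_mean_coverage,
    per_base_coverage,
    read_bedgraph,
    read_chrom_sizes,
    write_bedgraph,
)

from conftest import brute_force_bin_coverage, make_fragments


class TestTiling:
    def test_partial_last_bin(self):
        bins = tile_genome({"chr1": 25_000}, 10_000)
        assert bins.n_bins == 3
        assert bins.bin_end[-1] - bins.bin_start[-1] == 5_000

    def test_exact_fit(self):
        assert tile_genome({"chr1": 10_000}, 10_000).n_bins == 1

    def test_two_chromosome_count(self):
        bins = tile_genome({"chr1": 10_000_000, "chr2": 10_000_000}, 10_000)
        assert bins.n_bins == 2_000

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 0}, 10_000)

    def test_sliding_step(self):
        bins = tile_genome({"chr1": 30_000}, 10_000, step=5_000)
        assert bins.n_bins == 6
        assert bins.bin_start[1] == 5_000 and bins.bin_end[1] == 15_000


class TestOccupancy:
    def test_single_contained_fragment(self):
        bins = tile_genome({"chr1": 100_000}, 10_000)
        fs = make_fragments([("chr1", 1000, 1150)])
        track = compute_occupancy(fs, bins)
        assert track.values[0] == pytest.approx(150 / 10_000)
        assert np.all(track.values[1:] == 0)

    def test_boundary_straddling_fragment_splits_proportionally(self):
        bins = tile_genome({"chr1": 100_000}, 10_000)
        fs = make_fragments([("chr1", 9_900, 10_050)])
        track = compute_occupancy(fs, bins)
        assert track.values[0] == pytest.approx(100 / 10_000)
        assert track.values[1] == pytest.approx(50 / 10_000)
        assert np.all(track.values[2:] == 0)

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(11)
        chrom_sizes = {"chr1": 100_000}
        records = []
        for _ in range(200):
            start = int(rng.integers(0, 99_500))
            records.append(("chr1", start, start + int(rng.integers(50, 400))))
        bins = tile_genome(chrom_sizes, 10_000)
        got = compute_occupancy(make_fragments(records), bins).values
        expected = brute_force_bin_coverage(records, chrom_sizes, 10_000)
        assert np.allclose(got, expected, atol=1e-9, rtol=0)

    def test_fragment_longer_than_bin(self):
        bins = tile_genome({"chr1": 300}, 100)
        fs = make_fragments([("chr1", 50, 260)])
        track = compute_occupancy(fs, bins)
        assert track.values.tolist() == [0.5, 1.0, 0.6]

    def test_additive_over_disjoint_sets(self):
        bins = tile_genome({"chr1": 50_000}, 10_000)
        a = make_fragments([("chr1", 100, 250), ("chr1", 30_000, 30_170)])
        b = make_fragments([("chr1", 12_000, 12_150)])
        both = make_fragments(
            list(zip(a.chroms, a.starts, a.ends)) + list(zip(b.chroms, b.starts, b.ends))
        )
        assert np.allclose(
            compute_occupancy(both, bins).values,
            compute_occupancy(a, bins).values + compute_occupancy(b, bins).values,
        )

    def test_coverage_conservation(self):
        rng = np.random.default_rng(3)
        records = [
            ("chr1", int(s), int(s) + int(L))
            for s, L in zip(rng.integers(0, 90_000, 300), rng.integers(100, 200, 300))
        ]
        bins = tile_genome({"chr1": 100_000}, 10_000)
        track = compute_occupancy(make_fragments(records), bins)
        total_bases = sum(e - s for _, s, e in records)
        assert np.sum(track.values * bins.widths) == pytest.approx(total_bases)

    def test_shift_by_whole_bin_shifts_values(self):
        bins = tile_genome({"chr1": 100_000}, 10_000)
        records = [("chr1", 2_000, 2_160), ("chr1", 4_500, 4_650)]
        shifted = [("chr1", s + 10_000, e + 10_000) for _, s, e in records]
        v0 = compute_occupancy(make_fragments(records), bins).values
        v1 = compute_occupancy(make_fragments(shifted), bins).values
        assert np.allclose(v0[:-1], v1[1:])

    def test_sliding_windows_match_tiling_average(self):
        # with step == bin_size the generic per-bp path equals the fast path
        records = [("chr1", 120, 290), ("chr1", 9_950, 10_110)]
        fs = make_fragments(records)
        tiled = compute_occupancy(fs, tile_genome({"chr1": 30_000}, 10_000))
        slid = compute_occupancy(fs, tile_genome({"chr1": 30_000}, 10_000, step=5_000))
        assert np.allclose(tiled.values, slid.values[::2])


class TestNormalization:
    def test_constant_track_becomes_ones(self):
        bins = tile_genome({"chr1": 40_000}, 10_000)
        fs = make_fragments([("chr1", s, s + 200) for s in range(0, 40_000, 200)])
        track = normalize_track(compute_occupancy(fs, bins))
        assert np.allclose(track.values, 1.0)
        assert track.normalized

    def test_weighted_mean_is_one(self, default_tracks):
        bins, tracks = default_tracks
        w = bins.widths.astype(float)
        for track in tracks.values():
            assert np.sum(track.values * w) / w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_depth_doubling_invariance(self):
        bins = tile_genome({"chr1": 50_000}, 10_000)
        records = [("chr1", 100, 260), ("chr1", 20_000, 20_150), ("chr1", 41_000, 41_180)]
        single = normalize_track(compute_occupancy(make_fragments(records), bins))
        double = normalize_track(compute_occupancy(make_fragments(records * 2), bins))
        assert np.allclose(single.values, double.values)
        assert double.depth_constant == pytest.approx(2 * single.depth_constant)

    def test_all_zero_track_rejected(self):
        bins = tile_genome({"chr1": 10_000}, 10_000)
        with pytest.raises(ValueError, match="no coverage"):
            normalize_track(compute_occupancy(make_fragments([]), bins))


class TestGcContent:
    def _write_fasta(self, path, seqs):
        with open(path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        return path

    def test_all_g(self, tmp_path):
        fa = self._write_fasta(tmp_path / "g.fa", {"chr1": "G" * 100})
        fracs, mean = gc_content([("chr1", 0, 100)], fa)
        assert fracs[0] == 1.0 and mean == 1.0

    def test_acgt_repeats(self, tmp_path):
        fa = self._write_fasta(tmp_path / "r.fa", {"chr1": "ACGT" * 25})
        fracs, _ = gc_content([("chr1", 0, 100)], fa)
        assert fracs[0] == pytest.approx(0.5)

    def test_known_composition_and_n_exclusion(self, tmp_path):
        fa = self._write_fasta(tmp_path / "k.fa", {"chr1": "GGGCCAATTNN" + "A" * 9})
        fracs, mean = gc_content([("chr1", 0, 11), ("chr1", 11, 20)], fa)
        assert fracs[0] == pytest.approx(5 / 9)  # N excluded from denominator
        assert fracs[1] == 0.0
        assert mean == pytest.approx((5 / 9 * 11 + 0.0 * 9) / 20)

    def test_out_of_bounds_region(self, tmp_path):
        fa = self._write_fasta(tmp_path / "s.fa", {"chr1": "ACGT"})
        with pytest.raises(ValueError, match="bounds"):
            gc_content([("chr1", 0, 10)], fa)


class TestCnvOverlap:
    SEGMENTS = [
        CnvSegment("chr1", 0, 1000, 2.0),
        CnvSegment("chr1", 5000, 6000, 0.5),
        CnvSegment("chr2", 0, 500, 1.5),
    ]

    def test_disjoint_regions(self):
        assert region_cnv_overlap([("chr1", 2000, 3000)], self.SEGMENTS) == 0.0

    def test_one_in_four(self):
        regions = [
            ("chr1", 500, 1500),   # overlaps amplified
            ("chr1", 5100, 5200),  # overlaps, but log2 too low
            ("chr1", 8000, 9000),
            ("chr3", 0, 100),
        ]
        assert region_cnv_overlap(regions, self.SEGMENTS) == pytest.approx(0.25)

    def test_threshold_is_strict(self):
        seg = [CnvSegment("chr1", 0, 1000, 1.0)]
        assert region_cnv_overlap([("chr1", 0, 100)], seg, log2_min=1.0) == 0.0

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            region_cnv_overlap([], self.SEGMENTS)

    def test_empty_segments_give_zero(self):
        assert region_cnv_overlap([("chr1", 0, 100)], []) == 0.0


def test_bedgraph_roundtrip(tmp_path, default_tracks):
    bins, tracks = default_tracks
    track = next(iter(tracks.values()))
    p = tmp_path / "t.bedgraph"
    write_bedgraph(track, p)
    back = read_bedgraph(p, bins, track.sample_id, track.condition)
    assert np.allclose(back.values, track.values, rtol=1e-5)


def test_read_chrom_sizes(tmp_path):
    p = tmp_path / "sizes.tsv"
    p.write_text("chr1\t1000\nchr2\t500\n")
    assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 500}
    p.write_text("chr1\t-5\n")
    with pytest.raises(ValueError):
        read_chrom_sizes(p)


def test_per_bp_helpers_agree(default_cohort):
    cfg, frags, _, _ = default_cohort
    fs = frags["PRE00"]
    cov = per_base_coverage(fs, cfg.chrom_sizes)
    total = sum(arr.sum() for arr in cov.values())
    genome = sum(cfg.chrom_sizes.values())
    assert total / genome == pytest.approx(genome_mean_coverage(fs, cfg.chrom_sizes))
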