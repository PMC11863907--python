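import math

import numpy as np
import pytest

from cfdnafoot import (
    aggregate_profile,
    compare_groups,
    correlate_activity_expression,
    correlate_with_tumor_fraction,
    load_sites,
    select_top_fraction,
    tfbs_center_depth,
)
from cfdnafoot.tfbs import BindingSiteSet, write_sites_bed

from conftest import make_fragments


def make_sites(centers, tf="TF", chrom="chr1", strands=None, strengths=None, width=20):
    n = len(centers)
    centers = np.asarray(centers, dtype=np.int64)
    return BindingSiteSet(
        tf,
        np.array([chrom] * n, dtype=object),
        centers - width // 2,
        centers + width - width // 2,
        np.array(strands if strands is not None else ["."] * n, dtype=object),
        np.array(strengths if strengths is not None else [np.nan] * n, dtype=float),
    ).sort()


def tiling_fragments(chrom_size, frag_len=200, sample_id="s", condition="pre"):
    """Non-overlapping fragments covering the chromosome end to end:
    per-bp coverage is exactly 1 everywhere."""
    assert chrom_size % frag_len == 0
    return make_fragments(
        [("chr1", s, s + frag_len) for s in range(0, chrom_size, frag_len)],
        sample_id,
        condition,
    )


class TestLoadSites:
    def test_full_bed_line(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t120\tsite1\t9.5\t+\n")
        sites = load_sites(p, "REST")
        assert sites.centers[0] == 110
        assert sites.strengths[0] == pytest.approx(9.5)
        assert sites.strands[0] == "+"

    def test_minimal_bed_line(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t121\n")
        sites = load_sites(p, "REST")
        assert sites.centers[0] == 110  # floor((100+121)/2)
        assert sites.strands[0] == "." and math.isnan(sites.strengths[0])

    def test_empty_file(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("")
        assert load_sites(p, "REST").n_sites == 0

    def test_malformed_line_number(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t120\nchr1\tx\t140\n")
        with pytest.raises(ValueError, match=":2"):
            load_sites(p, "REST")

    def test_roundtrip(self, tmp_path):
        sites = make_sites([500, 1500], strands=["+", "-"], strengths=[1.5, 2.5])
        p = tmp_path / "out.bed"
        write_sites_bed(sites, p)
        back = load_sites(p, "TF")
        assert np.array_equal(back.starts, sites.starts)
        assert np.array_equal(back.ends, sites.ends)
        assert back.strands.tolist() == sites.strands.tolist()
        assert np.allclose(back.strengths, sites.strengths)


class TestTopFraction:
    def test_half_of_four(self):
        sites = make_sites([100, 200, 300, 400], strengths=[1, 2, 3, 4])
        top = select_top_fraction(sites, 0.5)
        assert sorted(top.centers.tolist()) == [300, 400]

    def test_ceiling_rule(self):
        sites = make_sites([100, 200, 300, 400, 500], strengths=[1, 2, 3, 4, 5])
        assert select_top_fraction(sites, 0.5).n_sites == 3

    def test_ties_deterministic(self):
        centers = list(range(1000, 11_000, 100))
        sites = make_sites(centers, strengths=[1.0] * 100)
        a = select_top_fraction(sites, 0.5)
        b = select_top_fraction(sites, 0.5)
        assert a.n_sites == 50
        assert np.array_equal(a.starts, b.starts)
        # ties broken by genomic position ascending
        assert sorted(a.centers.tolist()) == centers[:50]

    def test_idempotent_and_nested(self):
        rng = np.random.default_rng(4)
        sites = make_sites(
            list(range(1000, 1000 + 100 * 40, 100)), strengths=rng.random(40)
        )
        top50 = select_top_fraction(sites, 0.5)
        assert np.array_equal(select_top_fraction(top50, 1.0).starts, top50.starts)
        top25 = select_top_fraction(sites, 0.25)
        assert set(top25.centers.tolist()) <= set(top50.centers.tolist())

    def test_missing_strengths_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            select_top_fraction(make_sites([100, 200]), 0.5)


class TestCenterDepth:
    CHROM = {"chr1": 100_000}

    def test_uniform_coverage_scores_one(self):
        fs = tiling_fragments(100_000)
        for hw in (0, 15, 50):
            sites = make_sites([10_000, 50_000, 77_777])
            score = tfbs_center_depth(fs, sites, self.CHROM, half_width=hw)
            assert score.score == pytest.approx(1.0, abs=1e-12)

    def test_zeroed_centers_half_width_zero(self):
        # uniform coverage except a 1-bp hole at each site center
        frags = []
        holes = {10_000, 50_000}
        for s in range(0, 100_000, 200):
            cut = [h for h in holes if s <= h < s + 200]
            if cut:
                h = cut[0]
                if h > s:
                    frags.append(("chr1", s, h))
                if h + 1 < s + 200:
                    frags.append(("chr1", h + 1, s + 200))
            else:
                frags.append(("chr1", s, s + 200))
        fs = make_fragments(frags)
        sites = make_sites(sorted(holes))
        score = tfbs_center_depth(fs, sites, self.CHROM, half_width=0)
        assert score.score == 0.0

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(21)
        records = []
        for _ in range(300):
            start = int(rng.integers(0, 99_500))
            records.append(("chr1", start, start + int(rng.integers(120, 181))))
        fs = make_fragments(records)
        centers = rng.integers(1000, 99_000, size=25).tolist()
        sites = make_sites(centers)
        hw = 15
        got = tfbs_center_depth(fs, sites, self.CHROM, half_width=hw).score
        depth = np.zeros(100_000)
        for _, s, e in records:
            depth[s:e] += 1
        mean_cov = depth.mean()
        expected = np.mean(
            [depth[c - hw : c + hw + 1].mean() / mean_cov for c in centers]
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_sites_rejected(self):
        fs = tiling_fragments(100_000)
        with pytest.raises(ValueError):
            tfbs_center_depth(fs, make_sites([]), self.CHROM)


class TestAggregateProfile:
    CHROM = {"chr1": 100_000}

    def test_flat_under_uniform_coverage(self):
        fs = tiling_fragments(100_000)
        profile = aggregate_profile([fs], make_sites([30_000, 60_000]), self.CHROM,
                                    flank=500, step=10)
        assert np.allclose(profile.curves["pre"], 1.0, atol=1e-12)
        assert profile.offsets[0] == -500 and profile.offsets[-1] == 500
        assert np.array_equal(profile.offsets, -profile.offsets[::-1])

    def test_single_fragment_indicator(self):
        c = 50_000
        fs = make_fragments([("chr1", c - 75, c + 75)], condition="post")
        profile = aggregate_profile([fs], make_sites([c]), self.CHROM,
                                    flank=100, step=1)
        scale = 100_000 / 150  # 1 / genome mean coverage
        offsets = profile.offsets
        curve = profile.curves["post"]
        inside = (offsets >= -75) & (offsets < 75)
        assert np.allclose(curve[inside], scale)
        assert np.allclose(curve[~inside], 0.0)

    def test_minus_strand_sites_flip_orientation(self):
        c = 50_000
        fs = make_fragments([("chr1", c, c + 150)])  # covers only the right flank
        plus = aggregate_profile([fs], make_sites([c], strands=["+"]), self.CHROM,
                                 flank=200, step=1)
        minus = aggregate_profile([fs], make_sites([c], strands=["-"]), self.CHROM,
                                  flank=200, step=1)
        assert np.allclose(plus.curves["unknown"], minus.curves["unknown"][::-1])

    def test_strand_randomization_matches_all_plus(self, default_cohort):
        cfg, frags, _, sites = default_cohort
        from cfdnafoot.simulate import binding_site_sets

        bss = binding_site_sets(sites)["TFB"]
        fs = frags["PRE00"]
        randomized = aggregate_profile([fs], bss, cfg.chrom_sizes, flank=200, step=20)
        all_plus = BindingSiteSet(bss.tf_name, bss.chroms, bss.starts, bss.ends,
                                  np.array(["+"] * bss.n_sites, dtype=object),
                                  bss.strengths)
        plus = aggregate_profile([fs], all_plus, cfg.chrom_sizes, flank=200, step=20)
        # same sites, same fragments: only the orientation of each site's
        # window differs, so the curves agree within sampling error
        diff = np.abs(randomized.curves["pre"] - plus.curves["pre"])
        assert diff.mean() < 0.15

    def test_edge_sites_dropped(self):
        fs = tiling_fragments(100_000)
        profile = aggregate_profile([fs], make_sites([100, 50_000]), self.CHROM,
                                    flank=2000, step=10)
        assert profile.n_sites == 1
        with pytest.raises(ValueError, match="usable"):
            aggregate_profile([fs], make_sites([100]), self.CHROM, flank=2000)


class TestStatistics:
    def test_spearman_perfect_antirank(self):
        res = correlate_activity_expression(
            {"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1}
        )
        assert res.coefficient == pytest.approx(-1.0)
        assert res.n == 3

    def test_pairing_is_by_sample_id(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 9.9}
        expr = {"c": 1.0, "b": 2.0, "a": 3.0}  # different order, one missing
        res = correlate_activity_expression(scores, expr)
        assert res.coefficient == pytest.approx(-1.0)
        assert res.n == 3

    def test_pearson_three_point_closed_form(self):
        res = correlate_activity_expression(
            {"a": 0.0, "b": 1.0, "c": 2.0}, {"a": 5.0, "b": 3.0, "c": 1.0},
            method="pearson",
        )
        assert res.coefficient == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        res = correlate_activity_expression(
            {"a": 1, "b": 1, "c": 1}, {"a": 3, "b": 2, "c": 1}
        )
        assert math.isnan(res.coefficient)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            correlate_with_tumor_fraction({"a": 1, "b": 2}, {"a": 0.1, "b": 0.2})

    def test_tumor_fraction_perfect_anticorrelation(self):
        scores = {f"s{i}": 1.0 - 0.1 * i for i in range(5)}
        fractions = {f"s{i}": 0.1 * i for i in range(5)}
        res = correlate_with_tumor_fraction(scores, fractions)
        assert res.coefficient == pytest.approx(-1.0)
        assert res.p_value < 1e-6

    def test_mannwhitney_exact_small_groups(self):
        scores = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}
        groups = {k: ("low" if k in "abc" else "high") for k in scores}
        res = compare_groups(scores, groups)
        # U for the "high" (first label alphabetically) group vs "low":
        # all of (4,5,6) beat all of (1,2,3) -> U = 9; exact two-sided p = 0.1
        assert res.p_value == pytest.approx(0.1)
        assert res.medians == {"high": 5.0, "low": 2.0}

    def test_identical_groups_no_evidence(self):
        scores = {"a": 1, "b": 2, "c": 3, "d": 1, "e": 2, "f": 3}
        groups = {k: ("x" if k in "abc" else "y") for k in scores}
        assert compare_groups(scores, groups).p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        scores = {"a": 1, "b": 5, "c": 2, "d": 8, "e": 3, "f": 9}
        g1 = {k: ("x" if k in "abc" else "y") for k in scores}
        g2 = {k: ("y" if k in "abc" else "x") for k in scores}
        r1, r2 = compare_groups(scores, g1), compare_groups(scores, g2)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.medians["x"] == r2.medians["y"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": 1.0}, {"a": "x"})
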