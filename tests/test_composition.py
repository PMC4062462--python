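"""Positional profiles, window compositions, ratios, U/A ratio."""

import numpy as np
import pytest

from polyacomp.composition import (
    add_profiles,
    per_position_ratio,
    positional_profile,
    region_genome_ratio,
    round_half_up,
    standard_windows,
    ua_ratio,
    window_composition,
)
from polyacomp.errors import DegenerateInputError
from polyacomp.sequence_io import BaseComposition, GenomeStore, genome_composition
from polyacomp.site_mapper import PolyASite


def make_site(utr, site_base, cor, junction=0, chrom="c", strand="+"):
    downstream = site_base + cor
    run = len(downstream) - len(downstream.lstrip("A"))
    return PolyASite(
        chrom=chrom, strand=strand, junction=junction, anchor=utr,
        utr_window=utr, site_base=site_base, cor_window=cor,
        downstream_A_run=run, six_base_A_count=downstream[:6].count("A"),
        ip_flag=run >= 12,
    )


def random_site(rng, junction=0):
    draw = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return make_site(draw(100), draw(1), draw(100), junction=junction)


class TestPositionalProfile:
    def test_single_site_is_one_hot(self):
        s = make_site("A" * 100, "G", "C" * 100)
        prof = positional_profile([s])
        assert prof.n_sites == 1
        assert (prof.counts.sum(axis=1) == 1).all()
        assert prof.row(-1)[0] == 1           # A at position -1
        assert prof.row(0)[2] == 1            # G at the site base
        assert prof.row(42)[1] == 1           # C inside the COR

    def test_identical_sites_double_counts(self):
        s = make_site("A" * 100, "G", "C" * 100)
        p1 = positional_profile([s])
        p2 = positional_profile([s, s])
        assert (p2.counts == 2 * p1.counts).all()

    def test_matches_per_site_loop_oracle(self):
        rng = np.random.default_rng(5)
        sites = [random_site(rng, junction=i) for i in range(50)]
        prof = positional_profile(sites)
        for pos in (-100, -37, 0, 1, 55, 100):
            expected = [0, 0, 0, 0]
            for s in sites:
                seq = s.utr_window + s.site_base + s.cor_window
                expected["ACGT".index(seq[pos + 100])] += 1
            assert list(prof.row(pos)) == expected

    def test_empty_site_list_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            positional_profile([])

    def test_row_sums_equal_n_sites(self):
        rng = np.random.default_rng(6)
        sites = [random_site(rng) for _ in range(17)]
        prof = positional_profile(sites)
        assert (prof.counts.sum(axis=1) == 17).all()

    def test_additivity_of_profiles(self):
        rng = np.random.default_rng(7)
        a = [random_site(rng) for _ in range(9)]
        b = [random_site(rng) for _ in range(4)]
        combined = positional_profile(a + b)
        summed = add_profiles(positional_profile(a), positional_profile(b))
        assert (combined.counts == summed.counts).all()
        assert combined.n_sites == summed.n_sites


class TestWindowComposition:
    def test_all_A_cor_gives_100_percent_A(self):
        s = make_site("C" * 100, "G", "A" * 100)
        prof = positional_profile([s])
        comp = window_composition(prof, standard_windows()["COR100"])
        assert comp.pct_A == 100.0
        assert comp.alphabet_tag == "RNA"

    def test_percentages_conserve_to_100(self):
        rng = np.random.default_rng(8)
        prof = positional_profile([random_site(rng) for _ in range(20)])
        for spec in standard_windows().values():
            comp = window_composition(prof, spec)
            assert comp.pct_A + comp.pct_C + comp.pct_G + comp.pct_TU == (
                pytest.approx(100.0))

    def test_uniform_sites_within_3_sigma_of_25(self):
        rng = np.random.default_rng(9)
        n = 200
        prof = positional_profile([random_site(rng) for _ in range(n)])
        spec = standard_windows()["COR100"]
        comp = window_composition(prof, spec)
        se = 100 * np.sqrt(0.25 * 0.75 / (n * len(spec)))
        for pct in (comp.pct_A, comp.pct_C, comp.pct_G, comp.pct_TU):
            assert abs(pct - 25.0) < 3 * se

    def test_sixbase_window_equals_six_base_a_counts(self):
        rng = np.random.default_rng(10)
        sites = [random_site(rng) for _ in range(30)]
        prof = positional_profile(sites)
        comp = window_composition(prof, standard_windows()["SIXBASE"])
        total_a = sum(s.six_base_A_count for s in sites)
        assert comp.pct_A == pytest.approx(100 * total_a / (30 * 6))

    def test_cor_includes_site_shifts_window(self):
        s = make_site("C" * 100, "A", "G" * 100)
        prof = positional_profile([s])
        excl = window_composition(prof, standard_windows()["COR100"])
        incl = window_composition(
            prof, standard_windows(cor_includes_site=True)["COR100"])
        assert excl.pct_A == 0.0
        assert incl.pct_A == 1.0  # 1 of 100 positions


class TestRatios:
    def test_ratio_arithmetic(self):
        region = BaseComposition(25, 15, 10, 50, 100, "RNA")
        genome = BaseComposition(25, 25, 25, 25, 100, "DNA")
        rt = region_genome_ratio(region, genome)
        assert rt.ratio_TU == pytest.approx(2.0)
        assert rt.ratio_A == pytest.approx(1.0)

    def test_identity_when_region_equals_background(self):
        comp = BaseComposition(30, 20, 20, 30, 100, "DNA")
        rt = region_genome_ratio(comp, comp)
        assert all(r == pytest.approx(1.0) for r in rt.as_dict().values())

    def test_zero_background_flagged_undefined(self):
        region = BaseComposition(50, 25, 0, 25, 4, "RNA")
        genome = BaseComposition(50, 25, 0, 25, 4, "DNA")
        assert region_genome_ratio(region, genome).ratio_G is None

    def test_per_species_ratios_not_ratio_of_means(self):
        """Group summaries must average per-species ratios, not compute
        the ratio of group-mean compositions (the two differ)."""
        r1 = BaseComposition(20, 20, 20, 40, 100, "RNA")
        g1 = BaseComposition(30, 30, 20, 20, 100, "DNA")
        r2 = BaseComposition(30, 25, 15, 30, 100, "RNA")
        g2 = BaseComposition(25, 25, 20, 30, 100, "DNA")
        per_species = [region_genome_ratio(r1, g1).ratio_TU,
                       region_genome_ratio(r2, g2).ratio_TU]
        mean_of_ratios = np.mean(per_species)
        ratio_of_means = np.mean([r1.pct_TU, r2.pct_TU]) / np.mean(
            [g1.pct_TU, g2.pct_TU])
        assert mean_of_ratios != pytest.approx(ratio_of_means)
        assert mean_of_ratios == pytest.approx((40 / 20 + 30 / 30) / 2)

    def test_per_position_track_values(self):
        s1 = make_site("C" * 100, "G", "T" + "G" * 99)
        s2 = make_site("C" * 100, "G", "T" + "C" * 99)
        prof = positional_profile([s1, s2])
        genome = BaseComposition(25, 25, 25, 25, 100, "DNA")
        positions, track = per_position_ratio(prof, genome, "U")
        lookup = dict(zip(positions, track))
        assert lookup[1] == pytest.approx(4.0)   # all sites U at +1, genome 25%
        assert lookup[0] == pytest.approx(0.0)

    def test_track_consistent_with_single_position_windows(self):
        rng = np.random.default_rng(12)
        sites = [random_site(rng) for _ in range(25)]
        prof = positional_profile(sites)
        genome = BaseComposition(30, 20, 20, 30, 1000, "DNA")
        positions, track = per_position_ratio(prof, genome, "U")
        from polyacomp.composition import WindowSpec

        for pos in (-60, -1, 0, 1, 99):
            comp = window_composition(prof, WindowSpec("one", pos, pos))
            expected = comp.pct_TU / genome.pct_TU
            assert track[list(positions).index(pos)] == pytest.approx(expected)


class TestUARatio:
    @pytest.mark.parametrize(
        "a,u,expected",
        [
            (25.47, 40.79, 1.60),
            (36.57, 35.26, 0.96),
            (30.0, 30.0, 1.00),
        ],
    )
    def test_reporting_rounding(self, a, u, expected):
        rest = 100 - a - u
        comp = BaseComposition(a, rest / 2, rest / 2, u, 100, "RNA")
        assert round_half_up(ua_ratio(comp), 2) == expected

    def test_zero_A_undefined(self):
        comp = BaseComposition(0, 30, 30, 40, 10, "RNA")
        with pytest.raises(ZeroDivisionError):
            ua_ratio(comp)

    def test_round_half_up_at_boundary(self):
        assert round_half_up(1.605, 2) == 1.61
        assert round_half_up(0.125, 2) == 0.13
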