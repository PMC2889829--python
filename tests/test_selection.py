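"""Unit and property tests for the dN/dS selection screen."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from carotevol.alignment import CodonAlignment
from carotevol.codons import sense_codons
from carotevol.selection import (
    FILTERED,
    NC,
    OK,
    InsufficientDataError,
    PairRates,
    PairwiseRateTable,
    SelectionError,
    bin_histogram,
    build_rate_table,
    codon_site_counts,
    detect_elevated,
    filter_pairs,
    histogram_percentages,
    is_bimodal,
    jc_correct,
    mann_whitney,
    pairwise_ng86,
)

from conftest import mutate_sequence, random_codon_sequence
from oracles import ng86_brute, pathway_counts_brute, site_fractions_brute


class TestSiteCounts:
    def test_phenylalanine_has_one_third_synonymous_site(self):
        # among TTT's nine single changes only position-3 T->C is synonymous
        s, n = codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_methionine_has_no_synonymous_site(self):
        assert codon_site_counts("ATG")[0] == 0.0

    def test_stop_codon_rejected(self):
        with pytest.raises(SelectionError):
            codon_site_counts("TAA")

    def test_sites_sum_to_three_and_match_enumeration(self):
        for codon in sense_codons():
            s, n = codon_site_counts(codon)
            assert s + n == pytest.approx(3.0)
            assert s == pytest.approx(site_fractions_brute(codon), abs=1e-12)


class TestPairwiseNG86:
    def test_identical_sequences_have_no_differences(self, rng):
        seq = random_codon_sequence(rng, 30)
        counts = pairwise_ng86(seq, seq)
        assert counts.Sd == 0 and counts.Nd == 0
        assert counts.usable_codons == 30

    def test_lysine_synonymous_single_difference(self):
        counts = pairwise_ng86("AAA", "AAG")
        assert counts.Sd == pytest.approx(1.0)
        assert counts.Nd == pytest.approx(0.0)

    def test_sites_scale_with_usable_codons(self, rng):
        a = random_codon_sequence(rng, 40, allow_gaps=True)
        b = mutate_sequence(rng, random_codon_sequence(rng, 40, allow_gaps=True), 20)
        counts = pairwise_ng86(a, b)
        assert counts.S + counts.N == pytest.approx(3 * counts.usable_codons)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = random_codon_sequence(rng, 25)
            b = mutate_sequence(rng, a, 15)
            x, y = pairwise_ng86(a, b), pairwise_ng86(b, a)
            assert (x.S, x.N, x.Sd, x.Nd) == pytest.approx((y.S, y.N, y.Sd, y.Nd))

    def test_matches_exhaustive_pathway_oracle(self, rng):
        """200 random pairs against the independent brute-force counter."""
        for _ in range(200):
            n = int(rng.integers(1, 40))
            a = random_codon_sequence(rng, n, allow_gaps=True)
            b = mutate_sequence(rng, a, int(rng.integers(0, 3 * n)))
            counts = pairwise_ng86(a, b)
            S, N, Sd, Nd, usable = ng86_brute(a, b)
            assert counts.S == pytest.approx(S, abs=1e-9)
            assert counts.N == pytest.approx(N, abs=1e-9)
            assert counts.Sd == pytest.approx(Sd, abs=1e-9)
            assert counts.Nd == pytest.approx(Nd, abs=1e-9)
            assert counts.usable_codons == usable

    def test_stop_only_pathway_pair_skipped(self):
        # TGT (Cys) <-> TAC (Tyr): hand-checked against pathway enumeration
        expected = pathway_counts_brute("TGT", "TAC")
        counts = pairwise_ng86("TGT", "TAC")
        if expected is None:
            assert counts.usable_codons == 0
        else:
            assert counts.Sd == pytest.approx(expected[0])


class TestJukesCantor:
    def test_zero_and_reference_value(self):
        assert jc_correct(0.0) == 0.0
        assert jc_correct(0.05) == pytest.approx(0.05174, abs=5e-6)

    def test_domain_boundary_is_nc(self):
        assert jc_correct(0.75) is None
        assert jc_correct(0.9) is None
        with pytest.raises(SelectionError):
            jc_correct(-0.1)

    @given(st.floats(min_value=0.0, max_value=0.7495))
    @settings(derandomize=True, max_examples=200)
    def test_correction_dominates_p_and_increases(self, p):
        d = jc_correct(p)
        assert d >= p
        assert jc_correct(p + 0.0004) > d


class TestRateTable:
    def test_identical_pair_is_nc_zero_ds(self, rng):
        seq = random_codon_sequence(rng, 20)
        table = build_rate_table(CodonAlignment.from_pairs([("a", seq), ("b", seq)]))
        (pair,) = table.pairs
        assert pair.status == NC
        assert pair.dn == 0.0 and pair.ds == 0.0

    def test_row_count_is_all_unordered_pairs(self, rng):
        pairs = [(f"s{i}", random_codon_sequence(rng, 10)) for i in range(6)]
        table = build_rate_table(CodonAlignment.from_pairs(pairs))
        assert len(table) == 15

    def test_filter_bounds_are_strict(self):
        rows = [
            ("a", "b", 0.2, 1.6, OK),    # ds saturation
            ("a", "c", 0.005, 0.5, OK),  # dn too small
            ("a", "d", 0.01, 0.5, OK),   # dn exactly at bound -> filtered
            ("a", "e", 0.02, 1.5, OK),   # ds exactly at bound -> filtered
            ("a", "f", 0.02, 1.4, OK),
            ("a", "g", None, None, NC),
        ]
        table = PairwiseRateTable(
            pairs=[
                PairRates(x, y, dn, ds, dn / ds if dn and ds else None, status)
                for x, y, dn, ds, status in rows
            ],
            ids=("a", "b", "c", "d", "e", "f", "g"),
        )
        filtered = filter_pairs(table)
        statuses = [p.status for p in filtered.pairs]
        assert statuses == [FILTERED, FILTERED, FILTERED, FILTERED, OK, NC]


class TestHistogram:
    def test_rounding_half_away_from_zero(self):
        assert bin_histogram([0.14, 0.15, 1.04]) == {0.1: 1, 0.2: 1, 1.0: 1}

    def test_empty(self):
        assert bin_histogram([]) == {}

    def test_conservation_of_mass(self, rng):
        values = rng.uniform(0, 1, size=1000)
        hist = bin_histogram(values.tolist())
        assert sum(hist.values()) == 1000
        assert sum(histogram_percentages(hist).values()) == pytest.approx(100.0)

    def test_clear_bimodality_detected(self):
        hist = {0.2: 20, 0.3: 3, 1.0: 4, 1.1: 3}
        bimodal, lower, upper = is_bimodal(hist)
        assert bimodal and lower == pytest.approx(0.2) and upper == pytest.approx(1.0)

    def test_unimodal_distributions_rejected(self):
        assert not is_bimodal({0.9: 8, 1.0: 12, 1.1: 7})[0]
        # single stray outlier bins do not count as modes
        assert not is_bimodal({0.9: 13, 1.0: 5, 1.1: 5, 1.3: 2})[0]
        assert not is_bimodal({0.6: 1, 0.9: 8, 1.0: 11, 1.1: 4})[0]

    def test_upper_mode_below_one_rejected(self):
        assert not is_bimodal({0.2: 20, 0.8: 6})[0]


class TestMannWhitney:
    @pytest.mark.parametrize(
        "n1,n2,z,p",
        [
            (10, 10, -3.780, None),
            (3, 5, -2.236, 0.025),
            (16, 3, -2.683, None),
        ],
    )
    def test_complete_separation_z_values(self, n1, n2, z, p):
        high = [10.0 + i for i in range(n1)]
        low = [float(i) for i in range(n2)]
        u, z_obs, p_obs = mann_whitney(high, low)
        assert u == 0.0
        assert round(z_obs, 3) == z
        if p is not None:
            assert round(p_obs, 3) == p

    def test_perfect_interleaving_gives_zero_z(self):
        a = [1.0, 3.0, 5.0, 7.0]
        b = [2.0, 4.0, 6.0, 8.0]
        u, z, p = mann_whitney(a, b)
        assert u == pytest.approx(len(a) * len(b) / 2 + 2)  # near-symmetric
        a = [1.0, 4.0, 5.0, 8.0]
        b = [2.0, 3.0, 6.0, 7.0]
        u, z, p = mann_whitney(a, b)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(SelectionError):
            mann_whitney([], [1.0])


def _table_from_ratios(ratio_map):
    pairs = [
        PairRates(a, b, r * 0.5, 0.5, r, OK) for (a, b), r in ratio_map.items()
    ]
    ids = tuple(sorted({x for ab in ratio_map for x in ab}))
    return PairwiseRateTable(pairs=pairs, ids=ids)


class TestDetectElevated:
    def test_uniform_low_ratios_not_bimodal(self):
        ratio_map = {("a", "b"): 0.2, ("a", "c"): 0.21, ("b", "c"): 0.19}
        report = detect_elevated(_table_from_ratios(ratio_map))
        assert not report.bimodal and not report.flagged_sequences

    def test_flagged_vs_flagged_pairs_excluded(self):
        # x and y are responsible for every elevated comparison; their own
        # mutual comparison joins neither group
        ratio_map = {}
        background = ["b1", "b2", "b3", "b4", "b5", "b6"]
        for i, b in enumerate(background):
            for c in background[i + 1 :]:
                ratio_map[(b, c)] = 0.2
        for flagged in ("x", "y"):
            for b in background:
                ratio_map[(flagged, b)] = 1.1
        ratio_map[("x", "y")] = 0.15  # aberrantly low flagged-vs-flagged
        report = detect_elevated(_table_from_ratios(ratio_map))
        assert report.bimodal
        assert report.flagged_sequences == {"x", "y"}
        assert report.excluded == [0.15]
        assert len(report.elevated) == 12
        assert len(report.non_elevated) == 15
        assert report.Z < 0  # elevated group fully above background

    def test_single_sequence_rejected(self):
        table = PairwiseRateTable(pairs=[], ids=("only",))
        with pytest.raises(InsufficientDataError):
            detect_elevated(table)
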