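"""Tests for the parsimony-informative-site recombination screen."""

import numpy as np
import pytest

from carotevol import (
    CodonAlignment,
    classify_sites,
    gen_recombinant_alignment,
    gen_tree,
    q_null_test,
    q_statistic,
    sim_codon_alignment,
    third_positions,
)
from carotevol.recombination import (
    DegenerateInputError,
    INVARIANT,
    MULTI_STATE,
    SINGLETON,
    SiteAlignment,
    TWO_STATE_INFORMATIVE,
    nj_tree,
)
from carotevol.simulate import SimulationParams
from carotevol.trees import TreeError

from oracles import classify_brute


def _aln(*seqs):
    return CodonAlignment.from_pairs((f"s{i}", s) for i, s in enumerate(seqs))


def _sites(*seqs):
    return SiteAlignment(
        tuple(f"s{i}" for i in range(len(seqs))), tuple(seqs)
    )


class TestThirdPositions:
    def test_every_third_column_retained(self):
        aln = _aln("AAATTTGGG", "AAATTTGGG", "AAATTTGGG", "AAATTTGGG")
        sites = third_positions(aln)
        assert sites.length == 3
        assert sites.sequences[0] == "ATG"

    def test_gapped_third_position_column_removed(self):
        aln = _aln("AAATTT", "AAATT-", "AAATTT", "AAATTT")
        sites = third_positions(aln)
        assert sites.length == 1  # codon-2 third position (T/-/T/T) dropped

    def test_all_columns_gapped_rejected(self):
        aln = _aln("AA-", "AA-", "AAN", "AA-")
        with pytest.raises(DegenerateInputError):
            third_positions(aln)

    def test_matches_brute_force_column_filter(self, rng):
        for _ in range(20):
            n, codons = 5, 30
            rows = []
            for _ in range(n):
                chars = rng.choice(list("ACGT-N"), size=3 * codons,
                                   p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04])
                rows.append("".join(chars))
            aln = _aln(*rows)
            expected_cols = [
                k for k in range(codons)
                if all(r[3 * k + 2] in "ACGT" for r in rows)
            ]
            if not expected_cols:
                continue
            sites = third_positions(aln)
            for i, row in enumerate(rows):
                assert sites.sequences[i] == "".join(
                    row[3 * k + 2] for k in expected_cols
                )


class TestClassifySites:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", INVARIANT),
            ("AAAT", SINGLETON),
            ("AATT", TWO_STATE_INFORMATIVE),
            ("AACT", MULTI_STATE),
        ],
    )
    def test_column_classes(self, column, expected):
        sites = _sites(*[c for c in column])
        counts = classify_sites(sites).counts
        assert counts[expected] == 1
        assert sum(counts.values()) == 1

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            classify_sites(_sites("A", "A", "T"))

    def test_matches_tally_oracle(self, rng):
        for _ in range(20):
            n, length = int(rng.integers(4, 9)), 40
            rows = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
            sites = _sites(*rows)
            counts = classify_sites(sites).counts
            columns = ["".join(r[i] for r in rows) for i in range(length)]
            expected = classify_brute(columns)
            for cls in (INVARIANT, SINGLETON, TWO_STATE_INFORMATIVE, MULTI_STATE):
                assert counts[cls] == expected.count(cls)


class TestQStatistic:
    def test_undefined_without_polymorphism(self):
        result = q_statistic(_sites("AAA", "AAA", "AAA", "AAA"))
        assert result.q is None

    def test_half_informative(self):
        # one informative column (AATT) + one singleton column (AAAT)
        result = q_statistic(_sites("AA", "AA", "TA", "TT"))
        assert result.q == pytest.approx(0.5)
        assert result.n_polymorphic == 2

    def test_bounds(self):
        assert q_statistic(_sites("AT", "AT", "TA", "TA")).q == 1.0
        assert q_statistic(_sites("AT", "AA", "AA", "AA")).q == 0.0

    def test_invariant_to_sequence_and_column_permutation(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(6)]
        base = q_statistic(_sites(*rows)).q
        order = rng.permutation(6)
        cols = rng.permutation(30)
        shuffled = ["".join(rows[i][c] for c in cols) for i in order]
        assert q_statistic(_sites(*shuffled)).q == base


class TestQNullTest:
    def test_invalid_reps_rejected(self):
        sites = _sites("AT", "AA", "TA", "AA")
        tree = gen_tree(4, 0.1, seed=1)
        with pytest.raises(ValueError):
            q_null_test(sites, tree, n_reps=0)

    def test_missing_tree_leaves_rejected(self):
        sites = SiteAlignment(("x1", "x2", "x3", "x4"), ("A", "A", "T", "T"))
        with pytest.raises(TreeError):
            q_null_test(sites, gen_tree(4, 0.1, seed=1), n_reps=10)

    def test_deterministic_and_consistent(self):
        tree = gen_tree(6, 0.2, seed=8)
        aln = sim_codon_alignment(
            tree, SimulationParams(codon_length=150, default_omega=1.0, seed=8)
        )
        sites = third_positions(aln)
        r1 = q_null_test(sites, tree, n_reps=100, seed=5)
        r2 = q_null_test(sites, tree, n_reps=100, seed=5)
        assert (r1.p_lower, r1.p_upper) == (r2.p_lower, r2.p_upper)
        assert r1.q == r1.n_informative_two_state / r1.n_polymorphic
        assert 0 < r1.p_lower <= 1 and 0 < r1.p_upper <= 1
        # the two one-sided tails overlap only at the observed value
        assert r1.p_lower + r1.p_upper >= 1.0

    def test_extra_tree_leaves_are_pruned(self):
        tree = gen_tree(8, 0.2, seed=9)
        aln = sim_codon_alignment(
            tree, SimulationParams(codon_length=100, default_omega=1.0, seed=9)
        )
        keep = sorted(tree.leaf_names())[:5]
        sites = third_positions(aln.subset(keep))
        result = q_null_test(sites, tree, n_reps=50, seed=2)
        assert result.q is not None

    def test_recombinant_shifts_q_against_nj_null(self):
        """Power smoke check: recombinants between discordant trees trip
        the upper tail more often than clonal controls."""
        rec_hits = clonal_hits = 0
        n = 8
        for seed in range(n):
            t1 = gen_tree(8, 0.1, seed=300 + seed)
            t2 = gen_tree(8, 0.1, seed=600 + seed)
            params = SimulationParams(codon_length=300, default_omega=1.0, seed=seed)
            rec = gen_recombinant_alignment(t1, t2, 150, params)
            clo = sim_codon_alignment(t1, params)
            for aln, bump in ((rec, "rec"), (clo, "clo")):
                sites = third_positions(aln)
                res = q_null_test(sites, nj_tree(sites), n_reps=100, seed=seed)
                if res.p_upper is not None and res.p_upper < 0.05:
                    if bump == "rec":
                        rec_hits += 1
                    else:
                        clonal_hits += 1
        assert rec_hits > clonal_hits
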