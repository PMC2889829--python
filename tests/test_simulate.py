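"""Tests for tree, alignment and profile generators."""

import numpy as np
import pytest

from carotevol import (
    LabeledTree,
    gen_enzyme_profiles,
    gen_recombinant_alignment,
    gen_tree,
    plant_elevated_lineage,
    sim_codon_alignment,
)
from carotevol.codons import genetic_code
from carotevol.pathway import RegistryError
from carotevol.selection import build_rate_table
from carotevol.simulate import ConfigurationError, SimulationParams
from carotevol.trees import TreeError


def translate(seq):
    code = genetic_code()
    return "".join(code[seq[i : i + 3]] for i in range(0, len(seq), 3))


class TestGenTree:
    def test_two_taxa_forced_topology(self):
        tree = gen_tree(2, 0.1, seed=1)
        assert tree.n_leaves == 2
        internal = [
            n for n in tree.tree.preorder_node_iter() if not n.is_leaf()
        ]
        assert len(internal) == 1

    def test_seed_determinism(self):
        assert gen_tree(8, 0.1, seed=42).newick() == gen_tree(8, 0.1, seed=42).newick()
        assert gen_tree(8, 0.1, seed=42).newick() != gen_tree(8, 0.1, seed=43).newick()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            gen_tree(1, 0.1, seed=0)

    def test_branch_lengths_positive(self):
        tree = gen_tree(12, 0.05, seed=3)
        assert all(length > 0 for _, length in tree.branches())

    def test_total_length_matches_exponential_mean(self):
        """Monte-Carlo: an 8-taxon binary tree has 14 branches, so the mean
        total length over 200 seeds must sit within 3 standard errors of
        14 x 0.1."""
        totals = [gen_tree(8, 0.1, seed=s).total_branch_length() for s in range(200)]
        expected = 14 * 0.1
        se = (14 * 0.1**2 / 200) ** 0.5  # var of one exponential = mean^2
        assert abs(np.mean(totals) - expected) < 3 * se


class TestCodonSimulator:
    def test_omega_zero_preserves_protein(self):
        tree = gen_tree(6, 0.3, seed=7)
        aln = sim_codon_alignment(
            tree, SimulationParams(codon_length=80, default_omega=0.0, seed=3)
        )
        proteins = {translate(s) for s in aln.sequences}
        assert len(proteins) == 1

    def test_zero_branch_lengths_copy_root(self):
        tree = gen_tree(5, 0.1, seed=11)
        for name, _ in tree.branches():
            tree.set_branch_length(name, 0.0)
        aln = sim_codon_alignment(
            tree, SimulationParams(codon_length=50, default_omega=1.0, seed=5)
        )
        assert len(set(aln.sequences)) == 1

    def test_seed_determinism_and_shape(self):
        tree = gen_tree(6, 0.1, seed=2)
        params = SimulationParams(codon_length=40, default_omega=0.5, seed=9)
        a1 = sim_codon_alignment(tree, params)
        a2 = sim_codon_alignment(tree, params)
        assert a1.sequences == a2.sequences
        assert a1.length == 120
        assert sorted(a1.ids) == sorted(tree.leaf_names())

    def test_no_stop_codons_anywhere(self):
        tree = gen_tree(8, 0.4, seed=13)
        aln = sim_codon_alignment(
            tree, SimulationParams(codon_length=100, default_omega=1.5, seed=17)
        )
        for seq in aln.sequences:
            assert "*" not in translate(seq)

    def test_missing_omega_is_configuration_error(self):
        tree = gen_tree(4, 0.1, seed=1)
        params = SimulationParams(
            codon_length=10, omega_map={}, default_omega=None, seed=1
        )
        with pytest.raises(ConfigurationError):
            sim_codon_alignment(tree, params)

    def test_omega_monotone_in_estimated_dnds(self):
        """Mean estimated dN/dS must order as 0.2 < 1.0 < 1.5 on a fixed
        tree over replicate seeds."""
        tree = gen_tree(8, 0.1, seed=100)
        means = {}
        for omega in (0.2, 1.0, 1.5):
            ratios = []
            for seed in range(20):
                aln = sim_codon_alignment(
                    tree,
                    SimulationParams(
                        codon_length=500, default_omega=omega, seed=seed
                    ),
                )
                ratios.extend(build_rate_table(aln).ratios())
            means[omega] = np.mean(ratios)
        assert means[0.2] < means[1.0] < means[1.5]

    def test_neutral_estimates_center_on_one(self):
        """Simulator/estimator self-consistency: mean pairwise dN/dS at
        omega = 1 lies in [0.8, 1.2]."""
        ratios = []
        for seed in range(8):
            tree = gen_tree(8, 0.1, seed=200 + seed)
            aln = sim_codon_alignment(
                tree, SimulationParams(codon_length=500, default_omega=1.0, seed=seed)
            )
            ratios.extend(build_rate_table(aln).ratios())
        assert 0.8 <= np.mean(ratios) <= 1.2

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationParams(codon_length=0)
        with pytest.raises(ConfigurationError):
            SimulationParams(nucleotide_freqs=(0.5, 0.5, 0.1, 0.1))
        with pytest.raises(ConfigurationError):
            SimulationParams(omega_map={"x": -1.0})


class TestRecombinant:
    def test_leaf_set_mismatch_rejected(self):
        a, b = gen_tree(6, 0.1, 1), gen_tree(8, 0.1, 2)
        with pytest.raises(TreeError):
            gen_recombinant_alignment(
                a, b, 10, SimulationParams(codon_length=20, seed=1)
            )

    def test_breakpoint_bounds(self):
        t = gen_tree(4, 0.1, 1)
        for bp in (0, 20):
            with pytest.raises(ValueError):
                gen_recombinant_alignment(
                    t, t, bp, SimulationParams(codon_length=20, seed=1)
                )

    def test_segments_concatenate_per_leaf(self):
        t1, t2 = gen_tree(6, 0.1, 5), gen_tree(6, 0.1, 6)
        params = SimulationParams(codon_length=30, seed=4)
        aln = gen_recombinant_alignment(t1, t2, 12, params)
        assert aln.length == 90
        assert sorted(aln.ids) == sorted(t1.leaf_names())
        # deterministic
        again = gen_recombinant_alignment(t1, t2, 12, params)
        assert aln.sequences == again.sequences


class TestPlantedLineage:
    def test_planted_branch_gets_elevated_omega(self):
        tree = gen_tree(8, 0.05, seed=3)
        tree2, omega_map, leaf = plant_elevated_lineage(tree, seed=3)
        assert omega_map[leaf] == 1.5
        assert set(omega_map) == {name for name, _ in tree2.branches()}
        others = {b: w for b, w in omega_map.items() if b != leaf}
        assert set(others.values()) == {0.2}
        assert dict(tree2.branches())[leaf] == pytest.approx(0.6)

    def test_unknown_leaf_rejected(self):
        tree = gen_tree(4, 0.1, seed=1)
        with pytest.raises(TreeError):
            plant_elevated_lineage(tree, leaf="nope")


class TestEnzymeProfiles:
    def test_no_events_propagates_ancestral_set(self, registry):
        tree = gen_tree(6, 0.1, seed=9)
        ancestral = {"CrtB", "CrtI", "CrtY", "CrtZ"}
        profiles, log = gen_enzyme_profiles(
            tree, registry, ancestral, p_loss=0.0, n_hgt=0, seed=1
        )
        assert all(set(p.families) == ancestral for p in profiles.values())
        assert not log.losses and not log.transfers

    def test_certain_loss_empties_profiles(self, registry):
        tree = gen_tree(6, 0.1, seed=9)
        profiles, log = gen_enzyme_profiles(
            tree, registry, {"CrtB", "CrtI"}, p_loss=1.0, n_hgt=0, seed=1
        )
        assert all(not p.families for p in profiles.values())

    def test_unknown_family_rejected(self, registry):
        tree = gen_tree(4, 0.1, seed=1)
        with pytest.raises(RegistryError):
            gen_enzyme_profiles(tree, registry, {"NotAnEnzyme"}, seed=1)

    def test_event_log_conservation(self, registry):
        """Leaf profile size = |ancestral| - losses on path + transfers in,
        per the generator's own bookkeeping."""
        ancestral = {"CrtB", "CrtI", "CrtY", "CrtZ", "CrtW", "CrtU"}
        for seed in range(10):
            tree = gen_tree(10, 0.1, seed=seed)
            profiles, log = gen_enzyme_profiles(
                tree, registry, ancestral, p_loss=0.15, n_hgt=2, seed=seed
            )
            for leaf in tree.leaf_names():
                path = set()
                node = tree.node(leaf)
                while node is not None:
                    path.add(tree.name_of(node))
                    node = node.parent_node
                lost = {f for b, f in log.losses if b in path}
                gained = {f for _, b, f in log.transfers if b in path}
                expected = (ancestral - lost) | gained
                assert set(profiles[leaf].families) == expected

    def test_determinism(self, registry):
        tree = gen_tree(8, 0.1, seed=4)
        kwargs = dict(p_loss=0.2, n_hgt=1, seed=77)
        p1, l1 = gen_enzyme_profiles(tree, registry, {"CrtB", "CrtI"}, **kwargs)
        p2, l2 = gen_enzyme_profiles(tree, registry, {"CrtB", "CrtI"}, **kwargs)
        assert p1 == p2
        assert l1.losses == l2.losses and l1.transfers == l2.transfers
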