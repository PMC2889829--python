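"""q-statistic recombination screen on clonal vs recombinant alignments.

The statistic q is the fraction of polymorphic third-codon-position sites
that are two-state parsimony informative. Each alignment is compared with
1000 clonal alignments simulated on a neighbor-joining tree estimated from
the data itself (branch lengths rescaled to match the observed number of
polymorphic sites). Recombination between discordant genealogies
compresses the estimated tree's internal branches, so the observed q sits
in the upper tail of its clonal null.
"""

from carotevol import gen_recombinant_alignment, gen_tree, q_null_test, sim_codon_alignment, third_positions
from carotevol.recombination import nj_tree
from carotevol.simulate import SimulationParams

params = SimulationParams(codon_length=300, kappa=1.0, default_omega=1.0, seed=42)
tree_a = gen_tree(8, 0.1, seed=42)
tree_b = gen_tree(8, 0.1, seed=43)  # independent draw -> discordant topology

clonal = sim_codon_alignment(tree_a, params)
recombinant = gen_recombinant_alignment(tree_a, tree_b, breakpoint=150, params=params)

for label, alignment in (("clonal", clonal), ("recombinant", recombinant)):
    sites = third_positions(alignment)
    result = q_null_test(sites, nj_tree(sites), n_reps=1000, seed=42)
    print(
        f"{label:<12} q={result.q:.3f} "
        f"({result.n_informative_two_state}/{result.n_polymorphic} informative/polymorphic) "
        f"p_lower={result.p_lower:.3f} p_upper={result.p_upper:.3f}"
    )
# The clonal alignment's q is typical of its null (both tail probabilities
# moderate); the recombinant alignment shows an excess of informative
# sites relative to clonal expectation (small p_upper).
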