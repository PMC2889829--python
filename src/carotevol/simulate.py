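"""Synthetic data generation.

Everything downstream of this module (pathway reconstruction, clade
annotation, gain/loss parsimony, the dN/dS and recombination screens)
operates on trees, codon alignments and enzyme presence/absence profiles.
This module generates all three with planted, logged ground truth so the
screens can be exercised and calibrated without any external sequence data:

* Yule trees with exponential branch lengths;
* codon alignments evolved by a Gillespie simulation under an MG94-style
  parameterization (nucleotide-level rates, kappa for transitions, omega
  multiplying nonsynonymous changes, stop-creating mutations rejected),
  with omega settable per branch so elevated-ratio lineages can be planted;
* recombinant alignments whose two segments evolve on discordant trees;
* enzyme-family profiles produced by propagating an ancestral pathway gene
  set down a tree with per-branch stochastic loss and uniformly placed
  horizontal transfer events, all recorded in an event log.

Because the package measures selection with Nei–Gojobori counting, the
simulator by default calibrates its internal nonsynonymous rate multiplier
(a closed-form constant depending on kappa, the nucleotide frequencies and
the genetic code) so that the nominal omega of a branch equals the NG86
d_n/d_s that the selection screen converges to on long sequences; see
docs/methods.md. Set ``calibrate_omega=False`` for raw MG94 rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .alignment import CodonAlignment
from .codons import genetic_code, is_transition, sense_codons, single_neighbors
from .selection import codon_site_counts
from .trees import LabeledTree, TreeError


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Codon-simulation parameters.

    kappa:
        Transition/transversion rate ratio (dimensionless), default 2.
    omega_map:
        Mapping from branch (child node name) to omega, the
        nonsynonymous/synonymous rate ratio for that branch.
    default_omega:
        Omega for branches absent from ``omega_map``; a missing branch
        without a default is a configuration error.
    codon_length:
        Number of codons simulated.
    nucleotide_freqs:
        Equilibrium A/C/G/T frequencies; must sum to 1.
    seed:
        Seed for all randomness in one simulation call.
    calibrate_omega:
        Express omega on the NG86 d_n/d_s scale (see module docstring).
    """

    codon_length: int = 300
    kappa: float = 2.0
    omega_map: Dict[str, float] = field(default_factory=dict)
    default_omega: Optional[float] = 1.0
    nucleotide_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    table_id: int = 1
    calibrate_omega: bool = True

    def __post_init__(self) -> None:
        if self.codon_length < 1:
            raise ConfigurationError("codon_length must be >= 1")
        if abs(sum(self.nucleotide_freqs) - 1.0) > 1e-9:
            raise ConfigurationError("nucleotide frequencies must sum to 1")
        if any(f <= 0 for f in self.nucleotide_freqs):
            raise ConfigurationError("nucleotide frequencies must be positive")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        for branch, omega in self.omega_map.items():
            if omega < 0:
                raise ConfigurationError(f"omega < 0 on branch {branch}")
        if self.default_omega is not None and self.default_omega < 0:
            raise ConfigurationError("default_omega must be >= 0")

    def omega_for(self, branch: str) -> float:
        if branch in self.omega_map:
            return self.omega_map[branch]
        if self.default_omega is None:
            raise ConfigurationError(f"no omega for branch {branch} and no default")
        return self.default_omega


# ---------------------------------------------------------------------------
# Tree generation (Yule split process, exponential branch lengths)
# ---------------------------------------------------------------------------


def gen_tree(n_taxa: int, mean_branch_length: float = 0.1, seed: int = 0) -> LabeledTree:
    """Random binary tree: Yule topology, iid exponential branch lengths.

    A binary tree on ``n_taxa`` leaves has ``2*n_taxa - 2`` branches, so the
    expected total tree length is ``(2*n_taxa - 2) * mean_branch_length``.
    Deterministic in all arguments.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if mean_branch_length <= 0:
        raise ValueError("mean_branch_length must be positive")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    # start from a two-leaf tree, repeatedly split a uniformly chosen leaf
    leaves: List[dendropy.Node] = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        leaves.append(child)
    while len(leaves) < n_taxa:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            leaves.append(node.new_child())
    # name leaves deterministically in preorder
    leaf_counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            leaf_counter += 1
            node.taxon = taxon_ns.new_taxon(f"t{leaf_counter}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(mean_branch_length))
            if node.edge.length == 0.0:  # exclude the measure-zero degenerate draw
                node.edge.length = mean_branch_length * 1e-9
    return LabeledTree(tree)


# ---------------------------------------------------------------------------
# Codon substitution model
# ---------------------------------------------------------------------------


class _CodonModel:
    """Precomputed neighbor structure and rates for one (kappa, freqs, code).

    Rates follow MG94: a single-nucleotide change from codon c to codon c'
    at position with target nucleotide x has rate
    ``mu * kappa^[transition] * pi_x * (omega' if nonsynonymous)``, with
    stop-codon targets removed. ``mu`` normalizes the neutral (omega=1)
    expected substitution rate to one per nucleotide site, so branch
    lengths are expected substitutions per site at neutrality.
    """

    def __init__(self, kappa: float, freqs: Sequence[float], table_id: int):
        self.kappa = kappa
        self.freqs = tuple(freqs)
        self.table_id = table_id
        code = genetic_code(table_id)
        self.codons = sense_codons(table_id)
        self.index = {c: i for i, c in enumerate(self.codons)}
        pi = dict(zip("ACGT", freqs))

        # stationary-ish codon weights: product of nucleotide frequencies
        w = np.array(
            [pi[c[0]] * pi[c[1]] * pi[c[2]] for c in self.codons], dtype=float
        )
        self.codon_weights = w / w.sum()

        self.targets: List[np.ndarray] = []
        self.base_rates: List[np.ndarray] = []
        self.nonsyn: List[np.ndarray] = []
        for codon in self.codons:
            t_idx, rates, nonsyn = [], [], []
            for pos, mutant in single_neighbors(codon):
                if code[mutant] == "*":
                    continue
                rate = pi[mutant[pos]]
                if is_transition(codon[pos], mutant[pos]):
                    rate *= kappa
                t_idx.append(self.index[mutant])
                rates.append(rate)
                nonsyn.append(code[mutant] != code[codon])
            self.targets.append(np.array(t_idx, dtype=np.int64))
            self.base_rates.append(np.array(rates, dtype=float))
            self.nonsyn.append(np.array(nonsyn, dtype=bool))

        # normalization: neutral expected rate per codon = 3 (per nt site = 1)
        neutral = sum(
            self.codon_weights[i] * self.base_rates[i].sum()
            for i in range(len(self.codons))
        )
        self.mu = 3.0 / neutral
        self._per_omega: Dict[float, Tuple[List[np.ndarray], np.ndarray]] = {}

    def ng86_calibration(self) -> float:
        """Constant c(kappa, pi, code) with NG86 d_n/d_s -> omega when
        the internal nonsynonymous multiplier is ``omega * c``.

        Derived from the low-divergence limit: NG86 estimates
        (Nd/N)/(Sd/S); substitution fluxes are kappa- and pi-weighted while
        NG86 site counts are not, so c = (Fs * Nbar) / (Fn * Sbar) where
        Fs/Fn are neutral synonymous/nonsynonymous fluxes and Sbar/Nbar the
        mean NG86 site counts under the codon weights.
        """
        fs = fn = sbar = 0.0
        for i, codon in enumerate(self.codons):
            w = self.codon_weights[i]
            fs += w * self.base_rates[i][~self.nonsyn[i]].sum()
            fn += w * self.base_rates[i][self.nonsyn[i]].sum()
            s_sites, _ = codon_site_counts(codon, self.table_id)
            sbar += w * s_sites
        nbar = 3.0 - sbar
        return (fs * nbar) / (fn * sbar)

    def rates_for_omega(self, omega: float) -> Tuple[List[np.ndarray], np.ndarray]:
        key = round(omega, 12)
        if key not in self._per_omega:
            rates = []
            totals = np.empty(len(self.codons))
            for i in range(len(self.codons)):
                r = self.base_rates[i] * np.where(self.nonsyn[i], omega, 1.0) * self.mu
                rates.append(np.cumsum(r))
                totals[i] = r.sum()
            self._per_omega[key] = (rates, totals)
        return self._per_omega[key]


_MODEL_CACHE: Dict[tuple, _CodonModel] = {}


def _get_model(params: SimulationParams) -> _CodonModel:
    key = (params.kappa, params.nucleotide_freqs, params.table_id)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = _CodonModel(
            params.kappa, params.nucleotide_freqs, params.table_id
        )
    return _MODEL_CACHE[key]


def _evolve_branch(
    model: _CodonModel,
    codon_indices: np.ndarray,
    branch_length: float,
    omega_internal: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gillespie simulation of every codon independently along one branch."""
    cum_rates, totals = model.rates_for_omega(omega_internal)
    out = codon_indices.copy()
    if branch_length <= 0:
        return out
    for k in range(out.shape[0]):
        c = out[k]
        t_remaining = branch_length
        while True:
            lam = totals[c]
            if lam <= 0.0:  # e.g. omega = 0 and no synonymous neighbor
                break
            dt = rng.exponential(1.0 / lam)
            if dt >= t_remaining:
                break
            t_remaining -= dt
            cums = cum_rates[c]
            u = rng.random() * cums[-1]
            c = model.targets[c][int(np.searchsorted(cums, u))]
        out[k] = c
    return out


def sim_codon_alignment(tree: LabeledTree, params: SimulationParams) -> CodonAlignment:
    """Evolve a codon alignment along ``tree`` under ``params``.

    One sequence per leaf, length ``3 * codon_length``, no stop codons
    anywhere (stop-creating mutations are rejected by construction).
    Deterministic in tree, parameters and seed.
    """
    # validate omegas up front so a missing branch fails before simulating
    for branch, _ in tree.branches():
        params.omega_for(branch)
    model = _get_model(params)
    cal = model.ng86_calibration() if params.calibrate_omega else 1.0
    rng = np.random.default_rng(params.seed)

    root_codons = rng.choice(
        len(model.codons), size=params.codon_length, p=model.codon_weights
    )

    states: Dict[str, np.ndarray] = {}
    root_name = tree.name_of(tree.root)
    states[root_name] = root_codons
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        name = tree.name_of(node)
        parent = tree.name_of(node.parent_node)
        omega = params.omega_for(name)
        states[name] = _evolve_branch(
            model,
            states[parent],
            float(node.edge.length or 0.0),
            omega * cal,
            rng,
        )

    pairs = []
    for leaf in sorted(tree.leaf_names()):
        seq = "".join(model.codons[i] for i in states[leaf])
        pairs.append((leaf, seq))
    return CodonAlignment.from_pairs(pairs)


def gen_recombinant_alignment(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    breakpoint: int,
    params: SimulationParams,
) -> CodonAlignment:
    """Alignment whose codons [0, breakpoint) evolve on ``tree_a`` and the
    rest on ``tree_b`` — a positive control for recombination screens."""
    if set(tree_a.leaf_names()) != set(tree_b.leaf_names()):
        raise TreeError("trees must share the same leaf set")
    if not 0 < breakpoint < params.codon_length:
        raise ValueError("breakpoint must satisfy 0 < breakpoint < codon_length")
    seeds = np.random.SeedSequence(params.seed).generate_state(2)
    left = sim_codon_alignment(
        tree_a, replace(params, codon_length=breakpoint, seed=int(seeds[0]))
    )
    right = sim_codon_alignment(
        tree_b,
        replace(
            params,
            codon_length=params.codon_length - breakpoint,
            seed=int(seeds[1]),
        ),
    )
    return left.concat(right.subset(left.ids))


# ---------------------------------------------------------------------------
# Planted elevated-omega lineage
# ---------------------------------------------------------------------------


def plant_elevated_lineage(
    tree: LabeledTree,
    leaf: Optional[str] = None,
    omega_elevated: float = 1.5,
    omega_background: float = 0.2,
    elevated_branch_length: float = 0.6,
    seed: int = 0,
) -> Tuple[LabeledTree, Dict[str, float], str]:
    """Give one leaf an episode of positive selection.

    The chosen leaf's terminal branch gets ``omega_elevated`` and length
    ``elevated_branch_length`` (all other branches keep their lengths and
    get ``omega_background``). A pairwise d_n/d_s is a path-length-weighted
    mixture of branch omegas, so the planted branch must dominate the paths
    to the planted leaf for a pairwise screen to stand a chance of seeing
    it; the default length models the accelerated divergence that real
    positively selected sequences show against all their partners.

    Returns the modified tree, the omega map, and the planted leaf name.
    """
    tree = tree.copy()
    if leaf is None:
        rng = np.random.default_rng(seed)
        leaf = sorted(tree.leaf_names())[int(rng.integers(tree.n_leaves))]
    elif leaf not in tree.leaf_names():
        raise TreeError(f"unknown leaf: {leaf}")
    tree.set_branch_length(leaf, elevated_branch_length)
    omega_map = {branch: omega_background for branch, _ in tree.branches()}
    omega_map[leaf] = omega_elevated
    return tree, omega_map, leaf


# ---------------------------------------------------------------------------
# Enzyme-profile evolution with loss and horizontal transfer
# ---------------------------------------------------------------------------


@dataclass
class GeneEventLog:
    """Ground-truth record of simulated gene loss and transfer events."""

    losses: List[Tuple[str, str]] = field(default_factory=list)
    transfers: List[Tuple[str, str, str]] = field(default_factory=list)

    def loss_count(self, family: str) -> int:
        return sum(1 for _, fam in self.losses if fam == family)

    def transfer_count(self, family: str) -> int:
        return sum(1 for _, _, fam in self.transfers if fam == family)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("event\tbranch\tdonor\tfamily\n")
            for branch, fam in self.losses:
                fh.write(f"loss\t{branch}\t-\t{fam}\n")
            for donor, recipient, fam in self.transfers:
                fh.write(f"transfer\t{recipient}\t{donor}\t{fam}\n")


def gen_enzyme_profiles(
    tree: LabeledTree,
    graph,
    ancestral_set: Set[str],
    p_loss: float = 0.1,
    n_hgt: int = 0,
    seed: int = 0,
    p_rhodopsin: float = 0.5,
):
    """Evolve enzyme presence/absence profiles down ``tree``.

    The ancestral enzyme-family set is inherited along every branch, each
    present family being lost independently with probability ``p_loss`` per
    branch; afterwards ``n_hgt`` transfer events are placed uniformly over
    valid (donor branch, recipient branch, family) triples — donor carrying
    the family, recipient lacking it — and the family is restored
    throughout the recipient's subtree. A leaf gets ``rhodopsin=True`` with
    probability ``p_rhodopsin`` when its profile reaches beta-carotene (the
    retinal precursor), otherwise False.

    Returns ``(leaf name -> EnzymeProfile, GeneEventLog)``.
    """
    from .pathway import EnzymeProfile, RegistryError, reachable_compounds

    unknown = {f for f in ancestral_set if graph.base_family(f) not in graph.families}
    if unknown:
        raise RegistryError(f"unknown enzyme families: {sorted(unknown)}")
    if not 0.0 <= p_loss <= 1.0:
        raise ConfigurationError("p_loss must be a probability")
    if n_hgt < 0:
        raise ConfigurationError("n_hgt must be >= 0")

    rng = np.random.default_rng(seed)
    log = GeneEventLog()

    root_name = tree.name_of(tree.root)
    state: Dict[str, Set[str]] = {root_name: set(ancestral_set)}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        name = tree.name_of(node)
        parent = tree.name_of(node.parent_node)
        inherited = set()
        for fam in sorted(state[parent]):
            if rng.random() < p_loss:
                log.losses.append((name, fam))
            else:
                inherited.add(fam)
        state[name] = inherited

    branch_names = [name for name, _ in tree.branches()]
    subtree = {
        name: [tree.name_of(n) for n in tree.node(name).preorder_iter()]
        for name in branch_names
    }
    for _ in range(n_hgt):
        candidates = [
            (donor, recipient, fam)
            for fam in sorted(ancestral_set)
            for donor in branch_names
            if fam in state[donor]
            for recipient in branch_names
            if recipient != donor and fam not in state[recipient]
        ]
        if not candidates:
            break  # no valid placement remains
        donor, recipient, fam = candidates[int(rng.integers(len(candidates)))]
        for name in subtree[recipient]:
            state[name].add(fam)
        # a transfer overrides earlier losses in the recipient subtree
        log.losses = [
            (b, f)
            for b, f in log.losses
            if not (f == fam and b in subtree[recipient])
        ]
        log.transfers.append((donor, recipient, fam))

    profiles: Dict[str, "EnzymeProfile"] = {}
    for leaf in sorted(tree.leaf_names()):
        families = frozenset(state[leaf])
        reachable = reachable_compounds(graph, families)
        rhodopsin = bool(
            "beta-carotene" in reachable and rng.random() < p_rhodopsin
        )
        profiles[leaf] = EnzymeProfile(
            organism_id=leaf, families=families, rhodopsin=rhodopsin
        )
    return profiles, log
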