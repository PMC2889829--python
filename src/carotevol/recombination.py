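"""Parsimony-informative-site recombination screen.

The statistic q is the ratio of two-state parsimony-informative sites to
all polymorphic sites in an ungapped third-codon-position alignment. Its
significance is assessed against a clonal null: alignments of identical
dimensions simulated one site at a time on a reference tree under the
Jukes–Cantor model, with branch lengths rescaled so the expected number of
polymorphic columns matches the observed one (the expectation is computed
exactly by pruning, and the scale solved by bisection). Both one-sided
tail probabilities are reported; which tail is flagged is configurable,
since excess apparent rate heterogeneity and its deficit are both
departures from clonality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import CodonAlignment
from .trees import LabeledTree, TreeError

INVARIANT = "invariant"
SINGLETON = "singleton-polymorphic"
TWO_STATE_INFORMATIVE = "two-state-informative"
MULTI_STATE = "multi-state-polymorphic"

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class SiteAlignment:
    """Gap-free nucleotide alignment (one column per retained site)."""

    ids: Tuple[str, ...]
    sequences: Tuple[str, ...]

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        return np.array(
            [[_NT_INDEX[c] for c in seq] for seq in self.sequences], dtype=np.int8
        )


def third_positions(alignment: CodonAlignment) -> SiteAlignment:
    """Extract third codon positions, dropping columns with any gap or
    ambiguous character (complete deletion)."""
    cols = []
    for k in range(alignment.n_codons):
        col = [seq[3 * k + 2] for seq in alignment.sequences]
        if all(c in _NT_INDEX for c in col):
            cols.append(col)
    if not cols:
        raise DegenerateInputError("no ungapped third-position columns remain")
    seqs = ["".join(col[i] for col in cols) for i in range(alignment.n_sequences)]
    return SiteAlignment(alignment.ids, tuple(seqs))


# ---------------------------------------------------------------------------
# Site classification and q
# ---------------------------------------------------------------------------


@dataclass
class SiteClassification:
    counts: Dict[str, int]

    @property
    def n_polymorphic(self) -> int:
        return (
            self.counts[SINGLETON]
            + self.counts[TWO_STATE_INFORMATIVE]
            + self.counts[MULTI_STATE]
        )


def _classify_matrix(matrix: np.ndarray) -> Dict[str, int]:
    state_counts = np.stack([(matrix == s).sum(axis=0) for s in range(4)])
    n_states = (state_counts > 0).sum(axis=0)
    minor = np.where(state_counts > 0, state_counts, np.iinfo(np.int64).max).min(axis=0)
    counts = {
        INVARIANT: int((n_states == 1).sum()),
        SINGLETON: int(((n_states == 2) & (minor == 1)).sum()),
        TWO_STATE_INFORMATIVE: int(((n_states == 2) & (minor >= 2)).sum()),
        MULTI_STATE: int((n_states >= 3).sum()),
    }
    return counts


def classify_sites(alignment: SiteAlignment) -> SiteClassification:
    """Classify every column as invariant, singleton-polymorphic, two-state
    parsimony-informative or multi-state-polymorphic.

    A two-state column is parsimony informative when both states occur in
    at least two sequences, which requires at least four sequences.
    """
    if alignment.n_sequences < 4:
        raise ValueError("informative-site classification needs >= 4 sequences")
    return SiteClassification(_classify_matrix(alignment.matrix()))


@dataclass
class RecombinationResult:
    """q and (optionally) its clonal-null comparison."""

    q: Optional[float]
    n_polymorphic: int
    n_informative_two_state: int
    site_counts: Dict[str, int]
    P: Optional[float] = None
    p_lower: Optional[float] = None
    p_upper: Optional[float] = None
    n_reps: int = 0
    tail: str = "lower"

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "n_polymorphic": self.n_polymorphic,
            "n_informative_two_state": self.n_informative_two_state,
            "site_counts": self.site_counts,
            "P": self.P,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "n_reps": self.n_reps,
            "tail": self.tail,
        }


def q_statistic(alignment: SiteAlignment) -> RecombinationResult:
    """q = two-state parsimony-informative sites / polymorphic sites;
    undefined (q = None) when there are no polymorphic sites."""
    cls = classify_sites(alignment)
    n_poly = cls.n_polymorphic
    n_inf = cls.counts[TWO_STATE_INFORMATIVE]
    q = n_inf / n_poly if n_poly else None
    return RecombinationResult(
        q=q,
        n_polymorphic=n_poly,
        n_informative_two_state=n_inf,
        site_counts=dict(cls.counts),
    )


# ---------------------------------------------------------------------------
# Clonal null simulation
# ---------------------------------------------------------------------------


def _k80_probs(t: float, kappa: float) -> Tuple[float, float, float]:
    """K80 transition probabilities (same, transition, each transversion)
    for one branch of length ``t`` (expected substitutions per site)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_same, p_ts, p_tv


def _prob_monomorphic(
    tree: LabeledTree, leaf_order: Sequence[str], scale: float, kappa: float
) -> float:
    """Exact probability that one K80 site is invariant across the leaves,
    by pruning (kappa=1 reduces to Jukes–Cantor). Branch lengths are
    multiplied by ``scale``.

    Tracks, per node, the probability that all leaves below equal a fixed
    reference state given the node carries that state (``a``), its
    transition partner (``b``) or either transversion partner (``c``) —
    K80's state symmetry makes these three numbers sufficient.
    """
    a: Dict[str, float] = {}
    b: Dict[str, float] = {}
    c: Dict[str, float] = {}
    keep = set(leaf_order)
    for node in tree.tree.postorder_node_iter():
        name = tree.name_of(node)
        if node.is_leaf():
            a[name], b[name], c[name] = 1.0, 0.0, 0.0
            continue
        fa = fb = fc = 1.0
        for child in node.child_nodes():
            cname = tree.name_of(child)
            if child.is_leaf() and cname not in keep:
                continue
            t = float(child.edge.length or 0.0) * scale
            ps, pt, pv = _k80_probs(t, kappa)
            ca, cb, cc = a[cname], b[cname], c[cname]
            fa *= ps * ca + pt * cb + 2.0 * pv * cc
            fb *= pt * ca + ps * cb + 2.0 * pv * cc
            fc *= pv * ca + pv * cb + (ps + pt) * cc
        a[name], b[name], c[name] = fa, fb, fc
    root = tree.name_of(tree.root)
    return a[root] + b[root] + 2.0 * c[root]


def _solve_scale(
    tree: LabeledTree,
    leaf_order: Sequence[str],
    target_poly_fraction: float,
    kappa: float,
) -> float:
    """Bisection for the branch-length multiplier matching the expected
    polymorphic-column fraction."""
    target_mono = 1.0 - target_poly_fraction

    def mono(s: float) -> float:
        return _prob_monomorphic(tree, leaf_order, s, kappa)

    lo, hi = 1e-9, 1.0
    while mono(hi) > target_mono and hi < 1e6:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mono(mid) > target_mono:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_clonal(
    tree: LabeledTree,
    leaf_order: Sequence[str],
    n_sites: int,
    scale: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One clonal K80 alignment as an integer matrix (A,C,G,T = 0..3;
    transition partner of state s is (s + 2) % 4)."""
    states: Dict[str, np.ndarray] = {}
    root = tree.name_of(tree.root)
    states[root] = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        name = tree.name_of(node)
        parent = states[tree.name_of(node.parent_node)]
        t = float(node.edge.length or 0.0) * scale
        ps, pt, pv = _k80_probs(t, kappa)
        u = rng.random(n_sites)
        child = parent.copy()
        ts_mask = (u >= ps) & (u < ps + pt)
        child[ts_mask] = (child[ts_mask] + 2) % 4
        tv_mask = u >= ps + pt
        if tv_mask.any():
            flip = rng.integers(0, 2, size=int(tv_mask.sum()), dtype=np.int8)
            child[tv_mask] = (child[tv_mask] + 1 + 2 * flip) % 4
        states[name] = child
    return np.stack([states[leaf] for leaf in leaf_order])


def q_null_test(
    alignment: SiteAlignment,
    tree: LabeledTree,
    n_reps: int = 1000,
    seed: int = 0,
    tail: str = "lower",
    kappa: float = 1.0,
) -> RecombinationResult:
    """Compare observed q against a clonal simulation null on ``tree``.

    The tree's leaf set must contain every alignment id (extra leaves are
    ignored in the pruning/simulation). Null alignments have the observed
    dimensions, simulated under K80 with the given ``kappa`` (1 = the
    Jukes–Cantor default) and branch lengths rescaled so the expected
    number of polymorphic columns matches the observed count. A kappa
    mismatch between data and null inflates the upper tail (transition
    bias creates parallel substitutions that read as extra informative
    sites), so pass the data's kappa when it is known. Tail probabilities
    use the add-one rule ``(1 + #{q_null <= q_obs}) / (n_valid + 1)`` so
    the reported P is valid at its nominal level despite discreteness.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    missing = set(alignment.ids) - set(tree.leaf_names())
    if missing:
        raise TreeError(f"tree is missing alignment leaves: {sorted(missing)}")

    observed = q_statistic(alignment)
    if observed.q is None:
        return observed

    work_tree = tree
    if set(tree.leaf_names()) - set(alignment.ids):
        work_tree = tree.copy()
        work_tree.tree.retain_taxa_with_labels(list(alignment.ids))
        work_tree = LabeledTree.from_newick(work_tree.newick())

    leaf_order = list(alignment.ids)
    scale = _solve_scale(
        work_tree, leaf_order, observed.n_polymorphic / alignment.length, kappa
    )
    rng = np.random.default_rng(seed)
    n_le = n_ge = n_valid = 0
    for _ in range(n_reps):
        matrix = _simulate_clonal(
            work_tree, leaf_order, alignment.length, scale, kappa, rng
        )
        counts = _classify_matrix(matrix)
        n_poly = counts[SINGLETON] + counts[TWO_STATE_INFORMATIVE] + counts[MULTI_STATE]
        if n_poly == 0:
            continue
        q_null = counts[TWO_STATE_INFORMATIVE] / n_poly
        n_valid += 1
        if q_null <= observed.q:
            n_le += 1
        if q_null >= observed.q:
            n_ge += 1
    p_lower = (1 + n_le) / (n_valid + 1)
    p_upper = (1 + n_ge) / (n_valid + 1)
    observed.p_lower = p_lower
    observed.p_upper = p_upper
    observed.P = p_lower if tail == "lower" else p_upper
    observed.n_reps = n_valid
    observed.tail = tail
    return observed


def recombination_screen(
    alignment: CodonAlignment,
    tree: LabeledTree,
    n_reps: int = 1000,
    seed: int = 0,
    tail: str = "lower",
    kappa: float = 1.0,
) -> RecombinationResult:
    """Third positions -> q -> clonal null comparison, in one call."""
    return q_null_test(third_positions(alignment), tree, n_reps, seed, tail, kappa)


def nj_tree(alignment: SiteAlignment) -> LabeledTree:
    """Neighbor-joining tree from Jukes–Cantor distances of a site alignment.

    Used to provide the 'tree estimated from the data' input of the null
    test in simulation experiments; negative NJ branch lengths are clamped
    to zero. (Tree inference proper is outside this package's scope.)
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = alignment.n_sequences
    mat = alignment.matrix()
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float((mat[i] != mat[j]).mean())
            if p >= 0.75:
                d = 3.0  # saturated; a large finite stand-in
            else:
                d = -0.75 * math.log1p(-4.0 * p / 3.0)
            dm[i, j] = dm[j, i] = d
    import dendropy

    tree = nj(DistanceMatrix(dm, ids=list(alignment.ids)))
    dtree = dendropy.Tree.get(
        data=str(tree), schema="newick", preserve_underscores=True
    )
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    dtree.reroot_at_midpoint(update_bipartitions=False)
    return LabeledTree(dtree)
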