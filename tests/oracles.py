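"""Independent brute-force oracles used to validate the implementation.

These are deliberately written in the most literal style possible —
explicit enumeration, repeated rescanning, exhaustive labelings — and do
not share code with the package internals they check.
"""

from itertools import permutations, product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODE = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODE[_stop] = "*"


# ---------------------------------------------------------------------------
# NG86 sites and differences
# ---------------------------------------------------------------------------


def site_fractions_brute(codon: str) -> float:
    """Synonymous site count of one codon by listing all nine mutants."""
    total = 0.0
    for pos in range(3):
        mutants = [
            codon[:pos] + nt + codon[pos + 1 :]
            for nt in "ACGT"
            if nt != codon[pos]
        ]
        sense = [m for m in mutants if CODE[m] != "*"]
        if not sense:
            continue
        syn = [m for m in sense if CODE[m] == CODE[codon]]
        total += len(syn) / len(sense)
    return total


def pathway_counts_brute(codon_a: str, codon_b: str):
    """(Sd, Nd) between two codons averaged over stop-free pathways, or
    None when every pathway crosses a stop codon."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return (0.0, 0.0)
    outcomes = []
    for order in permutations(positions):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            following = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if CODE[following] == "*":
                blocked = True
                break
            if CODE[following] == CODE[current]:
                sd += 1
            else:
                nd += 1
            current = following
        if not blocked:
            outcomes.append((sd, nd))
    if not outcomes:
        return None
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


def ng86_brute(seq_a: str, seq_b: str):
    """Full NG86 accumulation over a pair of in-frame sequences.

    Returns (S, N, Sd, Nd, usable_codons). Codons with a gap, ambiguity or
    stop on either side are skipped, as are codon pairs connected only via
    stop pathways.
    """
    S = N = Sd = Nd = 0.0
    usable = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(c not in "ACGT" for c in ca + cb):
            continue
        if CODE[ca] == "*" or CODE[cb] == "*":
            continue
        path = pathway_counts_brute(ca, cb)
        if path is None:
            continue
        sa = site_fractions_brute(ca)
        sb = site_fractions_brute(cb)
        S += (sa + sb) / 2
        N += (3 - sa + 3 - sb) / 2
        Sd += path[0]
        Nd += path[1]
        usable += 1
    return S, N, Sd, Nd, usable


# ---------------------------------------------------------------------------
# Pathway closure
# ---------------------------------------------------------------------------


def closure_brute(reactions, precursors, active_keys):
    """Reachable compounds by rescanning the reaction list until stable."""
    reachable = set(precursors)
    while True:
        added = False
        for family, variant, substrate, product in reactions:
            if (family, variant) in active_keys and substrate in reachable:
                if product not in reachable:
                    reachable.add(product)
                    added = True
        if not added:
            return reachable


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive labeling
# ---------------------------------------------------------------------------


def fitch_brute(tree, presence):
    """Minimum change count over all 2^n_internal internal labelings."""
    internal = [
        tree.name_of(n)
        for n in tree.tree.preorder_node_iter()
        if not n.is_leaf()
    ]
    edges = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((tree.name_of(node.parent_node), tree.name_of(node)))
    best = None
    for assignment in product((0, 1), repeat=len(internal)):
        states = dict(zip(internal, assignment))
        states.update(presence)
        changes = sum(1 for a, b in edges if states[a] != states[b])
        if best is None or changes < best:
            best = changes
    return best


# ---------------------------------------------------------------------------
# Clade assignment by exhaustive clade scan
# ---------------------------------------------------------------------------


def assign_brute(tree, seeds, min_seed_leaves):
    """Per-leaf assignment by scanning every clade in the tree."""
    clades = []
    for node in tree.tree.preorder_node_iter():
        leaves = [tree.name_of(l) for l in node.leaf_iter()]
        clades.append(leaves)
    out = {}
    for leaf in tree.leaf_names():
        if leaf in seeds:
            continue
        candidates = [
            c
            for c in clades
            if leaf in c and sum(1 for l in c if l in seeds) >= min_seed_leaves
        ]
        if not candidates:
            out[leaf] = "UNASSIGNED"
            continue
        smallest = min(candidates, key=len)
        labels = {seeds[l] for l in smallest if l in seeds}
        out[leaf] = labels.pop() if len(labels) == 1 else "UNASSIGNED"
    return out


# ---------------------------------------------------------------------------
# Site classification by per-column tally
# ---------------------------------------------------------------------------


def classify_brute(columns):
    """Per-column classes from plain tallies; columns are strings."""
    out = []
    for col in columns:
        tally = {}
        for c in col:
            tally[c] = tally.get(c, 0) + 1
        states = sorted(tally)
        if len(states) == 1:
            out.append("invariant")
        elif len(states) == 2:
            if min(tally.values()) >= 2:
                out.append("two-state-informative")
            else:
                out.append("singleton-polymorphic")
        else:
            out.append("multi-state-polymorphic")
    return out
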