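"""Conservative clade-based annotation, dereplication and gain/loss parsimony.

Unlabeled tree leaves are assigned a putative function only when the
smallest enclosing clade with enough seed-labeled leaves is unanimous
about that function — mixed clades never yield an assignment, trading a
higher false-negative rate for a lower false-positive rate. Strain
dereplication collapses near-identical aligned protein sequences to one
representative. Fitch small parsimony counts the minimum gains/losses of a
binary presence/absence character on a reference tree; an event count
exceeding a user threshold is the package's flag for candidate horizontal
transfer (incongruence), without attempting full reconciliation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy

from .trees import LabeledTree

UNASSIGNED = "UNASSIGNED"


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fractional identity of two aligned sequences.

    Columns gapped in both sequences are ignored; a gap opposite a residue
    counts as a mismatch. An all-shared-gap pair has identity 0.
    """
    if len(seq_a) != len(seq_b):
        raise AnnotationError("sequences are not aligned (length mismatch)")
    matches = considered = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" and b == "-":
            continue
        considered += 1
        if a == b:
            matches += 1
    return matches / considered if considered else 0.0


def dereplicate(
    sequences: Dict[str, str], identity_threshold: float = 0.99
) -> Dict[str, List[str]]:
    """Collapse aligned sequences at >= ``identity_threshold`` identity.

    Clusters are connected components of the thresholded identity graph
    (so chains of near-identical strains collapse together); each cluster's
    representative is its longest ungapped sequence, ties broken by
    lexicographically smallest id. Returns ``representative -> members``.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise AnnotationError("identity_threshold must be in (0, 1]")
    ids = sorted(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise AnnotationError("sequences are not aligned (length mismatch)")

    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(sequences[a], sequences[b]) >= identity_threshold:
                parent[find(a)] = find(b)

    clusters: Dict[str, List[str]] = {}
    for sid in ids:
        clusters.setdefault(find(sid), []).append(sid)

    out: Dict[str, List[str]] = {}
    for members in clusters.values():
        rep = min(
            members,
            key=lambda sid: (-len(sequences[sid].replace("-", "")), sid),
        )
        out[rep] = sorted(members)
    return out


# ---------------------------------------------------------------------------
# Clade-based annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationResult:
    """Per-leaf assignments with the supporting clade and the rule fired."""

    assignments: Dict[str, str] = field(default_factory=dict)
    supporting_clade: Dict[str, str] = field(default_factory=dict)
    rationale: Dict[str, str] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("leaf\tassignment\tsupporting_clade\trationale\n")
            for leaf in sorted(self.assignments):
                fh.write(
                    f"{leaf}\t{self.assignments[leaf]}\t"
                    f"{self.supporting_clade.get(leaf, '-')}\t"
                    f"{self.rationale.get(leaf, '-')}\n"
                )


def assign_by_clade(tree: LabeledTree, min_seed_leaves: int = 2) -> AnnotationResult:
    """Assign seed labels to unlabeled leaves from their smallest qualifying clade.

    For each unlabeled leaf, ancestors are walked rootward until a clade
    containing at least ``min_seed_leaves`` seed-labeled leaves is found;
    the leaf receives that clade's label only if every seed label in it
    agrees, and ``UNASSIGNED`` otherwise (mixed clades never yield a
    guess). Labels present in the seed set are the only possible outputs.
    """
    seeds = tree.leaf_labels
    if not seeds:
        raise AnnotationError("tree has no seed-labeled leaves")
    result = AnnotationResult()
    for leaf_name in tree.leaf_names():
        if leaf_name in seeds:
            continue
        node = tree.node(leaf_name).parent_node
        assigned = False
        while node is not None:
            clade_leaves = [tree.name_of(l) for l in node.leaf_iter()]
            clade_seeds = [seeds[l] for l in clade_leaves if l in seeds]
            if len(clade_seeds) >= min_seed_leaves:
                labels = set(clade_seeds)
                if len(labels) == 1:
                    label = labels.pop()
                    result.assignments[leaf_name] = label
                    result.supporting_clade[leaf_name] = tree.name_of(node)
                    result.rationale[leaf_name] = (
                        f"unanimous clade of {len(clade_seeds)} seed leaves"
                    )
                else:
                    result.assignments[leaf_name] = UNASSIGNED
                    result.supporting_clade[leaf_name] = tree.name_of(node)
                    result.rationale[leaf_name] = (
                        f"mixed seed labels {sorted(labels)} in smallest qualifying clade"
                    )
                assigned = True
                break
            node = node.parent_node
        if not assigned:
            result.assignments[leaf_name] = UNASSIGNED
            result.rationale[leaf_name] = (
                f"no clade with >= {min_seed_leaves} seed leaves"
            )
    return result


# ---------------------------------------------------------------------------
# Fitch gain/loss parsimony
# ---------------------------------------------------------------------------


@dataclass
class GainLossResult:
    """Minimum-change reconstruction of one binary character."""

    family: str
    min_changes: int
    node_states: Dict[str, int]
    events: List[Tuple[str, str]]  # (branch = child node name, "gain"/"loss")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tmin_changes\tbranch\tevent\n")
            if not self.events:
                fh.write(f"{self.family}\t{self.min_changes}\t-\t-\n")
            for branch, kind in self.events:
                fh.write(f"{self.family}\t{self.min_changes}\t{branch}\t{kind}\n")


def fitch_gainloss(
    tree: LabeledTree,
    presence: Dict[str, int],
    family: str = "character",
) -> GainLossResult:
    """Fitch small parsimony for a binary presence/absence character.

    Runs the classic two-pass algorithm on the rooted tree (trees read from
    unrooted Newick are treated as rooted at their basal node; events on
    the two root-adjacent branches are then not reliably polarized). The
    top-down pass prefers the "present" state on ties, yielding one optimal
    internal labeling whose gain/loss event list has exactly
    ``min_changes`` entries.
    """
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in presence]
    if missing:
        raise AnnotationError(f"missing presence state for leaves: {missing}")
    for leaf, state in presence.items():
        if state not in (0, 1):
            raise AnnotationError(f"state for {leaf} must be 0 or 1")

    # bottom-up pass (Hartigan's generalization, exact for polytomies too):
    # keep the states attained by a maximal number of children; each child
    # not attaining them costs one change.
    state_sets: Dict[str, set] = {}
    changes = 0
    for node in tree.tree.postorder_node_iter():
        name = tree.name_of(node)
        if node.is_leaf():
            state_sets[name] = {presence[name]}
            continue
        child_sets = [state_sets[tree.name_of(c)] for c in node.child_nodes()]
        count = {s: sum(1 for cs in child_sets if s in cs) for s in (0, 1)}
        best = max(count.values())
        state_sets[name] = {s for s, c in count.items() if c == best}
        changes += len(child_sets) - best

    node_states: Dict[str, int] = {}
    events: List[Tuple[str, str]] = []
    for node in tree.tree.preorder_node_iter():
        name = tree.name_of(node)
        if node.parent_node is None:
            node_states[name] = 1 if 1 in state_sets[name] else 0
            continue
        parent_state = node_states[tree.name_of(node.parent_node)]
        if parent_state in state_sets[name]:
            node_states[name] = parent_state
        else:
            node_states[name] = 1 if 1 in state_sets[name] else 0
            events.append((name, "gain" if node_states[name] == 1 else "loss"))

    return GainLossResult(
        family=family,
        min_changes=changes,
        node_states=node_states,
        events=events,
    )
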