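"""Logical carotenoid pathway reconstruction from enzyme presence/absence.

The pathway graph encodes known carotenoid biosynthetic reactions as
single-substrate edges between compound nodes (precursors FPP and GGPP are
available a priori). Given an organism's complement of enzyme families the
reachable compound set is the least fixed point of applying every reaction
whose enzyme is present and whose substrate is already reachable; end
products are reachable compounds with no applicable outgoing reaction.
Enzymes present but without any reachable substrate are reported as dead
ends — candidate annotation errors or incomplete (decayed) pathways.

Enzyme variants that represent alternative activities of homologous
proteins (3- vs 4-step desaturases, mono- vs bicyclases) are distinct
registry entries written ``Family:variant`` (e.g. ``CrtI:3-step``); a bare
family symbol selects the registry's declared default variant (logged at
debug level; a warning fires when no default is declared).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

logger = logging.getLogger(__name__)


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    family: str
    variant: str
    substrate: str
    product: str

    @property
    def key(self) -> Tuple[str, str]:
        return (self.family, self.variant)


@dataclass(frozen=True)
class EnzymeProfile:
    """One organism's enzyme-family complement plus its rhodopsin flag.

    Family entries may carry a variant tag (``CrtI:3-step``); a bare symbol
    means the registry default variant.
    """

    organism_id: str
    families: FrozenSet[str]
    rhodopsin: bool = False


@dataclass(frozen=True)
class PathwayCall:
    """Inferred biosynthetic capability of one organism."""

    organism_id: str
    reachable: FrozenSet[str]
    end_products: FrozenSet[str]
    dead_ends: FrozenSet[str]
    incomplete_products: FrozenSet[str]
    rhodopsin: bool


@dataclass
class PathwayGraph:
    """Compound/reaction graph supporting reachability queries."""

    compounds: Dict[str, str]
    reactions: List[Reaction]
    precursors: Set[str]
    default_variants: Dict[str, str] = field(default_factory=dict)
    intermediates: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            for compound in (rxn.substrate, rxn.product):
                if compound not in self.compounds:
                    raise RegistryError(
                        f"reaction {rxn.family}:{rxn.variant} references "
                        f"unknown compound {compound!r}"
                    )
        for precursor in self.precursors:
            if precursor not in self.compounds:
                raise RegistryError(f"unknown precursor compound {precursor!r}")
        for compound in self.intermediates:
            if compound not in self.compounds:
                raise RegistryError(f"unknown intermediate compound {compound!r}")
        seen = set()
        for rxn in self.reactions:
            triple = (rxn.family, rxn.variant, rxn.substrate)
            if (triple + (rxn.product,)) in seen:
                raise RegistryError(f"duplicate reaction {triple}")
            seen.add(triple + (rxn.product,))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        """Kahn topological sort over the compound graph; cycles are errors."""
        indeg = {c: 0 for c in self.compounds}
        out: Dict[str, List[str]] = {c: [] for c in self.compounds}
        for rxn in self.reactions:
            out[rxn.substrate].append(rxn.product)
            indeg[rxn.product] += 1
        queue = [c for c, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for nxt in out[node]:
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    queue.append(nxt)
        if seen != len(self.compounds):
            raise RegistryError("pathway graph contains a cycle")

    @property
    def families(self) -> Set[str]:
        return {r.family for r in self.reactions}

    @staticmethod
    def base_family(entry: str) -> str:
        return entry.split(":", 1)[0]

    def variants_of(self, family: str) -> List[str]:
        return sorted({r.variant for r in self.reactions if r.family == family})

    def resolve_entry(self, entry: str) -> Tuple[str, str]:
        """Resolve ``Family`` or ``Family:variant`` to a registry key."""
        if ":" in entry:
            family, variant = entry.split(":", 1)
        else:
            family, variant = entry, None
        if family not in self.families:
            raise RegistryError(f"unknown enzyme family {family!r}")
        variants = self.variants_of(family)
        if variant is None:
            if len(variants) == 1:
                variant = variants[0]
            elif family in self.default_variants:
                variant = self.default_variants[family]
                logger.debug(
                    "bare symbol %s resolved to declared default variant %s",
                    family,
                    variant,
                )
            else:
                variant = variants[0]
                logger.warning(
                    "bare symbol %s has variants %s and no declared default; "
                    "using %s",
                    family,
                    variants,
                    variant,
                )
        elif variant not in variants:
            raise RegistryError(f"unknown variant {variant!r} for family {family!r}")
        return family, variant


# ---------------------------------------------------------------------------
# Registry loading
# ---------------------------------------------------------------------------


def _graph_from_dict(data: dict) -> PathwayGraph:
    try:
        reactions = [
            Reaction(
                r["family"],
                r.get("variant", ""),
                r["substrate"],
                r["product"],
            )
            for r in data["reactions"]
        ]
        return PathwayGraph(
            compounds=dict(data["compounds"]),
            reactions=reactions,
            precursors=set(data.get("precursors", ["FPP", "GGPP"])),
            default_variants=dict(data.get("default_variants", {})),
            intermediates=set(data.get("intermediates", [])),
        )
    except KeyError as exc:
        raise RegistryError(f"registry is missing field {exc}") from exc


def _graph_from_tsv(path: Path) -> PathwayGraph:
    """TSV registries list reactions only (enzyme_family, variant, substrate,
    product); compounds are inferred and tagged 'unknown', precursors default
    to FPP/GGPP unless a compound named FPP/GGPP never occurs."""
    reactions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "enzyme_family":
                continue
            if len(parts) != 4:
                raise RegistryError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            reactions.append(Reaction(parts[0], parts[1], parts[2], parts[3]))
    compounds = {c: "unknown" for r in reactions for c in (r.substrate, r.product)}
    precursors = {p for p in ("FPP", "GGPP") if p in compounds}
    # without curation, any compound some reaction consumes counts as an
    # intermediate for the incomplete-pathway flag
    intermediates = {r.substrate for r in reactions} - precursors
    return PathwayGraph(
        compounds=compounds,
        reactions=reactions,
        precursors=precursors,
        intermediates=intermediates,
    )


def load_registry(source: Optional[str] = None) -> PathwayGraph:
    """Load a pathway registry; with no argument, the shipped default."""
    if source is None:
        text = (
            resources.files("carotevol.data")
            .joinpath("pathway_registry.json")
            .read_text()
        )
        return _graph_from_dict(json.loads(text))
    path = Path(source)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return _graph_from_dict(json.load(fh))
    return _graph_from_tsv(path)


# ---------------------------------------------------------------------------
# Reachability queries
# ---------------------------------------------------------------------------


def _resolved_keys(graph: PathwayGraph, families: Iterable[str]) -> Set[Tuple[str, str]]:
    return {graph.resolve_entry(entry) for entry in families}


def reachable_compounds(graph: PathwayGraph, families: Iterable[str]) -> Set[str]:
    """Least fixed point: precursors plus every product of a present-enzyme
    reaction whose substrate is reachable."""
    keys = _resolved_keys(graph, families)
    active = [r for r in graph.reactions if r.key in keys]
    reachable = set(graph.precursors)
    changed = True
    while changed:
        changed = False
        for rxn in active:
            if rxn.substrate in reachable and rxn.product not in reachable:
                reachable.add(rxn.product)
                changed = True
    return reachable


def end_products(graph: PathwayGraph, families: Iterable[str]) -> Set[str]:
    """Reachable compounds with no applicable outgoing reaction, excluding
    the a-priori precursors."""
    keys = _resolved_keys(graph, families)
    active = [r for r in graph.reactions if r.key in keys]
    reachable = reachable_compounds(graph, families)
    consumed = {r.substrate for r in active if r.substrate in reachable}
    return reachable - consumed - graph.precursors


def reconstruct_profile(profile: EnzymeProfile, graph: PathwayGraph) -> PathwayCall:
    """Full pathway call for one organism.

    ``dead_ends`` are enzyme families present without any reachable
    substrate; ``incomplete_products`` are end products the registry marks
    as pathway intermediates (the organism stops short, e.g. at
    cis-lycopene without the CrtH isomerase) — both mark pathways as
    candidates for annotation gaps or genomic decay.
    """
    keys = _resolved_keys(graph, profile.families)
    reachable = reachable_compounds(graph, profile.families)
    ends = end_products(graph, profile.families)
    dead = set()
    for entry in profile.families:
        key = graph.resolve_entry(entry)
        substrates = {r.substrate for r in graph.reactions if r.key == key}
        if not substrates & reachable:
            dead.add(entry)
    incomplete = {c for c in ends if c in graph.intermediates}
    return PathwayCall(
        organism_id=profile.organism_id,
        reachable=frozenset(reachable),
        end_products=frozenset(ends),
        dead_ends=frozenset(dead),
        incomplete_products=frozenset(incomplete),
        rhodopsin=profile.rhodopsin,
    )


# ---------------------------------------------------------------------------
# Profile / call TSV round-tripping
# ---------------------------------------------------------------------------


def read_profiles(path) -> List[EnzymeProfile]:
    """Read profiles TSV: organism_id, enzyme_families (semicolon-separated),
    rhodopsin (0/1)."""
    profiles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "organism_id":
                continue
            if len(parts) != 3:
                raise RegistryError(f"{path}:{lineno}: expected 3 columns")
            families = frozenset(f for f in parts[1].split(";") if f)
            profiles.append(
                EnzymeProfile(parts[0], families, rhodopsin=parts[2].strip() == "1")
            )
    return profiles


def write_profiles(profiles: Iterable[EnzymeProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("organism_id\tenzyme_families\trhodopsin\n")
        for p in profiles:
            fams = ";".join(sorted(p.families))
            fh.write(f"{p.organism_id}\t{fams}\t{1 if p.rhodopsin else 0}\n")


def write_calls(calls: Iterable[PathwayCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("organism_id\tend_products\tdead_ends\tincomplete\trhodopsin\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.organism_id,
                        ";".join(sorted(c.end_products)),
                        ";".join(sorted(c.dead_ends)),
                        ";".join(sorted(c.incomplete_products)),
                        "1" if c.rhodopsin else "0",
                    ]
                )
                + "\n"
            )
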