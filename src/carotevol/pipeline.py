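"""End-to-end orchestration: reconstruct -> annotate -> gainloss -> select -> recomb.

The pipeline reads standard flat formats (FASTA alignments, Newick trees
with an optional sidecar leaf->label TSV, profile TSVs, a registry file),
runs each configured stage, and writes a manifest recording input
checksums and every output produced, so a rerun with identical inputs and
seeds yields a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .alignment import CodonAlignment
from .annotate import assign_by_clade, fitch_gainloss
from .pathway import load_registry, read_profiles, reconstruct_profile, write_calls
from .recombination import recombination_screen
from .selection import run_selection_screen
from .trees import LabeledTree

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run (CLI flags override file values)."""

    out_dir: str
    alignment: Optional[str] = None
    tree: Optional[str] = None
    leaf_labels: Optional[str] = None
    profiles: Optional[str] = None
    registry: Optional[str] = None
    dn_min: float = 0.01
    ds_max: float = 1.5
    tau: float = 0.9
    min_seed_leaves: int = 2
    null_kappa: float = 1.0
    n_reps: int = 1000
    seed: int = 0
    genetic_code: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("alignment", "tree", "leaf_labels", "profiles", "registry"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"missing input file for {name}: {value}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_leaf_labels(path) -> Dict[str, str]:
    labels = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("leaf", "leaf_name"):
                continue
            if len(parts) != 2:
                raise PipelineError(f"{path}:{lineno}: expected 2 columns")
            labels[parts[0]] = parts[1]
    return labels


def write_leaf_labels(labels: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tlabel\n")
        for leaf in sorted(labels):
            fh.write(f"{leaf}\t{labels[leaf]}\n")


def run_all(config: PipelineConfig) -> Dict:
    """Run every stage with configured inputs; returns the manifest dict.

    Stage failures raise ``PipelineError`` after the manifest (with the
    outputs produced so far) has been written, so partial results survive.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs = {
        name: getattr(config, name)
        for name in ("alignment", "tree", "leaf_labels", "profiles", "registry")
        if getattr(config, name) is not None
    }
    manifest: Dict = {
        "inputs": {name: _sha256(path) for name, path in inputs.items()},
        "seed": config.seed,
        "outputs": [],
        "stages": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        manifest["outputs"].extend(str(p) for p in paths)

    def write_manifest() -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        graph = load_registry(config.registry)

        if config.profiles:
            logger.info("stage reconstruct: %s", config.profiles)
            profiles = read_profiles(config.profiles)
            calls = [reconstruct_profile(p, graph) for p in profiles]
            calls_path = out_dir / "pathway_calls.tsv"
            write_calls(calls, calls_path)
            record("reconstruct", calls_path)

        tree = None
        if config.tree:
            labels = read_leaf_labels(config.leaf_labels) if config.leaf_labels else {}
            tree = LabeledTree.read(config.tree, labels)

        if tree is not None and tree.leaf_labels:
            logger.info("stage annotate: %s", config.tree)
            annotation = assign_by_clade(tree, config.min_seed_leaves)
            ann_path = out_dir / "annotations.tsv"
            annotation.write_tsv(ann_path)
            record("annotate", ann_path)

        if tree is not None and config.profiles:
            logger.info("stage gainloss")
            profiles = read_profiles(config.profiles)
            by_leaf = {p.organism_id: p for p in profiles}
            families = sorted({f for p in profiles for f in p.families})
            gl_path = out_dir / "gainloss.tsv"
            with open(gl_path, "w") as fh:
                fh.write("family\tmin_changes\tbranch\tevent\n")
                for family in families:
                    presence = {
                        leaf: int(
                            leaf in by_leaf and family in by_leaf[leaf].families
                        )
                        for leaf in tree.leaf_names()
                    }
                    res = fitch_gainloss(tree, presence, family=family)
                    if not res.events:
                        fh.write(f"{family}\t{res.min_changes}\t-\t-\n")
                    for branch, kind in res.events:
                        fh.write(f"{family}\t{res.min_changes}\t{branch}\t{kind}\n")
            record("gainloss", gl_path)

        if config.alignment:
            logger.info("stage select: %s", config.alignment)
            alignment = CodonAlignment.read_fasta(config.alignment)
            table, report = run_selection_screen(
                alignment,
                dn_min=config.dn_min,
                ds_max=config.ds_max,
                tau=config.tau,
                table_id=config.genetic_code,
            )
            table_path = out_dir / "rate_table.tsv"
            table.write_tsv(table_path)
            report_path = out_dir / "selection_report.json"
            with open(report_path, "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            record("select", table_path, report_path)

        if config.alignment and tree is not None:
            logger.info("stage recomb")
            alignment = CodonAlignment.read_fasta(config.alignment)
            result = recombination_screen(
                alignment,
                tree,
                n_reps=config.n_reps,
                seed=config.seed,
                kappa=config.null_kappa,
            )
            recomb_path = out_dir / "recombination.json"
            with open(recomb_path, "w") as fh:
                json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            record("recomb", recomb_path)
    except Exception as exc:
        manifest["error"] = str(exc)
        write_manifest()
        raise PipelineError(f"pipeline stage failed: {exc}") from exc

    write_manifest()
    return manifest


def demo(out_dir: str, seed: int = 0, n_taxa: int = 8, codon_length: int = 200) -> Dict:
    """Generate a small synthetic dataset and run the full pipeline on it."""
    from .simulate import (
        SimulationParams,
        gen_enzyme_profiles,
        gen_tree,
        plant_elevated_lineage,
        sim_codon_alignment,
    )
    from .pathway import write_profiles

    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    tree = gen_tree(n_taxa, 0.1, seed=seed)
    planted_tree, omega_map, planted = plant_elevated_lineage(tree, seed=seed)
    params = SimulationParams(
        codon_length=codon_length,
        omega_map=omega_map,
        default_omega=None,
        seed=seed,
    )
    alignment = sim_codon_alignment(planted_tree, params)
    aln_path = inputs / "alignment.fasta"
    alignment.write_fasta(aln_path)

    tree_path = inputs / "tree.nwk"
    planted_tree.write(tree_path)

    leaves = sorted(planted_tree.leaf_names())
    labels = {leaves[0]: "CrtB", leaves[1]: "CrtB", leaves[-1]: "CrtM"}
    labels_path = inputs / "leaf_labels.tsv"
    write_leaf_labels(labels, labels_path)

    graph = load_registry()
    profiles, _ = gen_enzyme_profiles(
        planted_tree,
        graph,
        {"CrtB", "CrtI", "CrtY", "CrtZ", "CrtW"},
        p_loss=0.1,
        n_hgt=1,
        seed=seed,
    )
    profiles_path = inputs / "profiles.tsv"
    write_profiles(profiles.values(), profiles_path)

    config = PipelineConfig(
        out_dir=str(out / "results"),
        alignment=str(aln_path),
        tree=str(tree_path),
        leaf_labels=str(labels_path),
        profiles=str(profiles_path),
        n_reps=200,
        seed=seed,
    )
    return run_all(config)
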