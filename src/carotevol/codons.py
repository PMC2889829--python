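"""Genetic-code utilities shared by the selection screen and the simulator."""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, Tuple

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> Dict[str, str]:
    """Codon -> amino acid mapping, with stop codons mapped to ``*``."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 1) -> Tuple[str, ...]:
    code = genetic_code(table_id)
    return tuple(sorted(c for c, aa in code.items() if aa != "*"))


def is_stop(codon: str, table_id: int = 1) -> bool:
    return genetic_code(table_id).get(codon) == "*"


def single_neighbors(codon: str) -> list[Tuple[int, str]]:
    """All nine single-nucleotide mutants as ``(position, new codon)``."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append((pos, codon[:pos] + nt + codon[pos + 1 :]))
    return out
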