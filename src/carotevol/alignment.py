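"""In-frame codon alignments and FASTA round-tripping."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGT-N")


class AlignmentError(ValueError):
    """Raised for ragged, out-of-frame or otherwise invalid alignments."""


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length, in-frame nucleotide sequences with identifiers.

    Sequences are upper-case strings over ``A/C/G/T/-/N`` whose common
    length is a multiple of three, so column ``3k..3k+2`` is codon ``k``.
    """

    ids: Tuple[str, ...]
    sequences: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise AlignmentError("alignment length is not a multiple of 3")
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(f"invalid characters in {sid}: {sorted(bad)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "CodonAlignment":
        ids, seqs = [], []
        for sid, seq in pairs:
            ids.append(sid)
            seqs.append(seq.upper())
        return cls(tuple(ids), tuple(seqs))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def sequence(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]

    def codons(self, sid: str) -> List[str]:
        seq = self.sequence(sid)
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def subset(self, keep_ids: Sequence[str]) -> "CodonAlignment":
        return CodonAlignment.from_pairs((sid, self.sequence(sid)) for sid in keep_ids)

    def concat(self, other: "CodonAlignment") -> "CodonAlignment":
        if self.ids != other.ids:
            raise AlignmentError("alignments must share an identical id order")
        return CodonAlignment(
            self.ids,
            tuple(a + b for a, b in zip(self.sequences, other.sequences)),
        )

    # -- FASTA ---------------------------------------------------------

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no FASTA records in {path}")
        return cls.from_pairs((r.id, str(r.seq)) for r in records)


def read_protein_fasta(path) -> dict[str, str]:
    """Read an aligned protein FASTA into an ``id -> sequence`` mapping."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return {r.id: str(r.seq).upper() for r in records}
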