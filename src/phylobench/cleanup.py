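"""Orthologous-group hygiene filters applied before tree building/scoring.

Three rules keep low-information sequences from adding noise:

* sequences with more than 5% unknown residues (amino acids) or unknown
  codons are dropped — the threshold is a strict ``>``, exactly 5% is kept;
* of identical sequences only the first copy (input order) is kept, since a
  method has no signal to place identical sequences relative to each other;
* a group is used only if at least 4 sequences survive (2 or 3 leaves can
  never show different unrooted topologies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

from Bio import SeqIO

__all__ = [
    "SequenceGroup",
    "SequenceRecord",
    "RemovalLogEntry",
    "FilterResult",
    "unknown_fraction",
    "filter_group",
    "read_fasta_group",
    "write_fasta_group",
    "write_removal_log",
]

MIN_GROUP_SIZE = 4
UNKNOWN_THRESHOLD = 0.05

_AA_UNKNOWN = {"X"}
# Bases that are not a definite A/C/G/T make the whole codon unknown.
_DNA_CERTAIN = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SequenceRecord:
    species: str
    sequence: str
    alphabet: str = "aa"  # "aa" | "codon" | "dna"


@dataclass(frozen=True)
class SequenceGroup:
    og_id: str
    records: Tuple[SequenceRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        species = [r.species for r in self.records]
        if len(set(species)) != len(species):
            dup = sorted({s for s in species if species.count(s) > 1})
            raise ValueError(f"duplicate species in group {self.og_id}: {dup}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class RemovalLogEntry:
    og_id: str
    species: str
    reason: str  # "unknown_fraction" | "duplicate"


@dataclass(frozen=True)
class FilterResult:
    group: SequenceGroup
    removed: Tuple[RemovalLogEntry, ...]
    accepted: bool  # >= MIN_GROUP_SIZE survivors


def unknown_fraction(sequence: str, alphabet: str = "aa") -> float:
    """Fraction of unknown symbols in a sequence.

    For amino acids an unknown symbol is ``X``.  For the codon alphabet the
    sequence is read in triplets and a codon counts as unknown if any of its
    three bases is not a definite A/C/G/T (N, X or an IUPAC ambiguity code).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if alphabet == "aa":
        return sum(1 for c in seq if c in _AA_UNKNOWN) / len(seq)
    if alphabet in ("codon", "dna"):
        if alphabet == "codon" and len(seq) % 3 != 0:
            raise ValueError(
                f"codon sequence length {len(seq)} is not a multiple of 3"
            )
        if alphabet == "dna":
            return sum(1 for c in seq if c not in _DNA_CERTAIN) / len(seq)
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        bad = sum(1 for c in codons if any(b not in _DNA_CERTAIN for b in c))
        return bad / len(codons)
    raise ValueError(f"unknown alphabet {alphabet!r}")


def filter_group(group: SequenceGroup) -> FilterResult:
    """Apply the unknown-fraction, duplicate and minimum-size rules.

    The unknown filter runs first, then exact-duplicate removal keeping the
    first copy in input order.  Rejection (fewer than 4 survivors) is a
    normal outcome flagged on the result, not an error.  Idempotent.
    """
    removed: List[RemovalLogEntry] = []
    survivors: List[SequenceRecord] = []
    for rec in group.records:
        if unknown_fraction(rec.sequence, rec.alphabet) > UNKNOWN_THRESHOLD:
            removed.append(
                RemovalLogEntry(group.og_id, rec.species, "unknown_fraction")
            )
        else:
            survivors.append(rec)
    seen: dict = {}
    deduped: List[SequenceRecord] = []
    for rec in survivors:
        key = rec.sequence.upper()
        if key in seen:
            removed.append(RemovalLogEntry(group.og_id, rec.species, "duplicate"))
        else:
            seen[key] = rec.species
            deduped.append(rec)
    out = replace(group, records=tuple(deduped))
    return FilterResult(out, tuple(removed), accepted=len(deduped) >= MIN_GROUP_SIZE)


def read_fasta_group(path, og_id: str, alphabet: str = "aa") -> SequenceGroup:
    """Read one orthologous group from FASTA; record ids are species labels."""
    records = [
        SequenceRecord(rec.id, str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return SequenceGroup(og_id, tuple(records))


def write_fasta_group(group: SequenceGroup, path) -> None:
    with open(path, "w") as fh:
        for rec in group.records:
            fh.write(f">{rec.species}\n{rec.sequence}\n")


def write_removal_log(entries, path) -> None:
    """Removal log as TSV: og_id, species, reason."""
    with open(path, "w") as fh:
        fh.write("og_id\tspecies\treason\n")
        for e in entries:
            fh.write(f"{e.og_id}\t{e.species}\t{e.reason}\n")
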