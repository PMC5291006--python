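"""Sequence and call-table I/O.

Reads reference mtDNA sequences from FASTA, reads per-subject base-call
tables (a minimal TSV stand-in for resequencing-array "SNP View" exports),
and reconstructs a subject's possibly ambiguous mtDNA sequence by applying
the calls to the reference.

Homoplasmic mutations are plain base substitutions; heteroplasmic mutations
(a mixture of molecules carrying different alleles) are encoded as a single
degenerate IUPAC symbol covering the observed alleles.  Per-allele fractions
are not modelled: every allele under a degenerate symbol is weighted equally
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes (lowercase) mapped to the set of pure bases each covers.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "a": frozenset("a"),
    "c": frozenset("c"),
    "g": frozenset("g"),
    "t": frozenset("t"),
    "r": frozenset("ag"),
    "y": frozenset("ct"),
    "s": frozenset("cg"),
    "w": frozenset("at"),
    "k": frozenset("gt"),
    "m": frozenset("ac"),
    "b": frozenset("cgt"),
    "d": frozenset("agt"),
    "h": frozenset("act"),
    "v": frozenset("acg"),
    "n": frozenset("acgt"),
}

PURE_BASES = ("a", "c", "g", "t")
IUPAC_ALPHABET = frozenset(IUPAC_CODES)
DEGENERATE_SYMBOLS = IUPAC_ALPHABET - frozenset(PURE_BASES)

#: Reverse lookup: frozenset of bases -> IUPAC symbol.
BASES_TO_SYMBOL: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}


class SequenceError(ValueError):
    """Raised for malformed sequences or call tables."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over the 15-letter lowercase IUPAC alphabet.

    Degenerate symbols represent heteroplasmic positions (or reference
    placeholders such as the rCRS 'n'), each standing for an equal-weight
    mixture of the pure bases it covers.
    """

    symbols: str
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise SequenceError("sequence must have length >= 1")
        for i, ch in enumerate(self.symbols):
            if ch not in IUPAC_ALPHABET:
                raise SequenceError(
                    f"illegal symbol {ch!r} at position {i + 1} "
                    f"(1-based) in sequence {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]


@dataclass(frozen=True)
class Call:
    """One base call at a 1-based reference position."""

    position: int
    ref_base: str
    call: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SequenceError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in PURE_BASES:
            raise SequenceError(
                f"ref_base must be one of a/c/g/t, got {self.ref_base!r} "
                f"at position {self.position}"
            )
        if self.call not in IUPAC_ALPHABET:
            raise SequenceError(
                f"call symbol {self.call!r} at position {self.position} "
                "is not an IUPAC nucleotide code"
            )

    @property
    def is_identity(self) -> bool:
        return self.call == self.ref_base

    @property
    def is_homoplasmic(self) -> bool:
        return self.call in PURE_BASES and self.call != self.ref_base

    @property
    def is_heteroplasmic(self) -> bool:
        return self.call in DEGENERATE_SYMBOLS


@dataclass
class CallTable:
    """Per-position base calls against a reference sequence.

    Positions are unique and 1-based (mtDNA nucleotide-position convention).
    Identity rows (call equal to the reference base) are permitted and have
    no effect when applied.
    """

    calls: list[Call] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[int, Call] = {}
        for c in self.calls:
            if c.position in seen:
                raise SequenceError(f"duplicate position {c.position} in call table")
            seen[c.position] = c
        self.calls = sorted(self.calls, key=lambda c: c.position)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def homoplasmic(self) -> list[Call]:
        return [c for c in self.calls if c.is_homoplasmic]

    @property
    def heteroplasmic(self) -> list[Call]:
        return [c for c in self.calls if c.is_heteroplasmic]

    def validate_against(self, reference: NucleotideSequence) -> None:
        """Check every row against the reference; report all problems at once."""
        problems = []
        for c in self.calls:
            if c.position > len(reference):
                problems.append(
                    f"position {c.position} beyond reference length {len(reference)}"
                )
            elif reference.symbols[c.position - 1] != c.ref_base:
                problems.append(
                    f"ref_base mismatch at position {c.position}: table says "
                    f"{c.ref_base!r}, reference has "
                    f"{reference.symbols[c.position - 1]!r}"
                )
        if problems:
            raise SequenceError(
                "call table rejected against reference:\n  " + "\n  ".join(problems)
            )


def read_fasta(path: str | Path) -> NucleotideSequence:
    """Read a single-record FASTA file.

    Symbols are lowercased and RNA 'u' is mapped to 't'.  If the file holds
    more than one record the first is used, with a warning.
    """
    path = Path(path)
    records = list(_BioSeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA record found in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    rec = records[0]
    symbols = str(rec.seq).lower().replace("u", "t")
    if not symbols:
        raise SequenceError(f"empty record {rec.id!r} in {path}")
    return NucleotideSequence(symbols=symbols, name=rec.id)


def write_fasta(seq: NucleotideSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(seq.symbols), id=seq.name or "sequence", description="")
    _BioSeqIO.write([rec], str(Path(path)), "fasta")


_CALL_COLUMNS = ["position", "ref_base", "call"]


def read_call_table(path: str | Path) -> CallTable:
    """Read a call table from TSV with header ``position  ref_base  call``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _CALL_COLUMNS:
        raise SequenceError(
            f"call table {path} must have header {_CALL_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    calls = []
    for i, row in df.iterrows():
        try:
            pos = int(row["position"])
        except (TypeError, ValueError):
            raise SequenceError(
                f"malformed position {row['position']!r} on line {i + 2} of {path}"
            ) from None
        calls.append(
            Call(position=pos, ref_base=str(row["ref_base"]).lower(),
                 call=str(row["call"]).lower())
        )
    return CallTable(calls)


def write_call_table(table: CallTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.position, c.ref_base, c.call) for c in table],
        columns=_CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def apply_calls(reference: NucleotideSequence, calls: CallTable) -> NucleotideSequence:
    """Return the reference with each called position's symbol replaced.

    Length-preserving; identity rows are no-ops.  Any ref_base mismatch
    aborts with a report of all mismatches.
    """
    calls.validate_against(reference)
    out = list(reference.symbols)
    for c in calls:
        out[c.position - 1] = c.call
    return NucleotideSequence(
        symbols="".join(out),
        name=f"{reference.name}+calls" if reference.name else "mutated",
    )
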