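"""Weighted Chaos Game Representation (CGR) of nucleotide sequences.

A CGR matrix at frame length L is a 2^L x 2^L table of length-L substring
frequencies arranged by recursive quadrant addressing: the first symbol of a
substring selects the coarsest quadrant, the next symbol the quadrant within
it, and so on.  With the base layout

    M1 = [[a, c],
          [g, t]]

(a top-left, c top-right, g bottom-left, t bottom-right) each substring s of
length L maps to a well-defined cell p(s), and the CGR matrix accumulates one
count per sliding window of the sequence.

Degenerate IUPAC symbols — the encoding of heteroplasmic mutations — are
handled by expanding every window that contains them into the full set of
pure substrings it covers, each contributing a fractional weight 1/(number
of expansions).  Total matrix mass therefore always equals the number of
windows, len(S) - L + 1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    Call,
    CallTable,
    IUPAC_CODES,
    NucleotideSequence,
    PURE_BASES,
    SequenceError,
)

# Row/column bit per base under the M1 = [[a,c],[g,t]] layout (row 0 = top).
_BASE_ROW = {"a": 0, "c": 0, "g": 1, "t": 1}
_BASE_COL = {"a": 0, "c": 1, "g": 0, "t": 1}

#: Practical frame-length cap; resolution degrades well before this for mtDNA.
MAX_FRAME_LENGTH = 12

#: Cap on the number of pure strings a single window may expand into (4**6).
DEFAULT_MAX_EXPANSIONS = 4096


@dataclass(frozen=True)
class CGRMatrix:
    """A 2^L x 2^L matrix of weighted substring frequencies."""

    values: np.ndarray
    frame_length: int
    source_name: str = ""

    def __post_init__(self) -> None:
        n = 2 ** self.frame_length
        if self.values.shape != (n, n):
            raise ValueError(
                f"CGR matrix for L={self.frame_length} must be {n}x{n}, "
                f"got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("CGR matrix entries must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


@dataclass
class MutationReport:
    """Per-sequence composition and mutation summary.

    Base counts are fractional when the sequence contains degenerate
    symbols: each ambiguous position contributes 1/degeneracy to every base
    it covers, so the counts always sum to the sequence length.
    """

    counts: dict[str, float]
    sequence_length: int
    homoplasmic: list[tuple[int, str, str]] = field(default_factory=list)
    heteroplasmic: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_homoplasmic(self) -> int:
        return len(self.homoplasmic)

    @property
    def n_heteroplasmic(self) -> int:
        return len(self.heteroplasmic)

    def to_dict(self) -> dict:
        return {
            "counts": {b: self.counts[b] for b in PURE_BASES},
            "sequence_length": self.sequence_length,
            "n_homoplasmic": self.n_homoplasmic,
            "n_heteroplasmic": self.n_heteroplasmic,
            "homoplasmic": [list(t) for t in self.homoplasmic],
            "heteroplasmic": [list(t) for t in self.heteroplasmic],
        }


def expand_ambiguous(substring: str) -> list[tuple[str, float]]:
    """Expand a substring with degenerate symbols into pure strings.

    Returns the Cartesian product of the base sets covered by each symbol,
    each pure string carrying weight 1/(number of strings); e.g. "tamcg"
    expands to [("taacg", 0.5), ("taccg", 0.5)].
    """
    choices = []
    for i, ch in enumerate(substring):
        bases = IUPAC_CODES.get(ch)
        if bases is None:
            raise SequenceError(
                f"illegal symbol {ch!r} at position {i + 1} of substring"
            )
        choices.append(sorted(bases))
    n = 1
    for c in choices:
        n *= len(c)
    w = 1.0 / n
    return [("".join(t), w) for t in itertools.product(*choices)]


def substring_position(s: str) -> tuple[int, int]:
    """Map a pure substring to its (row, col) cell in the 2^L x 2^L matrix.

    Symbol i (1-based, leftmost coarsest) contributes its row/column bit at
    weight 2^(L-i): row = sum_i r(s_i) 2^(L-i), col = sum_i c(s_i) 2^(L-i).
    """
    row = col = 0
    for ch in s:
        if ch not in _BASE_ROW:
            raise SequenceError(
                f"degenerate symbol {ch!r} must be expanded before positioning"
            )
        row = (row << 1) | _BASE_ROW[ch]
        col = (col << 1) | _BASE_COL[ch]
    return row, col


def cgr_matrix(
    seq: NucleotideSequence,
    L: int,
    *,
    circular: bool = False,
    max_expansions: int = DEFAULT_MAX_EXPANSIONS,
) -> CGRMatrix:
    """Build the weighted CGR matrix of ``seq`` at frame length ``L``.

    Every window of length L (offsets 0 .. len-L; with ``circular`` the
    wrap-around windows are added too) contributes total weight 1, split
    uniformly over its pure expansions when it contains degenerate symbols.
    """
    if L < 1 or L > MAX_FRAME_LENGTH:
        raise ValueError(f"frame length must be in [1, {MAX_FRAME_LENGTH}], got {L}")
    if L > len(seq):
        raise ValueError(f"frame length {L} exceeds sequence length {len(seq)}")

    symbols = seq.symbols + (seq.symbols[: L - 1] if circular and L > 1 else "")
    n_windows = len(symbols) - L + 1
    size = 2 ** L
    mat = np.zeros((size, size), dtype=float)

    # Vectorized path for pure windows: per-symbol row/col bits combined into
    # cell indices by a sliding dot product with powers of two.
    rbits = np.full(len(symbols), -1, dtype=np.int64)
    cbits = np.full(len(symbols), -1, dtype=np.int64)
    for base, rb in _BASE_ROW.items():
        idx = np.frombuffer(symbols.encode(), dtype=np.uint8) == ord(base)
        rbits[idx] = rb
        cbits[idx] = _BASE_COL[base]

    win_r = np.lib.stride_tricks.sliding_window_view(rbits, L)
    win_c = np.lib.stride_tricks.sliding_window_view(cbits, L)
    pure = (win_r >= 0).all(axis=1)
    pow2 = 1 << np.arange(L - 1, -1, -1, dtype=np.int64)
    rows = win_r[pure] @ pow2
    cols = win_c[pure] @ pow2
    np.add.at(mat, (rows, cols), 1.0)

    for off in np.flatnonzero(~pure):
        window = symbols[off : off + L]
        degeneracy = 1
        for ch in window:
            degeneracy *= len(IUPAC_CODES[ch])
        if degeneracy > max_expansions:
            raise SequenceError(
                f"window {window!r} at offset {off} expands into {degeneracy} "
                f"strings, above the cap of {max_expansions}"
            )
        for pure_s, w in expand_ambiguous(window):
            r, c = substring_position(pure_s)
            mat[r, c] += w

    assert abs(mat.sum() - n_windows) < 1e-6
    return CGRMatrix(values=mat, frame_length=L, source_name=seq.name)


def mutation_report(
    reference: NucleotideSequence,
    calls: CallTable,
    mutated: NucleotideSequence,
) -> MutationReport:
    """Summarise composition and mutation load of a reconstructed sequence."""
    counts = {b: 0.0 for b in PURE_BASES}
    for ch in mutated.symbols:
        bases = IUPAC_CODES[ch]
        w = 1.0 / len(bases)
        for b in bases:
            counts[b] += w
    return MutationReport(
        counts=counts,
        sequence_length=len(mutated),
        homoplasmic=[(c.position, c.ref_base, c.call) for c in calls.homoplasmic],
        heteroplasmic=[(c.position, c.ref_base, c.call) for c in calls.heteroplasmic],
    )


# ---------------------------------------------------------------------------
# Matrix / report serialisation

def write_matrix_csv(m: CGRMatrix, path: str | Path) -> None:
    """Dense CSV, row-major, row 0 = top."""
    np.savetxt(path, m.values, delimiter=",", fmt="%.12g")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_pgm(values: np.ndarray, path: str | Path, maxval: int = 65535) -> None:
    """ASCII (P2) PGM, linearly scaled so the matrix maximum maps to maxval."""
    vmax = values.max()
    scaled = np.zeros_like(values, dtype=np.int64) if vmax == 0 else np.round(
        values / vmax * maxval
    ).astype(np.int64)
    h, w = values.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{w} {h}\n{maxval}\n")
        for row in scaled:
            fh.write(" ".join(str(v) for v in row) + "\n")


def read_pgm(path: str | Path) -> np.ndarray:
    """Read an ASCII P2 PGM into floats in [0, maxval]."""
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise ValueError(f"{path} is not an ASCII (P2) PGM file")
    w, h, _maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
    data = np.array([float(t) for t in tokens[4 : 4 + w * h]])
    if data.size != w * h:
        raise ValueError(f"{path}: expected {w * h} pixels, found {data.size}")
    return data.reshape(h, w)


def write_report_json(report: MutationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
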