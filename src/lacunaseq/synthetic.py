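"""Synthetic fixtures: sequences, mutation tables, fractal and random images.

Everything the pipeline consumes can be generated here deterministically
from a seed: random nucleotide sequences with configurable base composition
(optionally with forbidden dinucleotides, e.g. CpG depletion, which gives a
human-mtDNA-like Sierpinski pattern in the CGR), injected homoplasmic and
heteroplasmic calls, deterministic fractal images (Sierpinski carpet) and
Bernoulli random binary images with a known analytic lacunarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import BASES_TO_SYMBOL, Call, CallTable, NucleotideSequence, PURE_BASES

#: Human mtDNA reference (rCRS) base composition as generator probabilities:
#: A/C-rich, G-poor (A=5124, C=5181, G=2169, T=4094 of 16569).
MTDNA_BASE_PROBS = (0.30926, 0.31270, 0.13091, 0.24713)

MTDNA_LENGTH = 16569


@dataclass(frozen=True)
class SequenceSimSpec:
    """Parameters of an i.i.d. random sequence with dinucleotide constraints."""

    length: int
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    forbidden_dinucleotides: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        p = np.asarray(self.base_probs, dtype=float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"base_probs must be 4 non-negative values summing to 1, got {self.base_probs}")
        for d in self.forbidden_dinucleotides:
            if len(d) != 2 or any(ch not in PURE_BASES for ch in d):
                raise ValueError(f"forbidden dinucleotide {d!r} must be two pure bases")


@dataclass(frozen=True)
class MutationSimSpec:
    """Numbers of homoplasmic and heteroplasmic calls to inject.

    Defaults are on the scale observed for AD mtDNA sequences (14 homoplasmic,
    3 heteroplasmic); the control-like scale is 18/5.
    """

    n_homoplasmic: int = 14
    n_heteroplasmic: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_homoplasmic < 0 or self.n_heteroplasmic < 0:
            raise ValueError("mutation counts must be non-negative")


#: Mutation-load presets matching the observed cohort scales.
AD_LIKE_MUTATIONS = MutationSimSpec(n_homoplasmic=14, n_heteroplasmic=3)
CONTROL_LIKE_MUTATIONS = MutationSimSpec(n_homoplasmic=18, n_heteroplasmic=5)


def random_sequence(spec: SequenceSimSpec) -> NucleotideSequence:
    """Draw an i.i.d. sequence from base_probs, rejecting forbidden dinucleotides.

    A symbol that would complete a forbidden dinucleotide is redrawn, so the
    output contains no forbidden pair; deterministic under the seed.
    """
    probs = np.asarray(spec.base_probs, dtype=float)
    allowed = probs > 0
    forbidden = {d for d in spec.forbidden_dinucleotides}
    # infeasible iff some drawable base forbids every drawable successor
    for i, x in enumerate(PURE_BASES):
        if allowed[i] and all(
            (not allowed[j]) or (x + y in forbidden) for j, y in enumerate(PURE_BASES)
        ):
            raise ValueError(f"no allowed successor for base {x!r}: constraints infeasible")

    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(4, size=spec.length, p=probs)
    if forbidden:
        for _ in range(10 * spec.length + 100):
            pairs = np.array(
                [PURE_BASES[a] + PURE_BASES[b] in forbidden
                 for a, b in zip(draws[:-1], draws[1:])]
            )
            bad = np.flatnonzero(pairs)
            if bad.size == 0:
                break
            draws[bad + 1] = rng.choice(4, size=bad.size, p=probs)
        else:  # pragma: no cover - bounded by the feasibility check above
            raise RuntimeError("rejection sampling failed to converge")
    symbols = "".join(PURE_BASES[i] for i in draws)
    return NucleotideSequence(symbols=symbols, name=f"sim-seed{spec.seed}")


def mtdna_like_sequence(seed: int = 0, length: int = MTDNA_LENGTH) -> NucleotideSequence:
    """A CpG-depleted random sequence with human-mtDNA base composition."""
    return random_sequence(
        SequenceSimSpec(
            length=length,
            base_probs=MTDNA_BASE_PROBS,
            forbidden_dinucleotides=("cg",),
            seed=seed,
        )
    )


def inject_mutations(seq: NucleotideSequence, spec: MutationSimSpec) -> CallTable:
    """Generate a random call table against ``seq``.

    Homoplasmic rows replace the reference base with a uniformly chosen
    different base; heteroplasmic rows use the 2-fold IUPAC symbol combining
    the reference base with one uniformly chosen other base (heteroplasmy is
    a mixture of reference and mutant molecules).  Positions are distinct,
    drawn from the pure-base positions of the sequence, and returned sorted.
    """
    total = spec.n_homoplasmic + spec.n_heteroplasmic
    eligible = np.array([i for i, ch in enumerate(seq.symbols) if ch in PURE_BASES])
    if total > eligible.size:
        raise ValueError(
            f"{total} mutations requested but only {eligible.size} eligible positions"
        )
    rng = np.random.default_rng(spec.seed)
    positions = rng.choice(eligible, size=total, replace=False)
    calls = []
    for j, pos0 in enumerate(positions):
        ref = seq.symbols[pos0]
        others = [b for b in PURE_BASES if b != ref]
        other = others[rng.integers(3)]
        if j < spec.n_homoplasmic:
            call = other
        else:
            call = BASES_TO_SYMBOL[frozenset({ref, other})]
        calls.append(Call(position=int(pos0) + 1, ref_base=ref, call=call))
    return CallTable(calls)


def sierpinski_carpet(depth: int) -> np.ndarray:
    """Binary 3^depth x 3^depth Sierpinski carpet (center ninth removed recursively).

    Total mass is 8**depth.
    """
    if not 1 <= depth <= 6:
        raise ValueError(f"depth must be in [1, 6], got {depth}")
    cell = np.ones((3, 3))
    cell[1, 1] = 0
    img = np.ones((1, 1))
    for _ in range(depth):
        img = np.kron(img, cell)
    return img


def bernoulli_image(h: int, w: int, p: float, seed: int = 0) -> np.ndarray:
    """i.i.d. binary image with P(pixel = 1) = p; deterministic under seed."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    rng = np.random.default_rng(seed)
    return (rng.random((h, w)) < p).astype(float)
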