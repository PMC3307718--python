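"""Protein sequences for the coarse-grained lattice model.

A chain is an ordered list of one-letter residue codes. Residue numbering is
1-based everywhere (``seq[36] == 'R'`` for the bundled histone H2AX), matching
the convention used when individual residues are discussed (36R, 91D, ...).

Residues are grouped into three coarse classes — hydrophobic, polar and
electrostatic — used only for reporting and for aggregate mobility/energy
statistics; the interaction model itself is fully pairwise via the contact
matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard one-letter amino-acid codes, alphabetical."""

#: residue -> integer index into the alphabet (and the contact matrix)
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

HYDROPHOBIC = frozenset("AVLIPFMW")
POLAR = frozenset("STNQHYCG")
ELECTROSTATIC = frozenset("DEKR")

DEFAULT_CLASSES: Mapping[str, str] = {
    **{a: "hydrophobic" for a in HYDROPHOBIC},
    **{a: "polar" for a in POLAR},
    **{a: "electrostatic" for a in ELECTROSTATIC},
}


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


def classify(residue: str, classes: Mapping[str, str] | None = None) -> str:
    """Return the coarse class of a residue.

    The default grouping puts D, E, K, R in ``electrostatic``; S, T, N, Q, H,
    Y, C, G in ``polar``; and A, V, L, I, P, F, M, W in ``hydrophobic``. Only
    the electrostatic set and the polar membership of Q and N are dictated by
    the physics we reproduce; the remainder is a common coarse-grained
    convention and may be overridden via *classes*.
    """
    residue = residue.upper()
    if residue not in AA_INDEX:
        raise SequenceError(f"unknown residue code {residue!r}")
    return (classes or DEFAULT_CLASSES)[residue]


@dataclass(frozen=True)
class ProteinSequence:
    """An ordered, validated amino-acid sequence with 1-based indexing."""

    residues: str
    name: str = "chain"

    def __post_init__(self) -> None:
        norm = self.residues.upper()
        if len(norm) < 2:
            raise SequenceError("a chain needs at least 2 residues")
        for pos, ch in enumerate(norm, start=1):
            if ch not in AA_INDEX:
                raise SequenceError(
                    f"invalid residue {ch!r} at position {pos} of {self.name!r}"
                )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """1-based residue access: ``seq[1]`` is the N-terminal residue."""
        if not 1 <= pos <= len(self):
            raise IndexError(f"residue index {pos} outside 1..{len(self)}")
        return self.residues[pos - 1]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues

    def indices(self) -> np.ndarray:
        """Residues as integer indices into :data:`AMINO_ACIDS` (shape (N,))."""
        return np.fromiter((AA_INDEX[a] for a in self.residues), dtype=np.int64)

    def classes(self, classes: Mapping[str, str] | None = None) -> list[str]:
        """Coarse class of every residue, in chain order."""
        return [classify(a, classes) for a in self.residues]

    def class_counts(self, classes: Mapping[str, str] | None = None) -> dict[str, int]:
        counts = {"hydrophobic": 0, "polar": 0, "electrostatic": 0}
        for c in self.classes(classes):
            counts[c] += 1
        return counts


def parse_one_letter(text: str, name: str = "chain") -> ProteinSequence:
    """Parse raw one-letter text or single-record FASTA into a sequence.

    Whitespace is ignored; lowercase letters are normalized to uppercase. If
    the text starts with ``>`` it is treated as FASTA and must contain exactly
    one record (this is a single-chain simulator).
    """
    stripped = text.lstrip()
    if stripped.startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise SequenceError(
                f"expected exactly one FASTA record, found {len(records)}"
            )
        return ProteinSequence(str(records[0].seq), name=records[0].id or name)
    letters = "".join(text.split())
    return ProteinSequence(letters, name=name)


def read_sequence(path) -> ProteinSequence:
    """Read a sequence file (FASTA or raw one-letter text)."""
    with open(path) as fh:
        return parse_one_letter(fh.read(), name=str(path))


def h2ax_sequence() -> ProteinSequence:
    """The bundled 143-residue histone H2AX reference sequence."""
    data = resources.files("bfmprotein.data").joinpath("h2ax.fasta").read_text()
    seq = parse_one_letter(data)
    return ProteinSequence(seq.residues, name="H2AX")


def random_sequence(n: int, seed: int, name: str | None = None) -> ProteinSequence:
    """Uniform random sequence of length *n*, deterministic for a given seed."""
    if n < 2:
        raise SequenceError("n must be >= 2")
    rng = np.random.default_rng(seed)
    letters = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    return ProteinSequence(letters, name=name or f"random-{n}-{seed}")
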