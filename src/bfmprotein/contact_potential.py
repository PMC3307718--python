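"""Knowledge-based residue–residue contact energies and the pair potential.

The interaction between two residues a distance ``r`` apart (in lattice
units) is a truncated generalized Lennard-Jones form

    u(r) = |eps| (sigma/r)^12 + eps (sigma/r)^6       for r < r_cut,
    u(r) = 0                                          otherwise,

with ``eps`` the residue-pair contact energy. The core is repulsive for any
nonzero coupling; an attractive pair (eps < 0) has its minimum at
``r = sigma * 2^(1/6)`` with depth ``eps / 4``. The cutoff is a sharp
truncation without an energy shift. With the default ``sigma = 1`` and
``r_cut = sqrt(8)`` only the inter-monomer lattice distances 2, sqrt(5) and
sqrt(6) ever fall inside the cutoff (sum-of-three-squares: 7 is not
representable), so on the lattice the potential takes exactly three nonzero
values per pair.

The packaged 20x20 table is a transcription of the classic Miyazawa–Jernigan
statistical contact energies e_ij (RT units), derived from residue–residue
contact counts over a large PDB ensemble. Two variants are exposed:

``contact``
    the raw table e_ij; every pair is attractive, dominated by
    hydrophobic–hydrophobic contacts.
``mixing`` (default)
    e'_ij = e_ij - (e_ii + e_jj)/2, the mixing/segregation part of the same
    table. Here the deepest wells are the oppositely-charged pairs (K–E,
    R–E, K–D, R–D), like-pair entries vanish, and hydrophobic–charged pairs
    are mildly repulsive — the sign structure (attractive and repulsive
    couplings, electrostatic residues with the largest well depth) that the
    histone study relies on.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence import AMINO_ACIDS, AA_INDEX

_PACKAGED = "mj_contact_energies.csv"
_SYMMETRY_TOL = 1e-9

VARIANTS = ("contact", "mixing")


class ContactMatrixError(ValueError):
    """Raised when a contact-energy table cannot be loaded."""


@dataclass(frozen=True)
class PotentialParams:
    """Lennard-Jones geometry: ``sigma`` and cutoff, in lattice units."""

    sigma: float = 1.0
    r_cut: float = float(np.sqrt(8.0))

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.r_cut <= self.sigma:
            raise ValueError("r_cut must exceed sigma")


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric 20x20 residue-pair energies over the standard alphabet."""

    entries: np.ndarray  # (20, 20), alphabetical AMINO_ACIDS order
    variant: str = "contact"
    checksum: str = ""  # sha256 of the source table text

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (20, 20):
            raise ContactMatrixError(f"expected 20x20 matrix, got {e.shape}")
        if not np.isfinite(e).all():
            raise ContactMatrixError("matrix contains non-finite entries")
        if np.abs(e - e.T).max() > _SYMMETRY_TOL:
            raise ContactMatrixError("matrix is not symmetric")
        object.__setattr__(self, "entries", e)

    def epsilon(self, a: str, b: str) -> float:
        """Pair energy eps(a, b); symmetric in its arguments."""
        return float(self.entries[AA_INDEX[a.upper()], AA_INDEX[b.upper()]])

    def to_mixing(self) -> "ContactMatrix":
        """The mixing form e'_ij = e_ij - (e_ii + e_jj)/2 of this table."""
        d = np.diag(self.entries)
        e = self.entries - 0.5 * (d[:, None] + d[None, :])
        return ContactMatrix(e, variant="mixing", checksum=self.checksum)


def _read_table(text: str) -> np.ndarray:
    df = pd.read_csv(io.StringIO(text), index_col=0, sep=None, engine="python")
    df.index = df.index.astype(str).str.strip().str.upper()
    df.columns = df.columns.astype(str).str.strip().str.upper()
    missing = sorted(set(AMINO_ACIDS) - set(df.index)) + sorted(
        set(AMINO_ACIDS) - set(df.columns)
    )
    if missing:
        raise ContactMatrixError(f"table is missing residues {missing}")
    df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
    try:
        e = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ContactMatrixError(f"non-numeric entry in table: {exc}") from exc
    if not np.isfinite(e).all():
        # table stores one triangle only: mirror the other
        filled = np.where(np.isnan(e), e.T, e)
        if np.isnan(filled).any():
            raise ContactMatrixError("table has missing residue pairs")
        e = filled
    if np.abs(e - e.T).max() > _SYMMETRY_TOL:
        raise ContactMatrixError("full table is asymmetric beyond 1e-9")
    # average the triangles so the stored matrix is exactly symmetric
    return 0.5 * (e + e.T)


def load_contact_matrix(source: str | Path | None = None,
                        variant: str = "mixing") -> ContactMatrix:
    """Load a 20x20 contact-energy table.

    Parameters
    ----------
    source
        Path to a tab/comma separated table with one-letter codes as the
        first row and column. ``None`` loads the packaged Miyazawa–Jernigan
        transcription.
    variant
        ``"contact"`` for the table as stored, ``"mixing"`` (default) for
        the mixing form e'_ij = e_ij - (e_ii + e_jj)/2.
    """
    if variant not in VARIANTS:
        raise ContactMatrixError(f"unknown variant {variant!r}; use one of {VARIANTS}")
    if source is None:
        text = resources.files("bfmprotein.data").joinpath(_PACKAGED).read_text()
    else:
        text = Path(source).read_text()
    checksum = hashlib.sha256(text.encode()).hexdigest()
    m = ContactMatrix(_read_table(text), variant="contact", checksum=checksum)
    return m.to_mixing() if variant == "mixing" else m


def epsilon(matrix: ContactMatrix, a: str, b: str) -> float:
    """Symmetric pair-energy lookup (function-style alias)."""
    return matrix.epsilon(a, b)


def pair_potential(r, eps, params: PotentialParams = PotentialParams()):
    """Evaluate u(r) for scalar or array ``r`` (lattice units).

    Zero exactly at and beyond the cutoff and for eps == 0; raises for
    non-positive distances.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    x6 = (params.sigma / r) ** 6
    u = np.where(r < params.r_cut, abs(eps) * x6 * x6 + eps * x6, 0.0)
    return float(u) if u.ndim == 0 else u


def lattice_pair_energies(matrix: ContactMatrix,
                          params: PotentialParams = PotentialParams()) -> dict[int, np.ndarray]:
    """Pair energy tables keyed by squared lattice distance inside the cutoff.

    Returns ``{d2: 20x20 array}`` for every representable squared separation
    ``d2`` with ``2 <= sqrt(d2) < r_cut`` (the default cutoff gives
    ``{4, 5, 6}``). Used to precompute per-pair energies for the MC kernel.
    """
    out: dict[int, np.ndarray] = {}
    for d2 in range(4, int(np.ceil(params.r_cut**2))):
        r = np.sqrt(d2)
        if r >= params.r_cut:
            continue
        # skip d2 not representable as a sum of three squares of a valid
        # center-center separation; 7 is the only gap below 8
        if d2 == 7:
            continue
        x6 = (params.sigma / r) ** 6
        out[d2] = np.abs(matrix.entries) * x6 * x6 + matrix.entries * x6
    return out
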