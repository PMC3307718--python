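"""Bond-fluctuation-model lattice state.

Each residue is a 2x2x2 cube of blocked sites on a periodic simple-cubic
lattice, addressed by the cube's reference corner. Consecutive residues are
joined by a bond vector from the canonical 108-vector set B — all signed
permutations of (2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0) and (3,1,0) —
whose lengths are 2, sqrt(5), sqrt(6), 3 and sqrt(10). Together with the
eight-site excluded volume this bond set makes chain crossing geometrically
impossible.

Positions are stored as *unwrapped* integers: a monomer that diffuses across
the box keeps growing coordinates, and all observables that need real-space
displacements (radius of gyration, center-of-mass MSD) use them directly.
Excluded volume and pair distances live on the torus: occupancy is indexed
modulo the box length L and pair separations use the minimum-image
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np

from .sequence import ProteinSequence

_BASE_BONDS = ((2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0), (3, 1, 0))

#: squared lengths a bond vector may take
ALLOWED_BOND_SQ = frozenset({4, 5, 6, 9, 10})

UNIT_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


class LatticeError(ValueError):
    """Raised for invalid lattice states or impossible embeddings."""


def bond_vector_set() -> np.ndarray:
    """The 108 allowed bond vectors, lexicographically sorted, shape (108, 3)."""
    vecs = set()
    for base in _BASE_BONDS:
        for perm in permutations(base):
            for signs in product((1, -1), repeat=3):
                vecs.add(tuple(p * s for p, s in zip(perm, signs)))
    return np.array(sorted(vecs), dtype=np.int64)


def bond_ok_table() -> np.ndarray:
    """Boolean lookup ``tab[dx+3, dy+3, dz+3]`` for bond validity."""
    tab = np.zeros((7, 7, 7), dtype=np.uint8)
    for v in bond_vector_set():
        tab[v[0] + 3, v[1] + 3, v[2] + 3] = 1
    return tab


def cube_sites(position: np.ndarray, L: int) -> np.ndarray:
    """The 8 lattice sites blocked by a monomer at *position*, wrapped mod L."""
    p = np.asarray(position, dtype=np.int64)
    offs = np.array(list(product((0, 1), repeat=3)), dtype=np.int64)
    return (p[None, :] + offs) % L


@dataclass
class MoveProposal:
    """Attempted single-monomer hop: residue index (0-based) + unit direction."""

    index: int
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.int64)
        if np.abs(d).sum() != 1:
            raise LatticeError("move direction must be a unit lattice vector")
        self.direction = d


@dataclass
class LatticeConformation:
    """Chain positions (unwrapped reference corners) in a periodic box."""

    positions: np.ndarray  # (N, 3) int64
    L: int
    _occupancy: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise LatticeError("positions must have shape (N, 3)")
        if self.L < 8:
            raise LatticeError("box length must be at least 8")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def bonds(self) -> np.ndarray:
        """Consecutive position differences, shape (N-1, 3)."""
        return np.diff(self.positions, axis=0)

    def rebuild_occupancy(self) -> np.ndarray:
        """Occupancy grid (L,L,L) uint8 rebuilt from positions alone."""
        occ = np.zeros((self.L, self.L, self.L), dtype=np.uint8)
        for p in self.positions:
            s = cube_sites(p, self.L)
            occ[s[:, 0], s[:, 1], s[:, 2]] += 1
        return occ

    @property
    def occupancy(self) -> np.ndarray:
        if self._occupancy is None:
            self._occupancy = self.rebuild_occupancy()
        return self._occupancy

    def validate(self) -> None:
        """Raise LatticeError unless all invariants hold."""
        b = self.bonds()
        sq = (b * b).sum(axis=1)
        bad = np.nonzero(~np.isin(sq, list(ALLOWED_BOND_SQ)))[0]
        if bad.size:
            raise LatticeError(f"bond {bad[0]}–{bad[0]+1} has |v|^2={sq[bad[0]]}")
        occ = self.rebuild_occupancy()
        if occ.max() > 1:
            raise LatticeError("excluded-volume violation: doubly blocked site")
        if int(occ.sum()) != 8 * self.n:
            raise LatticeError("occupancy does not cover 8 sites per monomer")

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image of integer displacement(s) d on the torus."""
        return (d + self.L // 2) % self.L - self.L // 2

    def copy(self) -> "LatticeConformation":
        return LatticeConformation(self.positions.copy(), self.L)


def is_valid_move(conf: LatticeConformation, move: MoveProposal) -> bool:
    """Geometric acceptance: excluded volume and bond restrictions only."""
    i = move.index
    new_pos = conf.positions[i] + move.direction
    # both adjacent bonds must stay in B
    for j in (i - 1, i + 1):
        if 0 <= j < conf.n:
            v = conf.positions[j] - new_pos
            if not (np.abs(v) <= 3).all() or int((v * v).sum()) not in ALLOWED_BOND_SQ:
                return False
    # newly claimed face of 4 sites must be free
    occ = conf.occupancy
    new_sites = cube_sites(new_pos, conf.L)
    old_sites = cube_sites(conf.positions[i], conf.L)
    old_set = {tuple(s) for s in old_sites}
    for s in new_sites:
        if tuple(s) not in old_set and occ[s[0], s[1], s[2]]:
            return False
    return True


def apply_move(conf: LatticeConformation, move: MoveProposal) -> None:
    """Apply a geometrically valid move in place, updating the occupancy cache."""
    occ = conf.occupancy
    old = cube_sites(conf.positions[move.index], conf.L)
    occ[old[:, 0], old[:, 1], old[:, 2]] -= 1
    conf.positions[move.index] += move.direction
    new = cube_sites(conf.positions[move.index], conf.L)
    occ[new[:, 0], new[:, 1], new[:, 2]] += 1


def initialize_random(seq: ProteinSequence, L: int, seed: int,
                      max_restarts: int = 100) -> LatticeConformation:
    """Grow a random self-avoiding conformation for *seq* in a box of side L.

    Sequential growth: each residue is appended at a uniformly chosen allowed
    bond vector whose cube does not collide with the chain so far; a dead end
    restarts the whole chain. Deterministic for a fixed seed.

    Growth is reliable when the box comfortably exceeds the coil size — a
    useful rule of thumb is L >= 4 * ceil(N**0.6); much smaller boxes exhaust
    the restart budget and raise.
    """
    n = len(seq)
    if 8 * n > L**3:
        raise LatticeError(
            f"cannot embed {n} monomers ({8*n} blocked sites) in a box of {L**3} sites; "
            "increase L"
        )
    rng = np.random.default_rng(seed)
    bonds = bond_vector_set()
    for _ in range(max_restarts):
        occ = np.zeros((L, L, L), dtype=np.uint8)
        pos = np.zeros((n, 3), dtype=np.int64)
        pos[0] = rng.integers(0, L, size=3)
        s = cube_sites(pos[0], L)
        occ[s[:, 0], s[:, 1], s[:, 2]] = 1
        ok = True
        for i in range(1, n):
            placed = False
            for k in rng.permutation(len(bonds)):
                cand = pos[i - 1] + bonds[k]
                s = cube_sites(cand, L)
                if occ[s[:, 0], s[:, 1], s[:, 2]].any():
                    continue
                pos[i] = cand
                occ[s[:, 0], s[:, 1], s[:, 2]] = 1
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            conf = LatticeConformation(pos, L)
            conf._occupancy = occ
            return conf
    raise LatticeError(
        f"failed to place a {n}-mer in a box of side {L} after {max_restarts} "
        "attempts; increase L"
    )
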