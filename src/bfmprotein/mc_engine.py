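"""Metropolis Monte Carlo engine.

One Monte Carlo step (MCS) is N attempted single-monomer hops, N being the
chain length; the attempted residue and the hop direction (one of the six
unit lattice vectors) are drawn uniformly at each attempt, and attempts
rejected on geometry alone still consume simulation time. Temperature is
normalized (k_B = 1, energies in the units of the contact table).

The production loop is the numba kernel in :mod:`bfmprotein._kernel`;
``total_energy`` / ``delta_energy`` here are straightforward numpy
implementations kept as the reference route for testing the incremental
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .contact_potential import ContactMatrix, PotentialParams, lattice_pair_energies, load_contact_matrix
from .lattice_bfm import LatticeConformation, bond_ok_table, initialize_random
from .sequence import ProteinSequence


@dataclass
class SimulationConfig:
    """Run parameters for a single-replicate simulation."""

    temperature: float = 1.0
    n_mcs: int = 100_000
    equil_frac: float = 0.5
    sample_every: int = 100
    seed: int = 0
    L: int = 128
    params: PotentialParams = field(default_factory=PotentialParams)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 <= self.equil_frac < 1:
            raise ValueError("equil_frac must be in [0, 1)")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.n_mcs < 0:
            raise ValueError("n_mcs must be non-negative")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Sampled output of one run (initial state included at t = 0)."""

    sequence: ProteinSequence
    config: SimulationConfig
    positions: np.ndarray      # (S, N, 3) unwrapped int64
    energies: np.ndarray       # (S,)
    accept_counts: np.ndarray  # (S, N) cumulative per-residue acceptances
    times: np.ndarray          # (S,) MCS timestamps
    final_energy: float        # incrementally tracked energy at the last MCS

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    def frame(self, k: int) -> LatticeConformation:
        return LatticeConformation(self.positions[k].copy(), self.config.L)

    def equilibrated(self) -> np.ndarray:
        """Boolean mask of samples past the equilibration window."""
        return self.times >= self.config.equil_frac * self.config.n_mcs

    def acceptance_rate(self) -> float:
        """Overall accepted fraction of attempts across the whole run."""
        total_attempts = self.times[-1] * self.n
        if total_attempts == 0:
            return 0.0
        return float(self.accept_counts[-1].sum() / total_attempts)


def _pair_energy_matrix(positions: np.ndarray, L: int, seq: ProteinSequence,
                        matrix: ContactMatrix, params: PotentialParams) -> np.ndarray:
    """(N, N) matrix of pair energies u(r_ij) with zero diagonal (numpy route)."""
    d = positions[None, :, :] - positions[:, None, :]
    d = (d + L // 2) % L - L // 2
    d2 = (d * d).sum(axis=-1).astype(float)
    np.fill_diagonal(d2, np.inf)
    idx = seq.indices()
    eps = matrix.entries[np.ix_(idx, idx)]
    x6 = (params.sigma**2 / d2) ** 3
    u = np.abs(eps) * x6 * x6 + eps * x6
    # compare on r, not r^2: squaring r_cut = sqrt(8) is not exact in floats
    u[np.sqrt(d2) >= params.r_cut] = 0.0
    return u


def total_energy(conf: LatticeConformation, seq: ProteinSequence,
                 matrix: ContactMatrix,
                 params: PotentialParams = PotentialParams()) -> float:
    """Sum of pair potentials over all unordered pairs (minimum image)."""
    return float(_pair_energy_matrix(conf.positions, conf.L, seq, matrix, params).sum() / 2.0)


def delta_energy(conf: LatticeConformation, seq: ProteinSequence,
                 matrix: ContactMatrix, index: int, new_position: np.ndarray,
                 params: PotentialParams = PotentialParams()) -> float:
    """Energy change if residue *index* moved to *new_position* (O(N))."""
    idx = seq.indices()
    eps = matrix.entries[idx[index], idx]
    half = conf.L // 2

    def site_energy(p):
        d = conf.positions - p[None, :]
        d = (d + half) % conf.L - half
        d2 = (d * d).sum(axis=1).astype(float)
        d2[index] = np.inf
        x6 = (params.sigma**2 / d2) ** 3
        u = np.abs(eps) * x6 * x6 + eps * x6
        u[np.sqrt(d2) >= params.r_cut] = 0.0
        return float(u.sum())

    return site_energy(np.asarray(new_position, dtype=np.int64)) - site_energy(conf.positions[index])


def metropolis_accept(dE: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/T)); T > 0."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if dE <= 0:
        return True
    return rng.random() < np.exp(-dE / T)


def _u_tables(matrix: ContactMatrix, params: PotentialParams) -> np.ndarray:
    """(3, 20, 20) kernel tables for squared separations 4, 5, 6."""
    if params.r_cut**2 > 8 + 1e-12:
        raise ValueError(
            "the lattice engine supports r_cut <= sqrt(8); larger cutoffs "
            "would need additional distance shells"
        )
    tabs = lattice_pair_energies(matrix, params)
    u = np.zeros((3, 20, 20), dtype=np.float64)
    for d2, t in tabs.items():
        u[d2 - 4] = t
    return u


def run(seq: ProteinSequence, config: SimulationConfig,
        matrix: ContactMatrix | None = None,
        initial: LatticeConformation | None = None) -> Trajectory:
    """Simulate *seq* under *config*; deterministic for a fixed seed.

    ``matrix=None`` loads the packaged contact table in its default (mixing)
    variant. An explicit *initial* conformation bypasses random placement.
    """
    if matrix is None:
        matrix = load_contact_matrix()
    ss = np.random.SeedSequence(config.seed)
    # keep both derived seeds in int32 range (numba's np.random.seed)
    init_seed, kern_seed = (int(s) % (2**31 - 1) for s in ss.generate_state(2))

    if initial is None:
        conf = initialize_random(seq, config.L, init_seed)
    else:
        conf = initial.copy()
        if conf.n != len(seq):
            raise ValueError("initial conformation length does not match sequence")
        conf.validate()

    u_tab = _u_tables(matrix, config.params)
    thermal = bool(np.any(u_tab))
    pos = conf.positions.copy()
    occ = conf.rebuild_occupancy()

    s_pos, s_e, s_acc, s_t, e_final = _kernel.run_mc(
        pos, occ, seq.indices(), u_tab, thermal, bond_ok_table(),
        config.L, float(config.temperature),
        int(config.n_mcs), int(config.sample_every), kern_seed,
    )
    return Trajectory(
        sequence=seq, config=config, positions=s_pos, energies=s_e,
        accept_counts=s_acc, times=s_t, final_energy=float(e_final),
    )
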