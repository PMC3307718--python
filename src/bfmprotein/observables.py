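"""Observables: chain size, per-residue profiles, dynamics, thermodynamics
and the structure factor with its power-law scaling fit.

All length scales are lattice units; time is measured in MCS. Per-residue
profiles are reported 1-based to line up with sequence numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contact_potential import ContactMatrix, PotentialParams
from .lattice_bfm import LatticeConformation
from .mc_engine import Trajectory, _pair_energy_matrix
from .sequence import ProteinSequence


# ---------------------------------------------------------------- chain size

def radius_of_gyration(positions: np.ndarray | LatticeConformation) -> float:
    """Root-mean-square distance of residues from their centroid.

    Uses unwrapped coordinates: the chain itself is never folded back into
    the box.
    """
    if isinstance(positions, LatticeConformation):
        positions = positions.positions
    r = np.asarray(positions, dtype=float)
    c = r.mean(axis=0)
    return float(np.sqrt(((r - c) ** 2).sum(axis=1).mean()))


def rg_series(traj: Trajectory) -> np.ndarray:
    """Radius of gyration at every sampled frame, shape (S,)."""
    r = traj.positions.astype(float)
    c = r.mean(axis=1, keepdims=True)
    return np.sqrt(((r - c) ** 2).sum(axis=2).mean(axis=1))


# ------------------------------------------------------- per-residue profiles

def residue_energy_profile(conf: LatticeConformation, seq: ProteinSequence,
                           matrix: ContactMatrix,
                           params: PotentialParams = PotentialParams()) -> np.ndarray:
    """E_n: interaction energy of each residue with all partners in range.

    Both partners are charged the full pair energy, so the profile sums to
    twice the total energy.
    """
    u = _pair_energy_matrix(conf.positions, conf.L, seq, matrix, params)
    return u.sum(axis=1)


def mean_energy_profile(traj: Trajectory, matrix: ContactMatrix,
                        params: PotentialParams = PotentialParams()) -> np.ndarray:
    """Post-equilibration time average of the per-residue energy profile."""
    mask = traj.equilibrated()
    frames = np.nonzero(mask)[0]
    if frames.size == 0:
        raise ValueError("no post-equilibration samples")
    acc = np.zeros(traj.n)
    for k in frames:
        acc += residue_energy_profile(traj.frame(k), traj.sequence, matrix, params)
    return acc / frames.size


def mobility_profile(traj: Trajectory) -> np.ndarray:
    """M_n: accepted moves per residue per MCS over the equilibrated window.

    Residues are attempted once per MCS on average, so M_n lies in [0, 1]
    in expectation; stochastic excursions above 1 are clamped.
    """
    mask = traj.equilibrated()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("no post-equilibration samples")
    first, last = idx[0], idx[-1]
    elapsed = traj.times[last] - traj.times[first]
    if elapsed == 0:
        raise ValueError("mobility needs a window of at least one MCS")
    m = (traj.accept_counts[last] - traj.accept_counts[first]) / elapsed
    return np.clip(m, 0.0, 1.0)


# ----------------------------------------------------------------- dynamics

def com_msd(traj: Trajectory, n_lags: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-origin-averaged mean squared displacement of the chain centroid.

    Returns (lags in MCS, MSD in lattice units squared) for every multiple
    of the sampling interval up to half the trajectory (or ``n_lags``).
    """
    com = traj.positions.astype(float).mean(axis=1)  # (S, 3), unwrapped
    s = com.shape[0]
    kmax = s - 1 if n_lags is None else min(n_lags, s - 1)
    lags = np.arange(1, kmax + 1)
    msd = np.empty(kmax)
    for k in lags:
        d = com[k:] - com[:-k]
        msd[k - 1] = (d**2).sum(axis=1).mean()
    return lags * (traj.times[1] - traj.times[0]), msd


# ----------------------------------------------------------- thermodynamics

def specific_heat(energies: np.ndarray, temperature: float, n_residues: int) -> float:
    """C_v = (<E^2> - <E>^2) / (N T^2), per residue, k_B = 1."""
    e = np.asarray(energies, dtype=float)
    if e.size < 2:
        raise ValueError("specific heat needs at least 2 energy samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(e.var() / (n_residues * temperature**2))


# ------------------------------------------------------------ structure factor

@dataclass(frozen=True)
class StructureFactorCurve:
    q: np.ndarray  # |q| grid, radians per lattice unit
    s: np.ndarray  # spherically averaged S(|q|)


@dataclass(frozen=True)
class ScalingFit:
    """|slope| of log S vs log q: the effective fractal dimension D = 1/nu."""

    dimension: float
    stderr: float
    q_min: float
    q_max: float
    n_points: int

    @property
    def nu(self) -> float:
        return 1.0 / self.dimension


def default_q_grid(L: int, n: int = 48) -> np.ndarray:
    """Log-spaced |q| from the box scale 2*pi/L up to the lattice scale pi."""
    return np.geomspace(2 * np.pi / L, np.pi, n)


def structure_factor(frames: np.ndarray, q_values: np.ndarray,
                     n_directions: int = 32, seed: int = 0) -> StructureFactorCurve:
    """Spherically averaged S(q) = <|sum_k exp(i q.r_k)|^2> / N.

    *frames* is (S, N, 3) or a single (N, 3) conformation; the spherical
    average uses ``n_directions`` seeded random unit vectors per |q|,
    additionally averaged over frames.
    """
    r = np.asarray(frames, dtype=float)
    if r.ndim == 2:
        r = r[None, :, :]
    s_frames, n, _ = r.shape
    rng = np.random.default_rng(seed)
    q_values = np.asarray(q_values, dtype=float)
    out = np.empty(q_values.size)
    for iq, q in enumerate(q_values):
        v = rng.normal(size=(n_directions, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        # phases: (S, N, M)
        phase = np.einsum("snk,mk->snm", r, q * v)
        amp2 = np.abs(np.exp(1j * phase).sum(axis=1)) ** 2  # (S, M)
        out[iq] = amp2.mean() / n
    return StructureFactorCurve(q=q_values, s=out)


def fit_power_law(curve: StructureFactorCurve, q_min: float, q_max: float) -> ScalingFit:
    """Least-squares slope of log S vs log q over [q_min, q_max]."""
    mask = (curve.q >= q_min) & (curve.q <= q_max) & (curve.s > 0)
    if mask.sum() < 5:
        raise ValueError(
            f"power-law fit needs >= 5 points in [{q_min:.3g}, {q_max:.3g}], "
            f"found {int(mask.sum())}"
        )
    res = stats.linregress(np.log(curve.q[mask]), np.log(curve.s[mask]))
    return ScalingFit(
        dimension=abs(float(res.slope)),
        stderr=float(res.stderr),
        q_min=q_min, q_max=q_max, n_points=int(mask.sum()),
    )


def scaling_window(rg: float) -> tuple[float, float]:
    """Default fit window bracketing the global-conformation regime.

    Spans 2*pi/(4 Rg) .. 4*pi/Rg: from just below the chain scale into the
    start of the intermediate regime.
    """
    return 2 * np.pi / (4 * rg), 4 * np.pi / rg


def effective_dimension(traj: Trajectory, n_frames: int = 64,
                        n_directions: int = 32, seed: int = 0,
                        window: tuple[float, float] | None = None) -> ScalingFit:
    """Structure-factor scaling fit on equilibrated frames of a trajectory."""
    idx = np.nonzero(traj.equilibrated())[0]
    if idx.size == 0:
        raise ValueError("no post-equilibration samples")
    take = idx[np.linspace(0, idx.size - 1, min(n_frames, idx.size)).astype(int)]
    frames = traj.positions[take].astype(float)
    rg = float(np.mean([radius_of_gyration(f) for f in frames]))
    q = default_q_grid(traj.config.L)
    curve = structure_factor(frames, q, n_directions=n_directions, seed=seed)
    if window is None:
        window = scaling_window(rg)
    return fit_power_law(curve, *window)
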