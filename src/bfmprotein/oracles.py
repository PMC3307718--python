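"""Exact Boltzmann ensembles for tiny chains.

Translation invariance is factored out analytically (the first monomer is
pinned at the origin), so a dimer has exactly the 108 bond-vector states and
a trimer at most 108^2 states before excluded-volume filtering. These
closed ensembles are the reference the Metropolis sampler is validated
against: exact <E>, <E^2>, <Rg^2> and the fluctuation specific heat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_potential import PotentialParams, pair_potential
from .lattice_bfm import bond_vector_set


@dataclass(frozen=True)
class ExactEnsemble:
    """Enumerated states with Boltzmann weights at temperature T."""

    energies: np.ndarray   # (n_states,)
    rg2: np.ndarray        # (n_states,) squared radius of gyration
    weights: np.ndarray    # (n_states,) normalized Boltzmann weights
    temperature: float
    n_residues: int
    bond_sq: np.ndarray | None = None  # per-state |bond|^2 (dimer only)

    @property
    def n_states(self) -> int:
        return self.energies.size

    @property
    def mean_energy(self) -> float:
        return float(self.weights @ self.energies)

    @property
    def mean_sq_energy(self) -> float:
        return float(self.weights @ self.energies**2)

    @property
    def var_energy(self) -> float:
        return self.mean_sq_energy - self.mean_energy**2

    @property
    def mean_rg2(self) -> float:
        return float(self.weights @ self.rg2)

    @property
    def specific_heat(self) -> float:
        """Fluctuation form, per residue: var(E) / (N T^2)."""
        return self.var_energy / (self.n_residues * self.temperature**2)

    def bond_class_probs(self) -> dict[int, float]:
        """Probability of each squared-bond-length class (dimer ensembles)."""
        if self.bond_sq is None:
            raise ValueError("bond classes are only defined for the dimer ensemble")
        return {
            int(c): float(self.weights[self.bond_sq == c].sum())
            for c in np.unique(self.bond_sq)
        }


def _boltzmann(energies: np.ndarray, T: float) -> np.ndarray:
    if T <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(energies - energies.min()) / T)
    return w / w.sum()


def dimer_exact(eps: float, T: float,
                params: PotentialParams = PotentialParams()) -> ExactEnsemble:
    """Exact dimer ensemble over the 108 relative bond vectors."""
    b = bond_vector_set().astype(float)
    sq = (b**2).sum(axis=1)
    r = np.sqrt(sq)
    e = pair_potential(r, eps, params)
    rg2 = sq / 4.0  # two equal masses at separation |b|
    return ExactEnsemble(
        energies=np.asarray(e, dtype=float), rg2=rg2,
        weights=_boltzmann(np.asarray(e, dtype=float), T),
        temperature=T, n_residues=2, bond_sq=sq.astype(int),
    )


def trimer_exact(eps_ab: float, eps_bc: float, eps_ac: float, T: float,
                 params: PotentialParams = PotentialParams()) -> ExactEnsemble:
    """Exact trimer ensemble over all valid (b1, b2) bond-vector pairs.

    States where the 2x2x2 cubes of monomers 1 and 3 overlap are discarded;
    bonded cubes can never overlap because every allowed bond has a
    component of magnitude >= 2.
    """
    b = bond_vector_set()
    n = len(b)
    b1 = np.repeat(b, n, axis=0)          # (108^2, 3)
    b2 = np.tile(b, (n, 1))
    r13 = b1 + b2
    valid = (np.abs(r13) >= 2).any(axis=1)
    b1, b2, r13 = b1[valid], b2[valid], r13[valid]

    def u(vec, eps):
        return pair_potential(np.sqrt((vec**2).sum(axis=1).astype(float)), eps, params)

    e = u(b1, eps_ab) + u(b2, eps_bc) + u(r13, eps_ac)
    # positions 0, b1, b1+b2 -> Rg^2 with equal masses
    p = np.stack([np.zeros_like(b1), b1, b1 + b2], axis=1).astype(float)
    c = p.mean(axis=1, keepdims=True)
    rg2 = ((p - c) ** 2).sum(axis=2).mean(axis=1)
    return ExactEnsemble(
        energies=e, rg2=rg2, weights=_boltzmann(e, T),
        temperature=T, n_residues=3,
    )
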