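# bfmprotein

Coarse-grained lattice Monte Carlo simulation of single protein chains,
built for studying how a specific residue sequence shapes a protein's
thermal response — which residues anchor its structure, how its size
(radius of gyration) depends on temperature, and how its mass distribution
crosses over from compact to self-avoiding-walk scaling. The bundled
reference case is the 143-residue histone H2AX, a chain whose charged
residues (D, E, K, R) dominate its conformational behavior.

The model is the bond-fluctuation model (BFM): each residue occupies a
2×2×2 cube of sites on a periodic cubic lattice, consecutive residues are
connected by one of 108 allowed bond vectors (lengths 2, √5, √6, 3, √10),
and single-bead Metropolis hops drive the dynamics at a normalized
temperature T (k_B = 1). Residue specificity enters through a
knowledge-based 20×20 contact-energy table ε_ij (a Miyazawa–Jernigan
transcription, shipped with the package) in a truncated Lennard-Jones pair
potential

    u(r) = |ε_ij| (σ/r)¹² + ε_ij (σ/r)⁶ ,  r < √8

Observables cover the full analysis pipeline: radius of gyration R_g,
per-residue energy and mobility profiles, center-of-mass mean squared
displacement, specific heat C_v = var(E)/(N T²), the spherically averaged
structure factor S(q), and its power-law exponent (effective dimension
D = 1/ν). Exact 108-state dimer and ≤108² trimer ensembles serve as
enumeration oracles that validate the sampler. See `docs/methods.md` for
the model details, defaults and limitations.

## Worked example

Anchor detection at low temperature — which residues hold the histone
together?

```python
import numpy as np
import bfmprotein as b
from bfmprotein import observables as obs

seq = b.h2ax_sequence()                  # bundled 143-residue chain
cfg = b.SimulationConfig(temperature=0.001, n_mcs=1_500_000,
                         sample_every=5_000, seed=1, L=48)
traj = b.run(seq, cfg)                   # packaged contact table (mixing)

mob = obs.mobility_profile(traj)         # accepted moves / MCS, per residue
elec = np.array([a in "DEKR" for a in seq])
print(f"Rg = {obs.rg_series(traj)[traj.equilibrated()].mean():.1f}")
print(f"electrostatic mobility = {mob[elec].mean():.4f}")
print(f"chain median mobility  = {np.median(mob):.4f}")
```

Output from this exact script:

```
Rg = 10.8
electrostatic mobility = 0.0027
chain median mobility  = 0.0488
```

At T = 0.001 the chain has contracted from its athermal size (R_g ≈ 20) to
a charge-bridged network (R_g ≈ 11), and the electrostatic residues move an
order of magnitude less than the typical residue — they are the anchors of
segmental aggregation. Re-running at T = 0.5 gives a self-avoiding walk
(mobility uniform ≈ 0.25, structure-factor dimension D ≈ 5/3).

The same pipeline is available from the shell:

```bash
bfmprotein run   --temp 0.001 --mcs 1500000 --box 48 --seed 1 --out out/
bfmprotein sweep --temps 0.001,0.005,0.02,0.1,0.5 --replicates 2 --out sweep/
bfmprotein analyze sweep/snapshot_T0.5.xyz --box 128
```

`sweep` writes per-temperature tables (`summary.csv`, per-residue profiles,
XYZ snapshots) and reports the crossover temperature T_c — the grid argmax
of ⟨R_g⟩(T), flagged `interior` only when it beats both neighbors by more
than one pooled standard error.

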