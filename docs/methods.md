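# Methods

## Model

`bfmprotein` simulates a single coarse-grained protein chain with the
bond-fluctuation model (BFM) on a periodic simple-cubic lattice. Each residue
is one bead occupying a 2×2×2 cube of lattice sites (excluded volume: no site
may be blocked twice). Consecutive residues are joined by a bond vector from
the canonical 108-vector set — all signed permutations of (2,0,0), (2,1,0),
(2,1,1), (2,2,1), (3,0,0), (3,1,0) — with lengths {2, √5, √6, 3, √10} in
lattice units. This combination of bond set and excluded volume makes chain
crossing geometrically impossible, so the dynamics respect topology without
any explicit entanglement check.

Non-bonded (and bonded) residue pairs interact through a truncated
generalized Lennard-Jones potential

    u(r) = |ε_ij| (σ/r)^12 + ε_ij (σ/r)^6,   r < r_c;   u = 0 otherwise,

with σ = 1 and r_c = √8 by default. The cutoff admits exactly three
inter-bead distances (2, √5, √6): squared separations 4, 5, 6 are the only
sums of three squares reachable by non-overlapping cubes below 8 (7 is not a
sum of three squares). The ε_ij are residue-pair contact energies taken from
a knowledge-based 20×20 table (below); positive entries are repulsive at
contact, negative attractive, and every pair retains a repulsive r⁻¹² core.
Bonded neighbors contribute to the energy like any other pair when inside
the cutoff (a switchable convention; bonds of length 3 and √10 are outside
the cutoff anyway).

Dynamics are single-bead Metropolis hops: a uniformly random residue is
moved one lattice unit in a uniformly random direction, the move is
discarded if it violates excluded volume or the bond set, and otherwise
accepted with probability min(1, exp(−ΔE/T)). Temperature is normalized
(k_B = 1, energies in the units of the contact table); it cannot be mapped
onto Kelvin without an experimental calibration, so all temperatures are
reported in reduced units. One Monte Carlo step (MCS) is N attempted moves
(N = chain length); geometric rejections consume attempts. Energy is tracked
incrementally by ΔE and verified in tests against from-scratch recomputation
(drift below 10⁻⁶ relative over 10⁵ MCS).

## Contact-energy table and its two variants

The packaged file `data/mj_contact_energies.csv` is a transcription of the
classic Miyazawa–Jernigan statistical contact energies e_ij (RT units),
estimated from residue–residue contact counts in a large ensemble of PDB
structures. The loader exposes two variants:

- **contact** — the table as stored. Every entry is negative and
  hydrophobic–hydrophobic pairs dominate (F–F ≈ −7.3, L–L ≈ −7.4, weakest
  K–K ≈ −0.1). A chain under this variant collapses on cooling like a
  homopolymer in poor solvent; the radius of gyration grows monotonically
  with temperature toward the athermal plateau.
- **mixing** (default) — e'_ij = e_ij − (e_ii + e_jj)/2, the
  mixing/segregation part of the same table. Like-pair entries vanish,
  oppositely charged pairs form the deepest wells (K–E ≈ −1.29, K–D, R–E,
  R–D ≈ −1), attractive couplings extend to polar–charged pairs (Q–K, N–K,
  Y–K, …), and hydrophobic–charged pairs are mildly repulsive (≈ +0.3…+0.8).

The mixing variant is the default because its sign structure is the one the
histone phenomenology requires: couplings of both signs, electrostatic
residues (D, E, K, R) with the largest well depth acting as anchors for
segmental aggregation, and — for H2AX — a non-monotonic temperature response
of the radius of gyration (see below). The raw table and any user-supplied
20×20 table remain selectable; the loaded file's SHA-256 is carried in the
`ContactMatrix` and echoed in reports.

With σ = 1 and contacts at r ≥ 2, a contact energy ε maps to
u(2) ≈ 0.0154·ε, so the deepest attractive contact of the mixing table is
about −0.02 energy units. "Low temperature" for H2AX therefore means
T ≲ 0.002 (several k_BT per contact) and "high temperature" T ≳ 0.2.

## Observables

- **Radius of gyration** R_g: RMS distance of beads from the chain centroid,
  computed on unwrapped coordinates (the chain is never folded into the
  box; only pair distances and occupancy are periodic).
- **Per-residue energy** E_n: sum of pair energies of residue n with every
  partner in range; both partners are charged the full pair energy, so
  Σ E_n = 2 E_total (asserted in tests).
- **Mobility** M_n: accepted moves of residue n per MCS over the
  post-equilibration window. Residues are attempted once per MCS on
  average, so M_n ∈ [0, 1] in expectation; values are clamped to that range
  in reports.
- **Center-of-mass MSD**: time-origin-averaged squared displacement of the
  centroid over lag times, on unwrapped coordinates.
- **Specific heat** C_v = (⟨E²⟩ − ⟨E⟩²)/(N T²), per residue, k_B = 1; the
  raw variance is reported alongside.
- **Structure factor** S(q) = ⟨|Σ_k exp(i q·r_k)|²⟩/N, spherically averaged
  over 32 seeded random unit directions per |q| (configurable) and over
  equilibrated frames; q is log-spaced from 2π/L to π.
- **Effective dimension** D: |slope| of log S vs log q over a fit window,
  with ν = 1/D. The default window spans 2π/(4R_g) … 4π/R_g, bracketing the
  crossover from the Guinier knee into the intermediate regime. Calibration
  against synthetic references (orientation-averaged rigid rod → D ≈ 1,
  amorphous ball → D ≈ 3, athermal chain → D ≈ 5/3) shows the estimate is
  window-sensitive for sharp compact objects (Porod q⁻⁴ scattering) but
  stable for fractal chains; the window is user-overridable everywhere.

## Exact small-chain ensembles

Translation invariance is factored analytically, so a dimer has exactly the
108 bond-vector states and a trimer ≤ 108² states (filtered for 1–3
excluded-volume overlap). The oracles give closed-form Boltzmann averages
⟨E⟩, ⟨E²⟩, ⟨R_g²⟩, and the fluctuation specific heat; the Metropolis engine
is validated against them (means within Monte Carlo error, chi-square on
bond-length classes, and the fluctuation–dissipation identity
var(E)/T² = d⟨E⟩/dT).

Useful frozen values: the athermal dimer has ⟨R_g²⟩ = 798/432 ≈ 1.8472
(class populations 6, 24, 24, 30, 24 for |b|² = 4, 5, 6, 9, 10), and the
T → 0 limit with uniform attraction ε = −1 is ⟨E⟩ → 2⁻¹² − 2⁻⁶ ≈ −0.01538
(length-2 bonds minimize u).

## Study design and default parameters

| parameter | default | why |
|---|---|---|
| box side L | 128 (64–48 for short diagnostics) | ≳ 6× athermal R_g of the 143-mer; finite-size effects checked by varying L |
| MCS per run | 10⁵–3×10⁶ | chosen per temperature: low-T relaxation is slowest; diagnostics state the length used |
| equilibration fraction | 0.5 | first half discarded for averages |
| sample interval | 10²–10⁴ MCS | decorrelates samples; mobility and C_v use the same window |
| T grid | 16 log-spaced points, 0.005–0.5 | brackets collapse (T ≲ 0.002) and athermal (T ≳ 0.2) regimes of the default table |
| replicates | 2+ | independent seeds `base + 1009·t_index + r`, echoed in outputs |

Replicates are statistically independent and may run concurrently; results
are identical to serial execution for the same per-replicate seeds.

The crossover temperature T_c is the grid argmax of ⟨R_g⟩(T). It is flagged
"interior" only when it is away from both grid boundaries and exceeds both
neighbors by more than one pooled standard error; a monotone or noisy
profile is reported as such rather than as a detection.

## What the simulations show for H2AX (and what they do not)

With the default table, the bundled 143-residue H2AX chain reproduces the
qualitative phenomenology of the underlying model study:

- at very low T (≈ 0.001) the chain binds into a network of charge-bridged
  segmental globules (E < 0, R_g well below athermal, effective dimension
  rising toward ≈ 2.3–2.5 at the run lengths bundled here), and the
  electrostatic residues are an order of magnitude less mobile than the
  chain median — they are the anchors;
- at intermediate T (≈ 0.005–0.02) the attraction releases while the
  repulsive hydrophobic–charged couplings still act, swelling the chain
  beyond its athermal size — the origin of the interior maximum of
  ⟨R_g⟩(T);
- at high T (≳ 0.2) interactions become irrelevant and the chain is a
  self-avoiding walk, D ≈ 5/3.

Two honest limitations. First, the low-T state at bundled run lengths is a
partially annealed network, not a fully equilibrated compact globule: the
effective dimension observed at 10⁶–3×10⁶ MCS is ≈ 2.3, short of the dense
limit D = 3; low-temperature relaxation is glassy and the equilibrium
globule is kinetically out of reach at these run lengths (the raw `contact`
variant, which collapses much harder, approaches the compact limit
instead). Second, all temperatures are reduced; nothing here claims Kelvin
values. The synthetic-sequence generator produces uniform-composition
chains, which are a useful null model but do not emulate the blocky charge
pattern of real histones, so sequence-specific effects (e.g. the location
of T_c) should not be generalized from random-sequence tests.

## Numerical choices

- Incremental-energy comparisons use r < r_c on distances, never d² against
  r_c² (squaring √8 is inexact in floating point and would admit the d² = 8
  shell).
- Random numbers: one `SeedSequence`-derived pair per run (placement,
  kernel); all seeds ≤ 2³¹.
- Degenerate inputs are errors, not silent answers: fewer than 2 energy
  samples for C_v, empty fit windows, zero-MCS mobility windows, chains
  that cannot embed in the box.
- Power-law fits require ≥ 5 points; ties in the crossover argmax resolve
  to the first (lowest-T) maximum.
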