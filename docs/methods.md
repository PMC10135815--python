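# Methods

## Model and units

Each residue is one bead at its Cα position.  Internal units are
GROMACS-style (nm, ps, kJ/mol, amu), so `1 kJ/mol = 1 amu nm² ps⁻²` and
the integrator needs no conversion factors; `kB = 0.0083145
kJ mol⁻¹ K⁻¹`.  Observables are reported in reduced units: temperature
in `T0 = 100 K`, time in `τ = 1 ns`, distances in Å where the
corresponding observable is conventionally quoted that way (z motion
rate, D, contact cutoffs).

The energy has three terms.  Bonds are harmonic, `K_b (r − r_0)²`
(note: no ½).  The Lennard-Jones term is written `ε[(σ/r)¹² − (σ/r)⁶]`,
i.e. without the conventional prefactor 4, so its well depth is ε/4 at
`r = 2^{1/6} σ`; this printed form is the package default
(`lj_prefactor_mode="as_printed"`) and the standard form is one switch
away.  Electrostatics are Debye–Hückel with `κ = 3.2 √C_salt nm⁻¹`.
The salt-dependent coefficient `B(κ)` defaults to 1; it is a plain
parameter (`b_kappa`) because no functional form is fixed by the model
definition.  Both nonbonded terms are truncated and energy-shifted to
zero at their cutoffs (defaults 3.0 nm = 3σ for LJ, 3.5 nm for DH);
directly bonded (1–2) pairs are excluded from nonbonded sums, 1–3 and
beyond are included.  Any pair involving at least one inserted glycine
interacts at `ε_insert` (including insert–insert pairs — the
"non-interacting tail" reading).

## Integrator and thermostat

BAOAB splitting with friction γ and thermal amplitude `√(kBT/m)` per
bead: mass enters both the inertial kicks and the Ornstein–Uhlenbeck
velocity update, so at fixed T and γ a bead of mass m diffuses with
`D = kBT/(mγ)`.  This is the entire mechanism by which mass scaling
acts: the potential energy surface is mass-independent, so equilibrium
ensembles coincide and only kinetics (and finite-time phase stability)
differ.  γ = 0 reduces the integrator exactly to velocity Verlet, which
the energy-conservation test exploits; that test uses a soft bond
(`K_b = 200`) so the bond period is well resolved at the production
time step and the shadow-energy oscillation (which is bounded, not
drift) stays at the 10⁻⁴ level.  At the production constants
(`K_b = 20 000`, dt = 2 fs) the bond mode has ω·dt ≈ 0.57: stable under
BAOAB but oscillating at the percent level, which is why the
conservation property is checked in the resolved regime.

Randomness: the production kernel draws its gaussians from numpy's
global MT19937 inside numba, seeded per integration segment from a
`SeedSequence` of the run seed; runs are bitwise-reproducible on one
thread.  Neighbor lists are Verlet lists with a 0.4 nm skin over a cell
list, rebuilt when any bead has moved more than half the skin.  The
kernels are compiled with fastmath; because LLVM then assumes finite
arithmetic, non-finite detection (the halt-with-diagnostic contract for
exploding configurations) lives in the Python driver, not the kernel.

## Slab protocol

Production geometry: 200 chains, box elongated to z = 300 nm with
31×31 nm (10 000 beads) or 34×34 nm (12 000 beads) cross-section.  The
default protocol constructs a compact slab directly — chains grown as
clash-rejecting random walks inside a central z-window at a target bead
density (0.6/nm³ production, 0.8 desk) — then relaxes briefly at
reduced time step and high friction, redraws velocities, equilibrates,
and runs production.  The literal cube-equilibrate-then-elongate path
is provided (`protocol="cube_then_slab"`); the coexistence observables
are equilibrium properties and do not depend on the path, and the
constructed-slab start replaces a pressure-coupled pre-equilibration
whose details are not part of the model definition.  Initial placement
enforces a 0.5 nm minimum inter-chain bead distance (0.8 σ for dense
desk starts) so the first relaxation never sees deep LJ overlaps.

Analysis uses the final 20 % of production (the last 1000 τ of a
5000 τ run) — shortened runs analyze the analogous tail fraction.

## Desk preset (scaled-down study conditions)

Integration tests and the acceptance script run a scaled-down pair
study: 30 chains x 20 beads, T in {1, 2, 3, 4} T0, masses 1.0 vs 1.5,
three seeds.  The production force field cannot be used there: with
eps = 0.001 kJ/mol << kBT no condensation occurs on any tractable
schedule, and raising eps under the production geometry (sigma = 1.0 nm
against r_0 = 0.38 nm) parks every 1-3 pair on a stiff LJ wall whose
frequency forces femtosecond steps.  The desk preset is therefore a
standard bead-spring LJ polymer sharing the model's functional forms:
bond length r_0 = sigma = 1.0 nm, K_b = 100 kJ nm^-2 mol^-1, LJ cutoff
2 sigma, dt = 12.5 fs, gamma = 0.25 ps^-1 (faster phase equilibration at
identical mass ordering of D = kBT/(m gamma)), box 13x13x60 nm so the
condensed slab spans ~2 of the 30 density windows -- the same
slab-to-window proportion as the production geometry, which keeps the
0.07/0.15 thresholds meaningful.

The cohesion is eps = 2.4 kJ/mol in the printed form (well depth
0.6 kJ/mol), which places the 20-mer critical temperature just above
1 T0.  The quench depth matters: a deeper quench (larger eps) leaves
the dilute phase empty at the lowest grid temperature -- the order
parameter saturates and the boundary flux is identically zero for both
masses, so the mass comparisons carry no signal there.  At depth
0.6 kJ/mol, T = 1 T0 shows obvious but unsaturated phase separation
with a populated dilute phase, and the rest of the grid covers the
dissolution.

Flux geometry and cadence.  The flux boundary sits at |z| = 12 nm --
in the dilute region, several slab half-widths out and clear of the
center: a boundary in the interfacial zone counts interface
fluctuations (which grow with condensate size and would invert the mass
ordering), and a near-center boundary in a partially dispersed system
sits inside the heavy system's residual density excess, which offsets
its mobility deficit.  Frames are stored every 0.0125 tau: the flux
indicator is a per-chain sign change between consecutive frames, so the
cadence must keep the rms chain displacement per interval well below
the boundary-to-interface gap or the indicator saturates.  Flux uses a
window-constant condensed-phase center (a fixed boundary plane): the
per-frame circular center of a nearly homogeneous system fluctuates
strongly from frame to frame and would inject spurious coherent
crossings.

The slab start is built at 0.8 beads/nm^3, near the dense-phase
density, so neither mass spends the short run on a compaction transient.
Production within each desk run is 0.5 tau after 0.4 tau of relaxation
+ equilibration, with the final 80 % of production analyzed (~32 frame
intervals per seed); these sizes keep the full paired grid at minutes
per cell.

What the desk runs do and do not show: they reproduce the qualitative
structure of the full-scale study -- order parameter falling with T,
heavier chains condensing more stably and moving/exchanging more slowly
-- but none of its absolute numbers (rates in A/tau, fluxes in
chains/tau, T_Cr values differ because the cohesion, chain length and
geometry are scaled).

## Observables: numerical choices

* Density windows: 30 half-open bins spanning [0, Lz); wrapped
  coordinates; `P_H/P_L` from the time-averaged profile over the
  analysis window (a per-frame variant is available).
* Condensed-phase center: circular mean of bead z (well defined when
  the slab straddles the periodic boundary); chain coordinates are
  minimum-image displacements from it; |z| binned into 30 windows over
  [0, Lz/2], values at exactly Lz/2 assigned to the last window.
* z motion rate uses unwrapped chain-CM z on the frame grid;
  off-grid frame times are rejected rather than resampled.
* Flux counts, per chain and interval, a sign change about either
  boundary plane (a chain crossing both planes in one interval still
  scores once, as a per-chain indicator).  The equivalent literal
  box-coordinate form (planes at 2750 ± 250 Å of a 3000 Å box) is kept
  for comparison; it assumes coordinates continuous around the center.
* Head-to-tail distance D excludes inserted glycines by default, so
  insertion chains are compared on the same underlying segment.
* E_inter credits each inter-chain contact to both partner chains.
  The |z|-profile tables drop windows beyond 140 nm in the production
  box (edge effects); the bound scales with the box.
* `tcr_threshold` interpolates linearly at the first downward 0.07
  crossing and reports censoring (`>= T_max` / `<= T_min`) when the
  series never crosses.  `tcr_fit` least-squares the power law with
  T_Cr multi-started on a deterministic grid; β is fixed at 0.325 (3D
  Ising) unless freed.  Points below the 0.07 threshold are excluded
  from the fit; at least three points must remain.

## Synthetic data

Generators carry ground truth computed at construction, never by the
code under test: sequences with exact charge censuses, scripted
single-bead-chain trajectories whose crossings and |Δz| sums are
counted from the script, slab configurations with recorded window
occupancies (aligned to the 30-window grid so a 1/30-fraction slab
fills exactly one window), and power-law binodals with stored
parameters.  Scripted trajectories pass through the same
TrajectorySeries container and writers as simulator output, so format
round-tripping is exercised for free.

## Known limitations

* The RGG fixture is a composition-matched synthetic stand-in (6 D/E,
  9 R over 50 residues, RGG-motif style), not the verified UniProt
  subsequence; the FASTA fixture is editable in place.  Every shipped
  analysis depends only on the charge composition.
* DCD output is float32 Å; round-trips meet 1e-6 nm only for
  coordinates ≲ 15 nm.  The extended-XYZ writer is full precision.
* Full production scale (2.5 × 10⁹ steps per cell) is supported by the
  same code paths but is not what the test suite runs; desk-scale
  results are trend-level evidence only.
* No Ewald electrostatics, constraints, barostats, or GPU execution.
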