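# cgslab

Coarse-grained slab simulations and analysis of how molecular **mass**
changes shift liquid–liquid phase separation (LLPS) of intrinsically
disordered FUS segments.

Two 50-residue FUS fragments — the nearly uncharged prion-like domain
(PLD, residues 1–50) and the charge-bearing RGG region (residues
453–502) — are modeled one bead per residue.  Mass is perturbed two
ways: scaling every bead mass (an isotope-labeling surrogate: 1.0, 1.1,
1.2, 1.3, 1.5 m0) or appending non-interacting glycine beads (10 at the
tail, or 5 at each end) whose extra mass matches a 1.2-scaled chain.
Because mass enters both inertia and the Langevin thermostat's drag,
heavier chains move more slowly at equal temperature — the package exists
to quantify how that pure-mass effect alters condensate stability.

## Model

Potential energy (kJ/mol, lengths in nm):

* bonds: `U_b = K_b (r − r_0)²` with `K_b = 20 000 kJ nm⁻² mol⁻¹`,
  `r_0 = 0.38 nm`;
* Lennard-Jones: `U_LJ = ε [(σ/r)¹² − (σ/r)⁶]` with `σ = 1.0 nm`,
  `ε = 0.001 kJ/mol` (`ε_insert = 0.00001` for any pair touching an
  inserted glycine — that is what "non-interacting" means here).  Note
  the model defines LJ *without* the conventional prefactor 4; the
  textbook form is available as `lj_prefactor_mode="standard_4eps"`;
* Debye–Hückel: `U_DH = K_c B(κ) q_i q_j exp(−κ r)/(ϵ_r r)` with
  `K_c = 138.94 kJ mol⁻¹ nm e⁻²`, `ϵ_r = 80`, `κ = 3.2 √C_salt nm⁻¹`
  (D/E → −1 e, K/R → +1 e, all else neutral).  Two solvent conditions:
  10 mM salt (κ ≈ 0.32 nm⁻¹) or electrostatics off.

Dynamics: BAOAB Langevin at temperature `T` (reported in `T0 = 100 K`
units), friction 1 ps⁻¹, time step 2 fs; times are reported in
`τ = 1 ns`.  Production geometry is the direct-coexistence slab: 200
chains in a box elongated to `z = 300 nm` (31×31 nm cross-section for
10 000-bead systems, 34×34 nm for 12 000).

Observables: the z axis is cut into 30 windows and the order parameter
is `P_H − P_L`, the spread of the windowed bead-occupancy fractions;
LLPS counts as obvious above 0.15 and as gone below 0.07, and the
critical temperature `T_Cr` is estimated both by threshold interpolation
and by fitting `P_H − P_L = A (T_Cr − T)^β`.  Chain-level metrics (after
re-centering on the condensed phase): the z motion rate (mean |Δz| of
chain centers of mass per τ, Å/τ), the flux of chains across the two
boundary planes at |z| = 25 nm (chains/τ), the chain probability profile
along |z|, the head-to-tail distance D (insert-excluding), and
opposite-charge contact counts E_intra (< 12 Å, same chain) and E_inter
(< 15 Å, across chains).

## Worked example

A scaled-down paired study (30 chains × 20 beads, desk preset, three
temperatures, masses 1.0 vs 1.5):

```python
from cgslab.grid import ExperimentGrid, run_grid

grid = ExperimentGrid(
    systems=("G" * 20,), mass_scales=(1.0, 1.5),
    temperatures=(1.0, 2.0, 4.0), seeds=(42,),
    preset="desk", n_chains=30,
)
df = run_grid(grid)
print(df[["mass_scale", "temperature", "ph_pl", "z_motion_rate",
          "flux"]].round(3).to_string(index=False))
```

```
 mass_scale  temperature  ph_pl  z_motion_rate  flux
        1.0          1.0  0.244        549.249   0.0
        1.0          2.0  0.034       1416.027 220.0
        1.0          4.0  0.019       1985.826 245.0
        1.5          1.0  0.250        488.449   0.0
        1.5          2.0  0.042       1193.613 210.0
        1.5          4.0  0.013       1617.006 257.5
```

Reading the table: `ph_pl` collapses above T = 1 (the desk-scale
critical temperature sits just above 1 T0) and at T = 1 is larger for
the heavier chains — mass increase stabilizes LLPS.  The z motion rate
(Å/τ) is smaller for mass 1.5 at every temperature: heavier chains are
slower, which is the mechanism.  Flux counts chains crossing the
|z| = 12 nm boundary planes per τ; it vanishes at T = 1 for this single
seed (escape events are rare in the phase-separated state) and grows as
the condensate dissolves.  Single-seed flux at high temperature is
noisy — the test suite asserts the mass orderings on three-seed
averages, where the heavier system's flux is lower at every
temperature.

## Command line

`cgslab build | simulate | analyze | phase-diagram | synth | run-grid |
check-forces` — thin wrappers over the library; `cgslab simulate
run.yaml` takes a YAML config (see `cgslab/config.py` docstring for the
schema) and writes DCD/extended-XYZ trajectories plus chain-CM tables.

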