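# forcekin

Force-dependent kinetics of single receptor/ligand bonds, built around
the question of how mechanical force reshapes T-cell antigen
discrimination.  T cells distinguish self from foreign peptide-MHC
(pMHC) by the off-rate of the TCR/pMHC bond, and they pull on that
bond while deciding.  `forcekin` implements the full computational
chain needed to study this in a cell-free setting:

- **Bell kinetics** (`forcekin.bell_kinetics`) — the slip/catch-bond
  model k_off(F) = k⁰_off·exp(F·x_β/k_BT), the fold-change calculus
  that links the x_β-vs-k_off coupling to discrimination, and
  Bell-Evans dynamic force spectroscopy with fitting.
- **Chamber hydrodynamics** (`forcekin.chamber`) — laminar-flow-chamber
  force calibration: flow rate → wall shear → bead velocity → tensile
  force on a single tethering bond, F = (R + Γ/a)·√(a/2L).
- **Arrest-survival analysis** (`forcekin.arrest_survival`) — from
  bead-arrest event tables to per-force off-rates: velocity binning,
  binding-linear-density specificity filtering, non-specific
  background correction of survival curves, three off-rate estimators
  (survival at 1 s / 2 s, exponential-plateau fit), Bell fits and the
  x_β-vs-K_D correlation across a ligand panel.
- **Coarse-grained pulling** (`forcekin.cg_pulling`) — structure-based
  one-bead-per-residue model (native-contact potential, Langevin
  dynamics, numba-accelerated), constant-speed dual-spring pulling,
  rupture-force statistics, Bell-Evans extraction and contact-deletion
  constructs.
- **Mechanical proofreading** (`forcekin.proofreading`) — kinetic
  proofreading with force-dependent membrane off-rate: occupancies
  C_T and C_N, potency, discrimination power α, and per-condition
  force/threshold fits with nested-model F tests.
- **Binding affinity** (`forcekin.affinity`) — Langmuir isotherm fits
  (free or standard-curve-constrained Bmax), mono-exponential
  dissociation fits, and k_on = k_off/K_D.
- **Synthetic data** (`forcekin.synthetic`) — seeded generators with
  known ground truth for every input the chain consumes, including a
  toy two-helix complex for the pulling simulator.

The central quantitative fact the package expresses: if x_β decreases
with k_off (as measured), force *compresses* off-rate differences
between ligands — a 100-fold difference at zero force becomes ~12-fold
at 15 pN with slope −0.3 nm/decade (and ~820-fold with the opposite
coupling) — so pulling on TCR/pMHC bonds impairs discrimination, and
force-shielding by adhesion receptors can restore it.

## Worked example

Simulate a flow-chamber experiment with a planted slip bond and
recover it:

```python
from forcekin.bell_kinetics import BellBond
from forcekin.synthetic import LFCSimConfig, simulate_arrest_table
from forcekin.arrest_survival import ligand_force_spectrum

cfg = LFCSimConfig(true_bond=BellBond(k0_off=0.29, x_beta=0.3),
                   n_beads=100)
sim = simulate_arrest_table(cfg, seed=11)
res = ligand_force_spectrum(sim.events, sim.controls,
                            summaries=sim.summaries)
bond = res.bells["exp_fit"]
print(f"k0_off = {bond.k0_off:.3f} 1/s, x_beta = {bond.x_beta:.3f} nm")
```

prints

```
k0_off = 0.297 1/s, x_beta = 0.291 nm
```

— the planted zero-force off-rate (0.29 s⁻¹) and force sensitivity
(0.3 nm) recovered within 3% from ~12,000 simulated arrests across six
velocity bins, after background correction and QC.  `res.table` holds
the per-bin forces and all three off-rate estimates.

The same chain is scriptable from the shell:

```
forcekin simulate lfc --seed 11 --out sim/
forcekin survival --events sim/events.csv --controls sim/controls.csv \
                  --summaries sim/summaries.csv --method exp_fit --out fits.json
forcekin force --velocity 100        # bond force (pN) at 100 um/s
```

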