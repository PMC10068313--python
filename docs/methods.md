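# Methods

`forcekin` models how mechanical force reshapes the dissociation
kinetics of receptor/ligand bonds — the T-cell receptor (TCR) binding
peptide-MHC (pMHC) is the motivating system — and what that does to
antigen discrimination.  This note documents the models, the choices
made where the underlying physics or published protocol left freedom,
and what the synthetic-data tests do and do not demonstrate.

## Bell kinetics and the fold-change calculus

A single bond under constant tensile force F dissociates at

    k_off(F) = k0_off * exp(F * x_beta / kB*T),

with `k0_off` the zero-force off-rate (1/s) and `x_beta` the force
sensitivity (nm), interpretable as the distance from the bound state to
the transition state.  `x_beta > 0` is a slip bond, `x_beta < 0` a
catch bond.  Defaults use kB = 0.0138 pN nm/K and T = 310.15 K
(kB*T = 4.2801 pN nm); the proofreading module instead fixes
kB*T = 4.2797 pN nm, the constant of its published formulation, so its
worked numbers reproduce exactly.

When `x_beta` varies linearly with log10(k_off), an applied force
rescales the *ratio* of two ligands' membrane off-rates by
`exp(slope * log10(ratio) * F / kB*T)` — independent of the absolute
rates (property-tested).  At 15 pN and slope ±0.3 nm/decade a 100-fold
off-rate difference becomes ~820-fold or ~12-fold.  Antigen
discrimination rides on this ratio, which is why the sign of the
x_beta–k_off coupling decides whether force helps or hurts.

Bell fits are performed as linear regression of ln(rate) on force:
the exponential model has multiplicative errors, the fit has
closed-form covariance, and a nonlinear option is available for
comparison.  Inverse-variance weights are applied when per-rate errors
are supplied, otherwise the fit is unweighted (the published protocol
does not state a weighting; both are exposed).

## Flow-chamber hydrodynamics

A microsphere of radius `a` tethered to the chamber floor in shear flow
G experiences drag R = 1.7005·6π·µa²G, torque Γ = 0.9440·4·µa³G, and a
lever-arm amplification √(a/2L) set by the bond length L, giving
F = (R + Γ/a)·√(a/2L).  The torque prefactor is implemented exactly as
published (no π); a `torque_with_pi` switch provides the standard
literature form.  The wall shear of a rectangular channel is
G = 6Q/(l·H²) — the published shorthand 6Q/H² omits the width and is
dimensionally a velocity, so the plane-Poiseuille form is used.
Bead velocity converts to shear through the wall-translation factor
0.7431 of a sphere moving in contact with a plane.  Defaults (4.5 µm
beads, 1 mPa·s medium, 30 nm tether) put bead velocities of 2–120 µm/s
at bond forces of roughly 1.3–80 pN, covering most of the assay's
5–120 pN working range; all constants are configurable and nothing in
the analysis depends on the defaults beyond this range statement.

## Arrest-survival analysis

The pipeline consumes arrest-event tables (duration, bead velocity,
condition, experiment) and proceeds:

1. **Velocity bins** [2,10), [10,20), [20,40), [40,60), [60,80),
   [80,120) µm/s, half-open; events outside are dropped.  The bin's
   force comes from its mean bead velocity.
2. **Specificity filter**: per bin, the fold change of binding linear
   density (arrests/mm) over the ligand-free control is aggregated
   geometrically across experiments; bins whose geo-mean divided by
   the geo-SEM factor falls below 1 are excluded.  Error bars of
   log-scale data are multiplicative, so "mean − SEM" is implemented
   as division by the factor; a literal subtraction mode exists.
   Under the null this rule still retains ~16% of bins (the one-sided
   tail of the bound), which is its designed false-acceptance rate.
3. **Survival**: s(t) = P(duration ≥ t) on the grid of observed
   durations (left-continuous step function; this convention matches
   the estimator "survival fraction at 1 s" evaluated at the first
   event at or after 1 s).
4. **Non-specific correction**: with sample and control arrest
   densities w_s > w_c, the specific survival is the mixture inversion
   (w_s·s_s − w_c·s_c)/(w_s − w_c), clipped to [0,1].  This preserves
   the probabilistic interpretation; plain pointwise subtraction is
   available.  A bin with w_c ≥ w_s is refused as fully non-specific.
5. **QC**: bins with fewer than 15 raw events in (1 s, 2 s] are
   excluded (half-open: exactly 1 s does not count, exactly 2 s does).
6. **Off-rates**, three estimators per bin: −ln s(1)/1, −ln s(2)/2,
   and a bounded fit of s(t) = (A−B)·exp(−k t) + B to the first 5 s
   (0 ≤ B ≤ A ≤ 1.05, parametrised B = A·b to keep the constraint
   exact).  The plateau B absorbs the long-lived subpopulation that
   makes raw survival non-exponential; when that subpopulation is
   present the at-1s/at-2s estimators are biased toward the plateau
   while the exponential fit recovers the fast rate — which is why
   parameter-recovery tests read the exponential-fit estimate, while
   all three are always reported.  A fit whose decaying amplitude
   A−B vanishes is flagged non-identifiable.
7. **Bell fit** per estimator over surviving bins (≥3 required), then
   across a ligand panel the regression of x_beta on log10(K_D).

A caution on uncertainties: the exponential-fit standard errors come
from autocorrelated survival-curve residuals and are treated as
relative weights, not calibrated intervals; interval statements in the
tests use the binomial delta-method error of the at-1s estimator or
Monte-Carlo spread.

## Synthetic flow-chamber data

The generator emulates, per experiment × velocity bin × ligand
density: bead velocities uniform within the bin; specific arrest
counts Poisson with mean BLD × distance, where the specific BLD scales
linearly with ligand density, with a lognormal day-to-day factor
(sd 0.15), and with a logistic encounter factor (midpoint 80 µm/s,
width 15 µm/s) emulating encounter-time-limited binding at fast flow;
specific lifetimes a mixture of Exp(k(F)) (Bell rate at the bin force)
and, with probability 0.10, a slow Exp(0.05 s⁻¹) plateau
subpopulation; non-specific arrests at 0.05 arrests/mm with
Exp(1.0 s⁻¹) lifetimes on every surface; durations rounded to the
20 ms frame grid with sub-half-frame arrests dropped (undetectable)
and censoring at the 90 s movie end.  Defaults correspond to a
well-behaved single-bond regime at roughly 500–4000 events per bin
with 100–300 beads; the plateau fraction and background level are
chosen at the low end of what real curves show so that the correction
and QC stages are exercised without dominating.

What these simulations do **not** emulate: multi-bond arrests, bead
collisions (real curves truncate at 5 s for this reason), tracking
noise in durations, force heterogeneity within a bin, or any
signalling-driven bond stabilisation.  Passing recovery tests
therefore demonstrates correctness of the estimators under the model's
own assumptions, not robustness to those artefacts.

## Coarse-grained pulling simulations

One bead per residue at the Cα position.  Native contacts are detected
on heavy atoms, either by van-der-Waals overlap (distance <
1.24·(r_i + r_j), the default for real structures) or by a plain
distance cutoff (4.5 Å default; used with CA-only toy structures at
5.8 Å); pairs (i, i±1) and (i, i±2) are never contacts.  The
potential: backbone springs at native lengths (k = 50 ε/Å² for i,i+1;
15 ε/Å² for i,i+2, acting as bending stiffness), intra-molecular
contacts as harmonic springs with stiffness 72·ε/r0² (the curvature of
the matching Lennard-Jones well — chains cannot unfold, so force
traces show a single rupture peak), inter-molecular contacts as 12-6
Lennard-Jones wells of depth ε_inter at the native distance, and a
generic ε·(4 Å/r)¹² repulsion between everything else.  The native
configuration is a stationary point up to the weak repulsion tail
(tested: residual force < 0.05 ε/Å).

Dynamics: BAOAB Langevin with unit mass and kB·T = 1, friction
γ = 1/τ; with γ = 0 the scheme is velocity Verlet and conserves energy
(drift < 0.1% over 10⁵ steps, tested).  The default timestep is
0.1/√k_max; the toy ensemble uses 0.02 τ, comfortably inside the
stability margin of its stiffest spring.  Pulling attaches κ = 0.12
kT/Å² springs to the C-termini of the two partner chains; one anchor
is fixed, the other retracts at constant v along the initial
anchor-to-anchor axis (not re-aligned during pulling).  The reported
force is the moving spring's extension component along that axis;
rupture is the maximum of the lightly smoothed trace, validated by all
inter-molecular contacts exceeding 1.5·r0 with the force relaxed below
a quarter of the peak.  Mean rupture force F_max(v) over replicates is
fitted with the Bell-Evans relation
F = (kT/x_beta)·ln(x_beta·κ·v/(kT·k_off)) as weighted least squares of
F on ln v, giving (k_off·τ, x_beta) per construct; time is left in
units of τ throughout.

The toy study: two idealised α-helices (26 residues each, 52 beads)
with a planted 14-contact interface, ε_inter = 3 kT (stable for
hundreds of τ unloaded, rupturing under load at every tested speed),
pulled at v = 0.005, 0.015 and 0.045 Å/τ with 10 replicates per speed,
across three nested constructs: the full interface, one with contacts
of a 5-residue edge window deleted (9 contacts), and one keeping only
the far edge (7 contacts).  These speeds sit above the published
protocol's range because the toy interface is far smaller than a real
TCR/pMHC interface; the qualitative Bell-Evans regime (F_max linear in
ln v) is verified rather than assumed.  The frozen ensemble reproduces
the study's simulation phenomenology at sign level: deletions raise
k_off·τ monotonically, lower x_beta, and the x_beta-vs-log10(k_off)
regression is negative.  Absolute slope values are parameter-sensitive
and are not an acceptance surface.

## Kinetic proofreading with force

C_T comes from two-species equilibrium (closed-form quadratic root),
C_N = (1 + k_m/k_p)^-N · C_T with N = 2.46 effective steps at
k_p = 2.15 s⁻¹, and potency is the ligand concentration driving
C_N to 10⁻⁴ — solved by bisection on the full model, or in the
ligand-limited regime by the closed form
P = λ + N·log10(1 + k_m/k_p) (log10 µM; the two agree to 1% when the
threshold concentration is far below receptor saturation, tested).
The membrane off-rate uses k_m = k_on·K_D·exp(x_beta(K_D)·F/4.2797)
with k_on = 0.0447 µM⁻¹s⁻¹.

The empirical force-sensitivity relation carries a unit subtlety: its
slope, −0.029 nm per decade of K_D, is unit-free, but the intercept
depends on the units of K_D inside the logarithm.  This package takes
the logarithm over K_D in molar units — on the µM scale,
x_beta = −0.029·log10(K_D/µM) + 0.064 nm — because that reading makes
agonist-range ligands slip bonds crossing to catch bonds only above
K_D ≈ 160 µM, which is the observed phenomenology (catch bonds occur
at very low affinity) and yields the model's documented behaviour:
potency rises with force (force costs sensitivity) and discrimination
power α falls monotonically from 1.51 at 0 pN to 0.95 at 150 pN.
Reading the intercept on the µM scale instead makes every measured
ligand a catch bond and inverts both behaviours.  The coefficients are
plain parameters for users who need either convention.

Fitting potency-vs-K_D data: free parameters are one force per
condition and either a shared or per-condition λ; N, k_p, k_on and the
relation stay fixed.  Least squares (multi-start over F) on log10
potency, unweighted by default (weighting by reported SEMs is an
option); standard errors from the Jacobian with residual-variance
scaling; forces bounded below by 0.  Global-vs-local λ is compared
with the extra-sum-of-squares F test, whose type-I error calibrates to
0.05 ± 0.02 in simulation.  Degrees of freedom are n_points minus free
parameters.  The recovery tests check unbiasedness of (F, λ) over
seeded replicates rather than a single draw, because any single fit
has only ~74% probability of landing all six parameters inside their
nominal 2-SE boxes.

## Binding affinity

Langmuir fits B = Bmax·[TCR]/(K_D + [TCR]) run with Bmax free (≥3
concentrations) or fixed from the antibody standard curve (≥2); an
unsaturated design (max concentration < 2.5·K_D) triggers a warning.
The standard curve regresses receptor Bmax on antibody Rmax through
the origin (both count active immobilised sites; an affine mode
exists), using only calibration points from saturated designs.  The
reporting rule: a constrained K_D above 20 µM is reported, otherwise
the free-Bmax fit.  Dissociation traces are fitted mono-exponentially
with the first post-injection sample skipped.  Double referencing is
assumed upstream; a paired-buffer subtraction helper is included, but
no instrument file formats are parsed.

## Problem sizes and determinism

All stochastic tests are seeded (hypothesis runs derandomised).  The
test suite's heavy items and their sizes: the toy pulling ensemble (90
trajectories, ~52 beads, a few minutes), the 100-replicate pipeline
sign check (5-ligand panels, ~1 minute), and the 500-replicate F-test
calibration (~10 s).  The acceptance script evaluates only closed-form
quantities and completes in seconds.

## Known limitations

- Single-barrier Bell phenomenology only; no two-pathway catch-bond
  models, and non-canonical bonds should be reported per-bin rather
  than force-fitted.
- The exact velocity→force constant of a real chamber depends on bead
  and tether parameters that must be calibrated per setup; defaults
  are plausible, not measured.
- The coarse-grained engine is O(N²) per step and intended for reduced
  systems (≲150 beads); real complex-scale runs need a neighbour list
  it does not have.
- Frame quantisation is treated as exact by the estimators; at rates
  approaching the frame rate (k·Δt ≳ 0.3) the plateau-bounded
  amplitude constraint starts to bias the exponential fit, but such
  bins are excluded by the event-count QC rule in practice.
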