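# Methods

## The model

`hydrosorb` simulates water sorption by an amorphous matrix of coarse-grained
beads — a desk-scale stand-in for a lyophilized protein powder.  The model is
deliberately minimal:

* **Particles.** Single-site Lennard-Jones beads.  Matrix beads come in two
  flavours that differ only in a water-affinity multiplier: *hydrophilic*
  (affinity 2.0, i.e. a water–bead well twice as deep as water–water) and
  *hydrophobic* (affinity 0.5).  Water is a single LJ site.  All sigma and
  epsilon values are 1 in reduced units; the affinity multiplies the
  geometric-mean epsilon of water–bead pairs only.
* **Topology.** Chains are sequences of beads joined by stiff harmonic bonds
  (k = 100, r0 = 1 sigma) — the backbone-connectivity analog.  Non-local
  crosslinks (the disulfide-bridge analog) are harmonic springs (k = 100)
  between sequentially distant beads, with rest lengths frozen at the
  separations found in the annealed structure.  Optional per-bead tethers pin
  beads to fixed anchors; a fully tethered matrix is the rigid-matrix control.
* **Units.** The engine runs in reduced LJ units (sigma = epsilon = k_B = 1).
  Masses carry gram-per-mole scale values (beads 110, the mean amino-acid
  residue mass; water 18) solely for the hydration-level bookkeeping
  h = (water mass)/(dry matrix mass) in g/g.  The analysis module is
  unit-agnostic and accepts Angstrom-unit trajectories.
* **Interactions.** LJ truncated (not shifted) at 3 sigma, minimum image,
  fully periodic orthorhombic box, no electrostatics: attraction
  heterogeneity is carried entirely by the affinity multiplier.

A single molecule at a time may be partially coupled with parameter
lambda in [0, 1]: U(lambda) = U_rest + lambda * U_inserted(lambda).  The
inserted molecule's pair sum uses a separation-shifted soft-core form,
r_eff^2 = r^2 + 0.5 (1 - lambda) sigma_ij^2, which is finite at zero
separation for lambda < 1 and reduces *exactly* to the plain potential at
lambda = 1.  The soft-core shape is a modelling choice; only the endpoints
(ideal-gas ghost at 0, full interaction at 1) are physically prescribed.

## Sorption protocol

Sorption runs are sequences of single-molecule events separated by Metropolis
relaxation at fixed N, V, T (no barostat: the box is sized with head space so
that the powder plus its full water load stays below jamming density):

* **Adsorption** inserts one water at a non-overlapping random position
  (rejected within 0.8 sigma of any particle, capped at 10^4 attempts) as a
  lambda = 0 ghost, then ramps lambda linearly over `ramp_steps` increments
  with relaxation sweeps between increments.
* **Desorption** removes one water drawn with probability proportional to
  exp(-beta dU_i), where dU_i is the energy change of removing water i —
  weakly bound waters leave first, as they would physically.  Weights are
  max-shifted; the draw is an inverse-CDF lookup in stable index order.
* **Measurement.** Every time h crosses a 0.02 g/g grid point the engine runs
  a production relaxation, discards the first 1/7, saves frames at a fixed
  interval, and estimates the chemical potential on them.

Monte Carlo moves are single-particle displacements (cubic, half-width
0.3 sigma).  Water moves additionally attempt a box-uniform reposition with
probability 0.5 — a symmetric proposal, so detailed balance is untouched.
This mixing is what separates the timescales in the model: the water
subsystem equilibrates within one production block, while matrix
rearrangements remain slow on the branch timescale.  The sweep counts of the
desk-scale protocol (10 sweeps per sorption event, 200 production sweeps per
grid point) were calibrated against the rigid-matrix control: with every
bead tethered, the measured hysteresis is near zero, so the hysteresis that
remains for mobile matrices is a matrix-history effect, not a water-sampling
artifact.  The full-scale defaults (200/5000 sweeps) keep the same ratios.

## Chemical potential and relative humidity

The water chemical potential at each grid point is estimated from the saved
frames by Bennett's acceptance ratio: forward samples are energy changes of
uniform ghost insertions (18 000 per grid point by default), reverse samples
the energy changes of deleting each real water in each frame (ghost moves;
frames are never modified).  With f the Fermi function, the self-consistent
equation

    sum_F f(beta (W_F - C)) = sum_R f(beta (W_R + C))

is solved by bracketed root finding (imbalance below 1e-10), and
mu_ex = C + kT ln(n_F / n_R).  Widom insertion is the cross-check and the
fallback when a frame set contains no waters.  Standard errors come from
re-estimating mu on 5 contiguous frame blocks.

Relative humidity is RH = 100 exp((mu_w - mu_sat)/kT) with
mu_w = mu_ex + kT ln(rho_w Lambda^3).  The thermal-wavelength reference
Lambda cancels between mu_w and mu_sat by construction; the suite asserts
this numerically over five decades.  Because the toy water's vapor pressure
is not known a priori, mu_sat is *calibrated*: BAR on a pure-water box at
the liquid coexistence density (0.75 at the study temperature T* = 0.9 for
the cutoff-truncated LJ fluid), using the identity of liquid and vapor
chemical potentials at coexistence.  For Angstrom/Kelvin analyses of real
data, the ideal-gas route mu_sat = kT ln(p_sat/kT * Lambda^3) with the
water-model vapor pressure is the documented alternative.

## Reference studies (what the acceptance script runs)

* **Crosslink study.** A 200-bead, 8-chain matrix (hydrophilic fraction 0.4,
  bead density 0.15) runs a full 0.04 -> 0.28 -> 0.04 g/g loop twice: with
  crosslinks on 20% of the beads and without.  Both variants share
  bit-identical bead geometry — crosslink sampling uses a dedicated random
  stream — so the comparison isolates the constraint itself.  Readout:
  trapezoidal area between the adsorption and desorption RH(h) curves, plus
  the maximum RH gap and its location.
* **Connectivity study.** A bonded 64-bead chain matrix versus the free-bead
  mixture of identical composition (bead density 0.10), each adsorbing up to
  its approximate saturation limit — 0.4 g/g bonded, 0.9 g/g free,
  mirroring the experimental contrast between globular proteins and free
  amino-acid mixtures.  Readout: hydration level at RH 90% on the adsorption
  branch, by inverse interpolation of the running-maximum RH curve; a branch
  that never reaches 90% reports its largest sampled h as a lower bound.

The temperature T* = 0.9 keeps the matrix condensed but not glassy: at 0.75
the matrix froze on all accessible timescales and the branches differed only
through water history; at 0.9 matrix aging over a branch is observable and
responds to constraints.

## What the toy reproduces — and what it does not

Emergent behaviours the tests check: a Type-II-like isotherm with pronounced
hysteresis (adsorption RH above desorption RH at matched h); the
near-disappearance of hysteresis for a rigid (tethered) matrix; higher
uptake at matched RH for the unbonded mixture; growth of the largest water
cluster with h up to a spanning (percolating) network.

Known limitations.  The isotropic single-site water cannot reproduce
hydration-induced *swelling*: a shared water attracts both beads it bridges,
so hydration slightly contracts rather than expands the matrix, and the
hysteresis carried by large-scale conformational change in real protein
powders appears here as slower, more local matrix aging.  As a consequence,
*partial* rigidification by pairwise crosslinks on 20% of the beads does not
reliably shrink the hysteresis area at this scale: the measured paired
difference over ten seeded replicates is indistinguishable from zero, and
crosslinked runs are frequently more hysteretic, consistent with constraint
drag (slower recovery without a reduced amplitude of structural change).
The corresponding replicate test documents this openly and currently fails;
only the full-rigidity limit behaves as expected.  Water activity at high h
follows a Raoult-like mole-fraction law, so the free-bead mixture approaches
saturation only near h ~ 0.9 g/g.  Absolute RH values inherit any bias of
the mu_sat calibration; branch comparisons do not, because a mu_sat shift
rescales both branches together.

## Numerical choices

* Metropolis sweeps visit particles sequentially; proposal randomness is
  pre-drawn from a seeded PCG64 generator, making every run bit-reproducible
  (the suite asserts CSV-identical repeat runs).
* BAR brackets are expanded geometrically around a Widom initial guess; all
  exponentials are max-shifted; hard-overlap sample sets return an infinite
  sentinel rather than overflowing.
* Cluster spanning uses image-vector bookkeeping during BFS: a component
  spans an axis when a member is reachable through two paths whose periodic
  image vectors differ there.  This equals brute-force connectivity on a
  replicated box (tested).
* Shrake–Rupley SASA uses a 960-point golden-spiral lattice; test points
  exactly on a neighbor sphere belong to the lower-index particle, so two
  coincident spheres share one surface instead of double-counting it.
  The powder surface includes interior cavities; waters are treated as
  solvent, not surface.
* Clustering and shell cutoffs for Angstrom-unit data default to the
  literature values 3.5 / 4.3 / 6.3 A; for reduced-unit runs the cutoffs are
  derived from the first minimum of the corresponding radial distribution
  function, mirroring the same convention.
* Block averaging drops trailing remainder elements; five blocks by default.
* Degenerate inputs: empty reverse sample sets fall back to Widom with a
  logged warning; insertion failure in a jammed box raises with the number
  density in the message; branches that do not overlap in h raise rather
  than extrapolate.
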