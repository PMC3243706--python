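# Methods

## The model

`mtsheet` simulates the growing plus end of a microtubule as a
coarse-grained particle system: one point mass of 55 kDa per tubulin
monomer (two per αβ-dimer), 13 protofilaments on a 3-monomer-pitch
helical lattice.  Internal units are nm (length), nN (force), kDa (mass);
energies are nN·nm and converted to thermal units through
k_BT = 4.141×10⁻³ nN·nm (300 K).  One internal time unit is
√(kDa·nm²/nN·nm).

Seven interaction classes act between bonded neighbours, each a harmonic
penalty `E = k/2·(deviation)²` on one geometric deviation:

| class | deviation | k | rest value |
|---|---|---|---|
| longitudinal stretch | axial neighbour distance | 3.0 nN/nm | 4.0 nm |
| lateral stretch | lateral neighbour distance | 14.0 nN/nm | 5.2 nm |
| diagonal stretch | diagonal neighbour distance | 3.0 nN/nm | 5.9988 / 7.1242 nm |
| longitudinal bend | supplement of the chain angle | 2.0 nN·nm | 5° (GTP) / 18° (GDP) |
| lateral bend | supplement of the turn angle | 8.5 nN·nm | 0° |
| longitudinal dihedral | twist of the bending plane vs. the radial plane | 0.04 nN·nm | 0° |
| lateral dihedral | angle between adjacent turn tangent planes | 0.17 nN·nm | 0° |

The diagonal rest lengths follow from the cylinder geometry: radius
R = 13·5.2/2π nm, lateral chord c = 2R·sin(π/13), helical rise
h = 3·4.0/13 nm per lateral step, diagonals √(c² + (4.0∓h)²).  Because
the lateral bend prefers *flat* sheets (tubulin readily forms planar
2-D sheets) while the closed wall forces a 2π/13 turn angle per joint,
every zipped joint stores ≈0.99 nN·nm (≈240 k_BT): the wall is a loaded
spring, and the sheet→tube transition is the loading step.

The seam maps monomer (12, j) to (0, j+3).  Above the zip front the seam
carries no interactions; the lattice there is an open helical ribbon (the
conformational cap).  Closure events add the lateral stretch, bend and
dihedral terms of the lowest open seam pair (diagonal seam terms are
optional and off by default), converting sheet to tube one monomer pair
at a time.

### Nucleotide states

Nucleotide state is tracked per monomer; hydrolysis (GTP→GDP,
irreversible) switches the equilibrium longitudinal bend angle of the
interfaces centred on that monomer from 5° to 18°.  Rules provided:
*synchronous* (everything below the top of the newly closed turn
hydrolyzes with the closure, so the GDP front trails the zip front by one
turn), *ordered cap* (only the top k dimer layers stay GTP), and *random*
(one uniform draw per sheet tubulin, hydrolyze iff draw > threshold).

### Dihedral (twist) terms

Twist angles are measured between a molecular plane and a reference plane
erected on a *radial direction*.  The default convention (`tube_axis`)
takes radial directions from the microtubule axis, which is stored on the
conformation and transforms with it under rigid motions — energies are
therefore frame invariant, while within a fixed frame the axis acts as a
weak external reference that remembers the tubular geometry.  An
alternative fully internal convention (`local_normal`) builds the
reference from the lattice's own bonds; it satisfies exact per-term force
and torque balance but gives a uniformly unrolling sheet no twist
penalty.  The two agree on the closed wall.

Two numerical choices make these terms robust:

* the penalty is `k/2·sin²θ` rather than `k/2·θ²` (identical to O(θ⁴));
  a protofilament held straight has no defined bending plane, and the
  plain angle's gradient diverges there, whereas sin² — a rational
  function of coordinates — is smooth and bounded through the degeneracy;
* normalisation denominators carry small regularisers (1e-12 nm² on unit
  vectors, 1e-2 nm⁴ on the sin² denominators), so exactly degenerate
  geometries evaluate to zero energy and zero force instead of NaN.

Gradients of all angular terms are generated symbolically
(`tools/generate_kernels.py`, a development-time script; the generated
module is committed) and compiled with numba; they match central finite
differences to ~1e-8 relative.

## Relaxation

After every discrete event the conformation is driven to equilibrium by
velocity-Verlet integration (dt = 0.1 internal time units) with velocity
rescaling: each step the velocities are scaled by one scalar so the mean
kinetic energy per monomer equals `kinetic_energy_target` (default
0.5 k_BT).  Equilibrium energies are insensitive to this target (0.03%
spread over 0.005–0.5 k_BT on the standard 520-monomer system); it only
sets the descent speed.  Because constant-kinetic-energy dynamics is
marginally damped (it can orbit a minimum indefinitely), velocities are
additionally zeroed whenever the total power F·v turns negative
(`uphill_reset`, on by default) — a FIRE-style quench that leaves minima
and the transient barrier untouched.  Convergence is declared when the
RMS of the total potential energy over the last ten steps differs from
the RMS over the last twenty by less than 1e-4 nN·nm; relaxed states
reach residual forces ≲0.2 nN and re-relaxing changes the energy by
<1e-3 nN·nm.  Integration without the thermostat conserves
potential+kinetic energy with O(dt²) errors (tested).

## Growth thermodynamics

A trial dimer at the tip of protofilament n changes the total energy by
ΔEₙ = (Eₙ − E₀)/k_BT + ΔG_assoc, where Eₙ is the relaxed equilibrium
energy with the dimer inserted and ΔG_assoc depends only on the lateral
bonds the incomer forms: gap (two sides) −16, side −12, crest −8 k_BT
(bond energies −19 longitudinal, −4 lateral per dimer, +11 k_BT
immobilisation penalty).  Sites with ΔEₙ ≥ 0 cannot fire; among negative
sites one event per step is drawn with probability ∝ exp(−ΔEₙ)
(policy-selectable: an independent-Metropolis variant and a forced-
acceptance mode for bookkeeping studies are provided).  Trial insertions
run on copies and roll back exactly.

A closure records the activation barrier (transient peak of the total
potential energy above the pre-closure equilibrium) and the energy
stepping (difference between successive equilibria), both in k_BT.  The
Tetris loop alternates layer filling (only protofilaments below the
current dimer-layer level are candidate sites, so a completed layer is
exactly 13 dimers) with a one-dimer-length seam advance (two monomer-pair
closures).

## Initial conformation

The closed body is placed on the reference cylinder; sheet monomers start
on a guess surface in which each protofilament bends radially outward by
the GTP intrinsic angle per interface.  The guess is then relaxed
(form-finding); the relaxed state — not the guess — defines the reference
equilibrium E₀.  The relaxed state is independent of the guess details
(a 5°-per-interface flare and a single 5° tilt converge to the same
minimum and energy).

## What the model reproduces, and what it does not

At the study conditions (30-monomer hydrolyzed body per protofilament +
ten-monomer GTP sheet, 520 monomers) the form-found equilibrium has
E₀ ≈ 1.0×10⁵ k_BT, dominated by lateral bending — the stored curvature
energy of the wall.  Successive seam closures are uniform: barriers and
steppings mutually equal within ~8%, stepping ≈ 3.0×10³ k_BT per monomer
pair.  Barrier and stepping are insensitive (≤10%) to the GTP intrinsic
curvature (0°/5°/15°), to the nucleotide composition of the sheet
(half-hydrolyzed, randomly hydrolyzed at threshold 0.5), and to tenfold
changes of either dihedral constant; softening the diagonal stiffness
tenfold raises the barrier by ~30% while leaving the stepping unchanged.

One genuine disagreement with the published account is documented rather
than patched: the converged equilibrium of the open sheet *unrolls*.
With a zero lateral-bend rest angle, a free ribbon anchored at the tube
rim releases ≈1 nN·nm per flattened joint, and the weak dihedral terms
(0.17/0.04 nN·nm) cannot hold the wrap under either radial-reference
convention; the upper sheet becomes a nearly flat paddle.  The seam gap
at the closure pair therefore grows with sheet length (≈8.4 nm for a
1-monomer sheet to ≈10.7 nm at 10) instead of saturating by 4 monomers.
Consequently the closure barrier is ≈5×10⁴ k_BT (the published value,
≈10⁴, corresponds to a ≈7.6 nm gap, i.e. a distinctly more wrapped
sheet), and the barrier-vs-sheet-length curve rises toward a plateau only
around 8–10 monomers, so the derived minimum stable cap computes to 4–5
dimer layers rather than 2.  The likely origin is that published sheet
conformations obtained by marginally damped constant-kinetic-energy
form-finding are incompletely unrolled metastable states; our quenched
relaxation converges to the true minima of the stated potential.  The
corresponding two acceptance tests are intentionally left failing.  A
related symptom: under the default energy-regulated policy a Tetris layer
can stall when the last gap insertions on the unrolled sheet cost more
strain than the association budget; the run then terminates with a stall
diagnostic.

The model has no excluded volume (the unrolled sheet may pass through
the tube's interior unhindered), no thermal fluctuations (temperature
enters only through the kinetic-energy scale and the k_BT conversion),
no dimer dissociation or bond rupture (depolymerisation is out of
scope), and no nucleation stage.

## Problem sizes and determinism

The standard experiment uses the full 520-monomer system; variant and
sensitivity batteries use a 12-monomer body with the same ten-monomer
sheet (barrier and stepping are end-local and insensitive to body
length); unit fixtures are a planar 3×4 grid and 13×N blunt tubes.  All
randomness flows from one seed through per-event-class substreams
(`mtsheet.io.rng_streams`), so identical configuration and seed reproduce
event logs bit-identically; the standard closure experiment consumes no
random draws at all.
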