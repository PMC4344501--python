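# Methods

## The model

A circular DNA molecule of ~3 kb is represented as a closed chain of 334
beads. One bead has diameter 1 sigma_LJ = 3 nm — the effective diameter
of B-DNA under physiological screening — and represents ~9 bp. Energies
are in eps_0 = 1 kT (4 x 10^-21 J); all samplers run at kT = 1.

The Hamiltonian:

* **Excluded volume.** Purely repulsive cut Lennard-Jones between all
  non-bonded bead pairs, truncated at r_cut = 1 sigma where the LJ
  potential crosses zero (the truncation is therefore continuous).
  Periodic systems use the minimum-image convention.
* **Bonds.** Harmonic, k_bond = 800 eps/sigma^2, r0 = 1 sigma. This keeps
  bond-length fluctuations below 3% (sd = 1/sqrt(800) ~ 0.035 sigma).
* **Bending.** Per junction, eps_b (1 - cos theta) with eps_b = 17 eps_0.
  The junction Boltzmann factor gives <cos theta> = coth(kappa) - 1/kappa,
  hence an exponential tangent-correlation decay with persistence length
  L_p = -b / ln<cos theta> = 16.5 beads ~ 49.5 nm, the standard 50 nm of
  double-stranded DNA. (A harmonic-in-theta bending term gives the same
  L_p at this stiffness to within a percent; the 1 - cos form is used
  throughout.)
* **Torsion.** Each bond carries a unit material normal; the frame lives
  at the bond, i.e. midway between consecutive bead centres. The junction
  excess-twist angle phi_i is the signed angle between the
  parallel-transported frame of the incoming bond and the frame of the
  outgoing bond, measured about the outgoing tangent; the energy is
  (k_twist/2) phi_i^2 per junction. k_twist = 31.7 eps/rad^2 per 3 nm
  junction corresponds to a torsional persistence length of ~95 nm.
  This mid-bond-frame construction remains well defined at 90-degree
  bending angles, where naive single-dihedral schemes fail.
* **Enhancer-promoter affinity.** A full (attractive) Lennard-Jones well
  of depth 8 kT between two designated beads half the ring apart
  (167 beads on the 334-bead ring), truncated and shifted to zero at two
  bead diameters so there is no impulsive force at the cutoff. Two sites
  are "in contact" when their centre-centre distance is below 2 sigma
  (surface-to-surface below one diameter).

Supercoiling is imposed topologically: a planar circle (writhe 0) is
given uniform junction twist summing to dLk turns, so the linking-number
deficit Lk = Tw + Wr = dLk holds by construction. dLk = -7 and -14 on
3000 bp at 10.5 bp/turn give supercoiling densities sigma ~ -0.025 and
-0.05 (sigma = dLk / (n_bp / 10.5)).

## Brownian dynamics

Overdamped Euler-Maruyama at kT = 1 with friction gamma = 1 per bead and
dt = 5 x 10^-4 reduced time units (stable at k_bond = 800; the integrator
refuses dt > 10^-3). Each step:

1. forces — bonds, bending, excluded volume, site pair, and the torsional
   force on positions, which is the holonomy gradient of the twist energy
   expressed through the curvature binormal
   (kb)_i = 2 e_{i-1} x e_i / (|e_{i-1}||e_i| + e_{i-1}.e_i)
   (the discrete-elastic-rod construction). The gradient is verified
   against finite differences in the test suite;
2. position update with Gaussian noise of variance 2 dt / gamma;
3. material frames are parallel-transported onto the new tangents. This
   transport is what conserves the linking number: any writhe change of
   the centreline appears as an equal and opposite twist change, and the
   suite asserts |Tw + Wr - dLk| < 0.05 turns along trajectories;
4. torsional Langevin rotation of each frame about its tangent,
   d alpha = (dt/gamma_t) k_twist (phi_{i+1} - phi_i) + noise.

Excluded-volume forces use a brute-force pair loop. At the desk-scale
system sizes this package targets (up to ~1500 beads) the O(N^2) loop in
compiled code is faster than maintaining a cell list under BD's
per-step full-force evaluation; the Monte Carlo sampler, whose moves are
local, does use an incremental cell list (below).

## Equilibrium Monte Carlo

A Metropolis sampler over the same Hamiltonian provides equilibrium
ensembles at a fraction of the BD cost, and serves as the independent
cross-check of the BD integrator (mean bending energies agree within
statistical error in the suite).

Moves are crankshaft rotations of a random contiguous arc about the
chord through its end beads (which preserves all bond lengths — the MC
chain has rigid unit bonds), plus rigid molecule translations in
multi-ring systems and tail rotations for open chains. Two regimes:

* **Topology-preserving (default for supercoiled or multi-molecule
  systems).** Every proposed move displaces every bead by less than
  d_max = 0.8 sigma. Crossing a strand of unit-spaced hard beads
  requires a single-move jump of ~1.4 sigma through the excluded shell,
  so knot and link types cannot change; molecules can neither thread
  one another nor unknot.
* **Unrestricted (dilute, torsionally relaxed single rings).** Arbitrary
  rotation angles. Strand passage is then possible, so the sampler
  targets the full equilibrium including knotted conformations — for a
  20-persistence-length ring of thickness sigma that knotted fraction is
  negligible, and mixing improves by an order of magnitude (asphericity
  autocorrelation time ~7 sweeps instead of ~800).

**Supercoiling.** For a torsionally constrained ring the uniform
harmonic twist is integrated out of White's theorem, leaving the
effective energy (2 pi^2 k_twist / n)(dLk - Wr)^2. The ring writhe is
updated move by move: a crankshaft rotates all affected segments rigidly,
so only changed-versus-unchanged segment pairs contribute, evaluated with
the exact per-pair solid angle. A full writhe recompute every few hundred
sweeps bounds accumulated rounding (tracked and recomputed values agree
to ~1e-8).

**Cell list.** Periodic multi-ring systems bin beads into cells of edge
>= 1 sigma + d_max, so the 27-cell neighbourhood of a moved bead covers
every pair that can enter the interaction cutoff during one move. The
list is updated incrementally on accepted moves and is verified in the
suite to reproduce the full-scan trajectory bitwise.

**Free chains.** For a torsionally unconstrained open chain without
excluded volume the junction angles are independent, so the equilibrium
ensemble is sampled exactly: cos theta is drawn by inverse CDF from
exp(kappa cos theta) on [-1, 1] and tangents are chained with uniform
azimuths. This exact sampler underlies the persistence-length
calibration.

## Crowding protocol

Volume occupancy phi is the bead-sphere fraction of the periodic box,
box edge L = (M n (pi/6) / phi)^{1/3}; 20% approximates the DNA
concentration of a bacterial nucleoid. Planar circles are far larger
than the target box, so crowded states are prepared by slow reduction:
each ring is first equilibrated in isolation to its dilute coil, the
coils are placed on a cubic lattice with clearance, and the box is
shrunk by 0.5% per interval with Metropolis relaxation between shrinks
(a shorter relaxation suffices while the occupancy is still below 2%);
molecule centroids are rescaled, internal coordinates are not. Core
overlaps (< 0.5 sigma) abort the protocol.

Equilibration is detected from per-molecule radius-of-gyration series:
the running tail mean must agree with the final-half mean within one
standard error (estimated from the final-half variance) for every
molecule, on a grid of 5% of the series; a plateau that begins beyond a
quarter of the series raises a not-equilibrated error, and production
runs must exceed eight times the detected equilibration index.

## Analyses

* **Characteristic inertial ellipsoid.** The principal moments
  I1 <= I2 <= I3 of a conformation (equal bead masses, rigid) are matched
  by a hollow ellipsoidal shell, I_a = (m/3)(b^2 + c^2) and cyclic, giving
  a^2 = 3 (I_b + I_c - I_a) / (2m) with a >= b >= c. Asphericity
  A = [(a-b)^2 + (a-c)^2 + (b-c)^2] / [2(a+b+c)^2] (0 for a sphere,
  -> 1 for a thin rod; 0.25 for a rigid planar ring) and prolateness
  P = (2a-b-c)(2b-a-c)(2c-a-b) / [2(a^2+b^2+c^2-ab-ac-bc)^{3/2}]
  (+1 perfectly prolate, -1 perfectly oblate, 0 by convention for a
  sphere). Both depend only on axis ratios, so the shell-versus-solid
  moment convention cancels in them.
* **2D asphericity** for traced planar molecules:
  A = (a - b)^2 / (a + b)^2 with a >= b the principal values of the 2D
  radius-of-gyration tensor (0 isotropic, 1 collinear).
* **Topology.** Writhe by the exact closed-form solid angle of every
  non-adjacent segment pair (equal to the Gauss double integral for a
  polygon; the suite checks it against dense quadrature to 1e-3); twist
  as sum(phi)/2 pi; Lk = Tw + Wr; sigma = Lk / Lk0.
* **Local intra-molecular thickness.** At bead i with tangent t, for
  each azimuth u perpendicular to t the largest sphere of radius rho
  placed tangentially (centre at r_i + (rho + sigma/2) u) that avoids
  every bead outside a +-10-bead exclusion window (and all other
  molecules, by default) satisfies in closed form
  rho(u) = min_j |d_j|^2 / (2 u.d_j) - sigma/2 over obstructions with
  u.d_j > 0. The thickness is t_i = 2 min_u rho(u) + sigma over 36
  azimuths, capped at 2 x 15 sigma + sigma. "Any azimuth" is read as
  for-all (minimum), so one-sided obstruction collapses the thickness;
  two touching strands give exactly one bead diameter. The closed form
  replaces an iterative radius search; an exhaustive grid oracle in the
  suite agrees to < 1e-3.
* **Contacts.** Contact fraction = fraction of sampled frames with site
  distance < 2 sigma, block-averaged for errors. Because spontaneous
  juxtaposition of sites half a ring apart is rare at desk scale, the
  equilibrium fraction is computed by umbrella sampling along the pair
  distance (harmonic windows, WHAM stitching) and exact reweighting of
  the resulting separation density by the Boltzmann factor of the
  attraction. Error bars come from multinomial bootstrap over window
  histograms.

## Desk-scale study conditions

The reference study conditions are 20 molecules of 334 beads per box,
occupancies 0/5/10/20%, dLk in {0, -7, -14}, millions of sampled
configurations — weeks of CPU in this implementation, exposed as the
CLI's `--full` grid profile. The default tests and the acceptance script
use reduced conditions chosen once:

* dilute nicked shape: one 334-bead ring, ~2000 near-independent samples
  (autocorrelation time ~7 sweeps under unrestricted moves);
* crowding response: 6 rings of 167 beads (10 persistence lengths) at
  phi = 0.10 versus dilute, asserting the directional asphericity
  increase — shorter rings relax several-fold faster under the
  topology-preserving moves, while the driving physics (topological
  exclusion between unlinked rings) is unchanged;
* contact ordering: a 100-bead ring at sigma ~ -0.023 versus its nicked
  counterpart, via the umbrella estimator (see the limitation below on
  what this condition can and cannot show).

Passing these desk-scale tests demonstrates the machinery and the
direction of the effects accessible at reduced size, not the full-scale
numbers; the full grid reproduces the reference conditions exactly by
construction.

## What the synthetic fixtures do and do not emulate

Planar/twisted circles, plectonemes of prescribed writhe (the interwound
two-start superhelix obeys Wr = +-2 W sin gamma exactly, inverted so the
requested writhe is hit within discretisation error), ellipsoid shells
realising the hollow-shell moment convention, and parallel-strand probes
give every analysis a ground-truth input without simulation. They do not
emulate thermal roughness, sequence effects, AFM imaging noise, or
branched plectonemes.

## Known limitations

* Two supercoiling effects require the flexible regime (contour length
  many times the persistence length, i.e. the full 334-bead molecule)
  and are *not* reproduced — in fact they reverse — on the short rings
  the desk-scale tests can afford. (i) Contact enhancement between sites
  half a ring apart: a short supercoiled ring is a stiff interwound rod
  whose apices hold the two sites apart (umbrella free energies put
  their juxtaposition far above the nicked control's), whereas the real
  effect relies on slithering registry along a long flexible plectoneme.
  (ii) The higher asphericity of dilute supercoiled versus nicked
  molecules: the short nicked reference is a disc-like stiff ring
  (asphericity near the planar 0.25 limit), so compact writhed shapes
  score *lower*, whereas the 334-bead nicked coil scores ~0.10 and the
  elongated plectoneme above it. Both effects are expected from the
  model at full scale but need the `--full` run lengths.

* The mid-bond material-frame twist is one of several discrete twist
  definitions in use for bead-chain DNA; its correctness here is
  established through conserved quantities (Lk bookkeeping along
  trajectories) and finite-difference force checks rather than
  term-by-term comparison with any particular published discretisation.
* The MC sampler's rigid bonds differ from BD's harmonic bonds;
  observable differences are below statistical resolution in the
  cross-checks but would matter for bond-length-sensitive quantities.
* Crowded-state equilibration at 334 beads is slow under
  topology-preserving local moves; crowded ensemble means at full scale
  should be produced with the `--full` profile and generous run lengths.
* Writhe bookkeeping is exact to ~1e-8 per configuration (arcsin
  conditioning), far below the 0.05-turn tolerance used for topology
  conservation.
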