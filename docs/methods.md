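# Methods

## The model

`ipecsim` simulates the electrostatic co-assembly of oppositely charged
diblock polyelectrolytes and the solubilization of multiply charged,
disk-like porphyrin models into the resulting interpolyelectrolyte-complex
(IPEC) cores, using dissipative particle dynamics (DPD) with explicit
smeared-charge electrostatics.  All quantities are in reduced DPD units:
the interaction cutoff r_c, the bead mass m and the thermal energy kT are
the units of length, mass and energy.

Eight bead species make up the systems:

| species | role | valence |
|---|---|---|
| A+, A- | charged polyelectrolyte monomers | +1 / -1 |
| B | neutral water-soluble block monomer | 0 |
| P | hydrophobic porphyrin ring bead | 0 |
| Pq+ | charged porphyrin periphery bead | +1 |
| CI+, CI- | monovalent counterions / salt | +1 / -1 |
| S | solvent | 0 |

The copolymer is a linear A10B25 diblock (one charge per A bead, net
charge +-10); the porphyrin unit is a rigid, planar assembly of four P
beads on a square (side 0.7 r_c by default) with four Pq+ beads displaced
outward along the diagonals (arm 0.7 r_c), net charge +4.  Counterions
are never a free parameter: each A+ bead brings one CI-, each A- one
CI+, each Pq+ one CI-, and salt enters as CI+/CI- pairs, so every built
system is electroneutral by construction.  Boxes are cubic, periodic,
and filled with solvent to the reference density rho = 3.

### Conservative forces

Non-electrostatic interactions are the standard DPD soft repulsion
F = a_ij (1 - r/r_c) r_hat for r < r_c.  Like-bead repulsion at rho = 3
is a_ii = 25 and unlike pairs map from the Flory parameter through
a_ij = 25 + 3.27 chi, so 25/26.6/39.7 correspond to an athermal, a theta
and a poor solvent.  The default table encodes the calibrated chemistry:
hydrophobic PE backbones (a_AS = 35), marginal solubility of the neutral
block (a_BS = 26), backbone/shell incompatibility (a_AB = 35), mutually
attractive porphyrin rings (a_PP = 18), poorly soluble porphyrin beads
(a_PS = a_PqS = 39), an ion-backbone attraction (a_ACI = 27), and 25
otherwise.  Chains carry harmonic bonds U = k/2 (r - r0)^2 with k = 4,
r0 = 0, whose equilibrium bond length under the soft repulsion is about
0.7 r_c — the length scale used for initial conformations and for the
cluster contact criterion.

### Electrostatics

Point charges are forbidden with soft cores (opposite charges would fall
onto each other), so each unit charge is smeared into a Slater cloud
rho(r) ~ exp(-2r/lambda) with lambda = 0.2 r_c, which localizes 99.7% of
the charge within one bead radius (closed-form radial integral, verified
in the tests).  The two-cloud interaction has the exact form

    U(r) = (Gamma/4 pi) q_i q_j / r * [1 - e^{-2u}(1 + 11u/8 + 3u^2/4 + u^3/6)],
    u = r/lambda,

finite at contact (U(0) = 5 Gamma q_i q_j / (32 pi lambda)) and
point-Coulomb beyond a few lambda.  The dimensionless coupling Gamma
(the prefactor of the reduced Coulomb interaction) defaults to 13.87,
the common room-temperature aqueous parameterization for this smearing
family; it is configurable.

Periodic sums use a classical Ewald decomposition for point charges plus
a short-range real-space correction (point to Slater), which decays as
e^{-10 r} and is negligible at the real-space cutoff (3 r_c minimum).
The splitting parameter and reciprocal cutoff are auto-tuned from a
target relative force accuracy (default 1e-4).  A brute-force validation
oracle sums images over cubic shells with the conducting-boundary dipole
correction, so both routes converge to the same (tinfoil) limit; the
test suite holds them to 0.1% agreement on random neutral charge sets.

### Integration

A modified velocity-Verlet scheme advances the equations of motion:
positions move with the current forces, forces are re-evaluated at
velocities predicted with a factor lambda_vv, and velocities are
corrected with the mean force.  Defaults: dt = 0.04, gamma = 4.5,
sigma = sqrt(2 gamma kT) enforced (fluctuation-dissipation; sigma is
never an independent input), lambda_vv = 0.65 — the prediction factor
recommended in the original DPD literature for sigma = 3, adopted here
because the plain lambda = 1/2 scheme overshoots the set temperature by
a few percent at dt = 0.04.  The test suite verifies that the thermostat
holds a 3000-bead solvent box at kT = 1 within 2% over 10^4 steps at
these settings.

The pair random force draws one noise value per (pair, step) from a
counter-based hash of (seed, step, i, j), so Newton's third law holds
exactly, trajectories are reproducible regardless of iteration order,
and a run can be resumed from a text dump: at every frame checkpoint the
engine canonicalizes its state (wraps coordinates, refits rigid bodies
from the written values, recomputes forces), making the continuation of
a dumped run bit-identical to an uninterrupted one.

Porphyrins are integrated as rigid bodies: forces and torques accumulate
on the center of mass, the orientation matrix advances by a Rodrigues
rotation and is re-orthonormalized every step, and bead coordinates are
regenerated from the body frame.  Intra-body distances are therefore
preserved to machine precision over arbitrarily long runs; the tests
bound the drift at 1e-8 over 10^4 steps.

Neighbor search is a cell-sorted linked-cell pass producing a Verlet
pair list with a 0.3 r_c skin, rebuilt when any bead has moved half the
skin; a brute-force all-pairs oracle in the tests pins the resulting
forces to 1e-10.  Boxes smaller than three cells per edge fall back to
an all-pairs scan.

## Observables

**Associates and aggregates.**  Two molecules belong to the same
associate when any two of their core-forming beads (A+, A-, P, Pq+)
approach within d_cut = 0.7 r_c (the bond-length scale) under minimum
image; single-linkage transitive closure defines the clusters.
Restricting the criterion to core species keeps brushing B-shell
contacts from merging distinct associates.  Porphyrin aggregates use
the same criterion restricted to P/Pq+ beads.  The cutoff is one
configurable parameter used for both purposes; the tests check the
clustering against a brute-force union-find oracle at 0.6-1.0 r_c.

**Association statistics.**  Per frame, every cluster holding at least
one chain contributes its chain count AS (unimers included, porphyrins
counted separately).  Over frames, N(AS) accumulates into number
fractions, weight fractions F_w(AS) ~ AS N(AS), and the number average
<AS>_n.  Time averages discard the first 10% of frames as equilibration
unless overridden.  A porphyrin counts as solubilized (f_P+) when its
cluster also contains a chain.  Core compositions report per-cluster
(n_PE+, n_PE-, n_P+) and the net charge 10 (n_PE+ - n_PE-) + 4 n_P+.

**Radial density profiles.**  For each associate passing an AS filter,
the core center is the center of mass of its core beads after
minimum-image unwrapping (cores spanning more than half the box are
skipped and counted); species densities accumulate in spherical shells
of 0.25 r_c by default and average over associates and frames.  The
distance axis is r in r_c units from the core center, with no
radius-of-gyration rescaling.  Mass conservation (profile integral =
mean per-associate bead count) is enforced in the tests to binning
error.

## Initial states

*Random dispersion*: chains as freely jointed walks (step 0.7 r_c),
porphyrins at uniform random positions/orientations, ions and solvent
uniform; velocities Maxwell at kT = 1 with net momentum removed and
rigid-body beads projected onto exact rigid motion.

*Pre-aggregated associate*: all A blocks packed as confined, outward-
biased random walks inside a central sphere whose radius sets the mean A
density to rho, each chain anchored next to an already placed bead so
the core is one contact cluster by construction (verified, with bounded
deterministic retries); B blocks extend radially outward of the sphere,
compressed to fit the box when necessary.  At step 0 the associate has
AS equal to the chain count and the core sphere contains no B beads.

*Porphyrin insertion*: each inserted unit (plus its four CI-) replaces
twelve solvent beads (total bead count conserved) at a random position
and orientation with every bead at least 1.0 r_c from any polymer bead
— "dissolved in the bulk without touching the associates".

*Cluster fixture*: groups of chains packed on a grid with intra-group
contacts below d_cut and inter-group gaps above 2 d_cut, returning
ground-truth labels for validating the analysis chain.

## What the synthetic conditions do and do not show

The builders generate exactly the study conditions (chain architecture
A10B25, stoichiometric mixtures, explicit ions, rho = 3); the full-scale
experiments use 137+137 chains with 10-120 porphyrins and 10^6-10^7
steps.  The test suite runs the same physics at reduced scale — boxes of
L = 6-10, 6-20 chains, 2-14 porphyrins, 10^3-10^4 steps — chosen so each
scenario resolves its qualitative signature (core-shell segregation,
counterion condensation, aggregation trends with concentration and salt,
quantitative porphyrin uptake) in minutes on one CPU.  Passing these
scaled-down checks demonstrates that the implementation produces the
right physics and trends; it does not reproduce equilibrium constants
or full-scale kinetics (e.g. the <AS>_n plateau values of the large
system), which require the full-length runs.  Trend checks pool frames
over a few fixed seeds; they assert monotone direction with a margin,
not specific values, since individual scaled-down runs fluctuate.

## Numerical choices and degenerate inputs

- Soft conservative force at r = 0 is defined as the zero vector (the
  potential is finite; the direction is undefined).
- The smeared pair force uses a series expansion below r/lambda = 1e-3
  to avoid cancellation; it is exactly 0 at r = 0.
- Ewald requires neutrality and rejects non-neutral charge sets; boxes
  smaller than twice the real-space cutoff shrink the cutoff and retune
  the splitting automatically.
- Cluster identification wraps coordinates before the periodic k-d tree
  query; results are invariant under global translation and rewrapping.
- A step displacing any free bead by more than r_c aborts the run with
  a diagnostic rather than silently producing garbage.
- The box-size floor for the preaggregated builder is the requirement
  that the B brush fit within L/2 (bond spacing is compressed to 0.1 r_c
  before failing).

## Open choices made here

- Porphyrin geometry (square side, arm length) defaults to the bond
  length scale 0.7 r_c; both are configurable recipe keys.
- Box size is a free recipe parameter (the source tables fix only chain
  counts); L = 30 holds the full 274-chain recipe at a polymer volume
  fraction of about 4%.
- Salt amounts are a free recipe parameter swept in the tests.
- RDP centering uses the core center of mass (not the whole-associate
  COM); profiles are insensitive to this for the well-segregated cores
  the tests build.
- The chain-association and porphyrin-aggregation cutoffs are one
  parameter (default 0.7 r_c).

## Known limitations

- No pressure coupling, no GPU/parallel execution; one CPU is assumed.
- The coarse-grained model cannot distinguish J- from H-type porphyrin
  aggregates; only aggregation numbers and geometry are reported.
- Reduced units throughout; no mapping to physical units is provided.
- Exact bit-level reproducibility holds for a fixed platform/compiler;
  across machines, trajectories of chaotic many-body runs may differ in
  the last bit and diverge, which is why stochastic checks assert
  trends and tolerances rather than trajectories.
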