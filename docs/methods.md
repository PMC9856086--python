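# Methods

This note documents the model behind `ringfree`, the choices made where the
design was genuinely open, and what the shipped fixtures do and do not
demonstrate.

## The artifact and its symptom

A *ring penetration* is a bonded atom pair threaded through a small closed
ring so that the bond segment crosses the ring face.  In a classical force
field this configuration is a local minimum: the harmonic bond term grows
quadratically, while the Lennard-Jones wall of the ring grows much faster,
so minimization stretches the bond rather than pulling it through.  The
observable symptom is therefore a bond whose measured length exceeds its
force-field equilibrium length b₀ by an anomalous margin.  A fixed absolute
length threshold (historically 1.65 Å) misfires on bonds to larger
elements, so detection is parameter-aware: a bond is flagged when
`length − b₀ ≥ cutoff`, with `cutoff = 0.4 Å` by default.  The geometric
ground truth — does the segment actually cross a ring face? — is computed
independently by intersecting each bond segment with a fan triangulation of
every small ring (size ≤ 7; larger macrocycles are legitimate chemistry,
not artifacts) about its centroid.  The fan is watertight for planar
aromatics and puckered hexose chairs alike.

## The repair loop

Each *stage* is a bounded minimization (default 500 steps) followed by a
long-bond measurement and a three-way branch:

1. worst deviation ≥ cutoff → **biased round**: select every bond within
   `window = 0.1 Å` of the worst (attacking all long bonds at once is
   unstable for complex tangles; attacking only the worst few is not), then
   attach biases and soft-core flags and minimize again;
2. worst deviation < cutoff after a perturbed stage → **verification
   round**: strip every bias and flag and minimize with the plain
   potential;
3. worst deviation < cutoff after an unperturbed stage → **done**.

Convergence is thus only ever certified by an unbiased, hard-core stage.  A
clean input takes the minimum path — one unperturbed stage, no biases ever
built.  The loop is capped at 100 stages (the verification round counts
against the cap) so termination is guaranteed; hitting the cap returns a
distinct nonzero exit status with all outputs still written.

Per target bond the biased round constructs:

- **perpendicular pulls**: each bond atom is pulled (harmonic, k = 10
  kcal mol⁻¹ Å⁻²) toward its own target 10 Å from the bond midpoint in the
  plane normal to the bond, the two targets on opposite sides.  Opposing
  targets maximize the lateral shear that frees a threaded bond.  The
  in-plane direction is the run's only stochastic element, drawn from the
  seeded generator, so whole runs replay bit-identically for a fixed seed.
- **separation bias**: a one-sided harmonic (k = 10 kcal mol⁻¹ Å⁻²) on the
  distance between the mass-weighted centers of the bond pair and of its
  ring neighborhood (ring atoms within 4 Å of the midpoint, completed to
  bonded depth 2), active only below the 10 Å target — it pushes "up to"
  the target and never pulls back.
- **density hill**: a Gaussian repulsive potential
  `h·exp(−r²/(2σ²))` with h = 20 kcal mol⁻¹ and σ = radius/2 = 2 Å at the
  bond midpoint, exempting the bond's own atoms, which evacuates the
  tangled region.
- **soft-core flagging** of the bond atoms plus everything within 4 Å of
  the midpoint (below).

If the same bond remains the system's longest between successive
iterations, all of its force constants double — `k·2ⁿ` after n repeats —
so stubborn geometries eventually see arbitrarily strong unsticking
forces.  Escalation records key on bond identity and deliberately survive
verification rounds: a piercing that relaxes below the cutoff under the
soft core, fails verification, and re-reveals its long bond resumes its
escalation history instead of restarting.  Bonds that leave the target set
lose their biases and records.

## Energy model

CHARMM-convention bonded terms (`k(b−b₀)²` bonds, `k(θ−θ₀)²` angles,
`k(1+cos(nφ−δ))` dihedrals with multiplicities and wildcard middle-pair
lookup, harmonic impropers), 12-6 Lennard-Jones with
`rmin = rmin_i/2 + rmin_j/2`, `ε = √(ε_i ε_j)`, and Coulomb electrostatics
screened by a relative dielectric (default 80, emulating solvent screening
for vacuum runs).  Nonbonded terms switch smoothly to zero between 10 and
12 Å; there is no periodicity and no mesh electrostatics — repair runs are
non-periodic by construction.  1-2 and 1-3 pairs are excluded; 1-4 pairs
interact at full strength (special 1-4 parameter tables and NBFIX are
omitted; the fixtures are built to be insensitive to this).  Urey-Bradley
and cross-term corrections are likewise omitted — a documented limitation
for quantitative energetics on real CHARMM36m inputs, irrelevant to the
geometry of artifact removal at fixture scale.

**Soft core.**  Every nonbonded pair with at least one flagged atom
interacts at the effective distance `r_eff = √(r² + δ²)` (both LJ and
Coulomb), which is finite at r = 0 and lets tangled atoms pass through one
another.  This is a single "coupled-but-softened" state with one
parameter — the loop needs a softened landscape, not an alchemical free
energy, so no coupling schedule exists.  The default is δ = 2.5 Å: at
carbon-carbon contact (rmin ≈ 4 Å) this caps the pair energy near
20 kcal mol⁻¹, which a stretched-bond spring (k_b ≈ 220 kcal mol⁻¹ Å⁻²
at ~0.5 Å of stretch) can push through.  Substantially smaller δ leaves
multi-thousand-kcal walls at ring-contact distances and the loop cycles
without ever unthreading; δ → 0 recovers the standard potential exactly
(verified as a property test).

**Minimizer.**  Polak-Ribière(+) conjugate gradient with an Armijo
backtracking line search and a per-step displacement cap (0.2 Å for the
first trial step).  Non-finite trial energies are treated as rejected
steps, so the line search backtracks out of overlaps instead of aborting.
The method is fully deterministic; the accepted-step energy trace is
non-increasing by construction.  Termination is by step budget or by
gradient tolerance (max |∇E| < 10⁻⁴ kcal mol⁻¹ Å⁻¹ by default, which also
covers a stalled line search at the numerical floor).  Forces for every
term — including all biases and restraints — are exact gradients, checked
against central differences at 10⁻⁴ relative tolerance in the suite.

## Chirality preservation

Biased stages apply large forces and the soft core lets atoms
interpenetrate, so stereocenters can silently invert — and an inverted
sugar is far harder to spot afterwards than a stretched bond.  By default
every *potential* stereocenter is restrained: any atom with exactly four
bonded neighbors whose branches are pairwise distinguishable at the first
shell (neighbor type plus the types around it).  This over-includes
relative to full priority-rule perception, which is safe — a restraint on
a non-center is harmless, a missed center is not.

The restrained coordinate is the dihedral of the four index-ordered
substituents.  The measured chirality sign is the sign of the substituent
tetrahedron's volume, `sign(det[r₂−r₁, r₃−r₁, r₄−r₁])`, which involves
only the substituents; a restraint built on the center plus three
substituents leaves the fourth free to swing through the plane (observed
directly: two glyco-toy stereocenters inverted under a default repair with
center-based restraints), so the restraint is placed on exactly the four
atoms whose rearrangement defines the sign.  Each restraint is harmonic
(`k_chi = 50 kcal mol⁻¹ rad⁻²` by default) and targets the dihedral
*measured in the input structure*: the tool preserves the stereochemistry
it was given, it never imposes an idealized one.  Restraints are generated
once, from the input coordinates, and stay active through biased and
verification stages alike.

## Fixtures: what they emulate and what they do not

All fixtures are generated programmatically, validate their own manifests
against the geometric oracle at build time, and resolve completely against
an embedded minimal parameter set (aromatic/aliphatic carbon,
hydroxyl/ether/glycosidic oxygen, amide nitrogen, carbonyl; chemically
reasonable k, b₀, θ₀, LJ values) that round-trips through the real
parameter parser.  A 0.02 Å seeded jitter breaks the constructions' exact
symmetries so the deterministic minimizer never starts on a saddle point.

- **Pierced benzene-ethane** (20 atoms): an aromatic six-ring with a
  two-carbon bond threaded through its centroid, built 0.57 Å over
  equilibrium.  Plain minimization *increases* the stretch (to ≈ 1.7 Å)
  while the piercing persists — the canonical local minimum.
- **Toy polymer** (5 para-linked aromatic units, CH₂ linkers, 64 atoms):
  three linker bonds threaded through rings two units down the chain, each
  engineered by rigidly repositioning the downstream remainder of the
  chain and scanning a deterministic set of orientations until the oracle
  confirms exactly the intended count.  Emulates a tangled polymer with
  multiple simultaneous piercings.
- **Glyco-peptide toy** (3 residues, two hexopyranose-like chairs,
  75 atoms, 11 detected stereocenters): one sugar ring threaded by the
  other glycosylated side chain's CB-OG bond.  Emulates carbohydrate
  chains tangled with a protein backbone, where stereochemistry matters.
- **Strained variant** of the glyco toy: both glycosidic attachments are
  tilted toward their ring planes (strain parameter 1.4 on the
  interpolation from the ideal tetrahedral link direction toward the ring
  plane — within the band where the center remains unambiguously chiral
  but poised).  An unrestrained repair run inverts at least one anomeric
  center; the default restrained run preserves every sign.  The deliberate
  strain is extreme by construction, and the default restraint strength is
  a balance, not a guarantee: a sufficiently unlucky bias direction can
  overcome k_chi = 50 on this fixture, which is precisely why it serves as
  the adversarial demonstration.

What passing on these fixtures does **not** show: performance or energetic
accuracy on real force fields (no 1-4 scaling, Urey-Bradley, or CMAP), nor
convergence behavior at the scale of multi-million-atom assemblies, where
many piercings interact and runs take many more cycles.  The fixtures
establish the logic of the loop — detection, branch control, bias
escalation, certified convergence, stereochemistry preservation — at sizes
(≤ 500 atoms) where every claim can be verified by independent oracles in
seconds.

## Numerical choices and degenerate inputs

- Ties for the longest bond break on the smaller atom-index pair;
  deviation is signed but only stretching is ever flagged.
- The worst-bond selection window is closed at its boundary
  (`deviation ≥ max − window`).
- Segment/triangle intersection uses the plane-crossing sign test plus
  barycentric coordinates with a 10⁻⁹ inclusive slack (watertight across
  fan edges; in-plane segments do not count as crossings); triangles with
  area ≤ 10⁻⁸ Å² are rejected as degenerate.
- Stereocenters whose substituents are coplanar within 10⁻⁶ Å³ have no
  sign and raise a typed error; centers that are planar as built are
  skipped at detection time.
- The separation bias carries a seeded fallback direction for the
  measure-zero start where both centers coincide exactly (a symmetric
  pierced geometry), where the distance gradient is undefined.
- Ring enumeration is a minimum cycle basis (smallest set of smallest
  rings) filtered to size ≤ 7, each cycle ordered into a bonded walk and
  canonicalized (smallest member first, smaller neighbor second), so all
  downstream geometry is deterministic.
- Run configs are flat key-value YAML; unknown keys warn rather than fail,
  missing required keys fail naming themselves, and paths resolve relative
  to the config file.

## Problem sizes and determinism

The shipped test suite and the acceptance script run the complete loop on
all fixtures (plus restrained/unrestrained pairs) in about a minute on one
CPU; individual repair runs converge in 3-5 stages of 500 steps.  With a
fixed seed, two runs on identical inputs produce identical traces and
final coordinates, even though the perpendicular-pull directions are
random variables of the seed.
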