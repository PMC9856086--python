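# ringfree

Detect and repair **ring-penetration artifacts** in biomolecular simulation
systems.

When complex systems are assembled from pieces — polymers inflated from
optimized fragments, docked capsid subunits, glycans grafted onto a protein —
a bond sometimes ends up threaded through a small ring (an aromatic or a
hexose).  For a classical force field this *pierced ring* is a local energy
minimum: stretching the threaded bond far past its equilibrium length is
cheaper than forcing atoms through the ring's Lennard-Jones wall, so plain
minimization can never fix it.  The symptom is a **long bond**; the cause is
a geometric threading; the cure is an iterative loop of *biased, soft-core
minimizations* that shears the bond out of the ring while preserving
stereochemistry.

`ringfree` implements the full workflow for CHARMM-format inputs
(PSF/PDB/PRM):

- **Detection.** Per-bond deviation `d = b − b₀` against the force-field
  equilibrium length; bonds with `d ≥ 0.4 Å` are flagged, and each iteration
  targets every bond within `0.1 Å` of the worst one.  A geometric oracle
  (segment/ring-face intersection over a fan triangulation) confirms actual
  piercings, and stereocenters are inventoried from the topology.
- **Repair.** For each target bond: the two atoms are pulled toward opposite
  points 10 Å away in the plane perpendicular to the bond; a one-sided
  harmonic pushes the mass-weighted centers of the bond and its ring
  neighborhood apart (up to 10 Å); a Gaussian repulsive hill evacuates the
  tangled region; and all nearby atoms become *soft-core*
  (`r_eff = √(r² + δ²)`) so they can pass through each other.  If the same
  bond stays the longest between iterations, all of its bias force constants
  double (`k·2ⁿ` after n repeats).
- **Certification.** Convergence (worst deviation < 0.4 Å) only counts when
  measured after a stage with *no* biases and *no* soft core; the loop is
  capped at 100 stages of 500 minimization steps.  Chirality is protected
  throughout by harmonic restraints on each stereocenter's substituent
  dihedral, targeted at the input geometry.

The package ships deterministic pierced test systems (a benzene ring with an
ethane threaded through it, a para-linked aromatic polymer with engineered
piercings, a glycosylated peptide toy) with an embedded minimal parameter
set, so everything runs self-contained.

## Worked example

```python
from ringfree import fixtures, RunConfig, run_lbe, find_piercings
from ringfree.stretch_detect import bond_deviations, largest_deviation

bundle = fixtures.make_pierced_benzene_ethane()
print(len(find_piercings(bundle.system)))          # 1  (the threaded C-C)

result = run_lbe(RunConfig(seed=1), system=bundle.system, params=bundle.params)
for row in result.state.trace:
    print(row.stage, row.bond, round(row.deviation, 3))
print(len(find_piercings(result.system)))          # 0
```

prints

```
1
0 (12, 13) 0.518
1 (12, 13) 1.667
2 (12, 13) 0.234
3 (4, 5) 0.029
0
```

Row 0 is the as-built structure: the ethane C–C (atoms 12–13) is 0.518 Å
longer than its 1.53 Å equilibrium.  Stage 1 (plain minimization) makes it
*worse* — 1.667 Å of stretch — because the minimizer presses the two carbons
against opposite faces of the ring: the classic pierced-ring local minimum.
Stage 2 runs with biases and soft core and frees the bond (0.234 Å); stage 3
re-minimizes with the plain potential and certifies convergence, after which
the worst bond in the whole system is an aromatic C–C within 0.03 Å of
equilibrium and the geometric oracle finds no piercing.

The same loop is available from the shell:

```bash
ringfree fixtures --name benzene-ethane --out demo/
ringfree detect demo/benzene-ethane.yaml     # report long bonds + piercings
ringfree fix demo/benzene-ethane.yaml        # run the repair loop
ringfree trace demo --label benzene-ethane   # longest-bond trace table
```

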