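# Methods

## The model

`swdock` performs rigid-body Monte Carlo ensemble docking of all-atom
protein structures.  Two units (monomers, or pre-formed dimers in
tetramer mode) are docked repeatedly from random mutual orientations;
each run produces one optimized complex, and the collection of complexes
is analyzed statistically.  The interface energy of a pose is

    U = sum over intermolecular atom pairs (i, j) of
        U_H(r_ij) + U_EL(r_ij) + U_HP(r_ij)

with three piecewise-constant (square-well) pair potentials, all
expressed in *h-bond units* — the depth of one hydrogen bond is −1 and is
calibrated to 3 kcal/mol:

* **Hydrogen bond** `U_H`: −1 for `sigma <= r < 3.2 Å` between a donor
  (N/O/S bearing a covalently bonded hydrogen) and an acceptor (any O or
  S; template nitrogens such as neutral His ND1/NE2 when they carry no
  hydrogen).  `sigma` is the sum of the two van der Waals radii, the
  hard-core distance.  Distance is the only criterion; no angular term.
* **Electrostatics** `U_EL`: a double well between formally charged
  atoms: magnitude 0.4 for `sigma < r < 1.4 sigma`, 0.12 for
  `1.4 sigma <= r < 2.3 sigma`, zero beyond.  0.4 is the median
  salt-bridge free-energy gain at a protein surface (1.2 kcal/mol)
  normalized by the h-bond energy (3 kcal/mol); the outer well is 30% of
  the inner.  The sign is positive (repulsive) for like charges,
  negative for opposite charges.
* **Hydropathy** `U_HP`: for two side-chain heavy atoms of the same
  hydropathy class within 160% of their summed vdW radii,
  `U_HP = HP_i + HP_j` with `HP_t = −s_t × SASA_t / n_t` normalized to
  the h-bond energy.  `s_t` is the atomic solvation parameter of type
  `t` (C +18, neutral N/O −7, N⁺ −34, O⁻ −20, S +18 cal Å⁻² mol⁻¹),
  `SASA_t` a per-type reference solvent-accessible area, and `n_t ≈ 2` a
  neighbor-count estimate.  Hydrophobic pairs (carbon, sulfur) attract,
  hydrophilic pairs repel; mixed pairs are excluded by default (a config
  flag enables the signed sum).

Pairs closer than `sigma` are **clashes**: they contribute no well energy
but are counted, and the Monte Carlo objective is
`F = U + clash_weight × n_clashes` (default weight 1 h-bond unit per
clashing pair), so the search is simultaneously pressed toward minimal
energy and minimal overlap.  All wells are half-open `[lower, upper)`;
the h-bond well includes `r = sigma`, the electrostatic wells exclude it.
Hydrogens participate only in donor detection and clash counting — the
solvation table has no hydrogen type and charges sit on heavy atoms.

### Reference SASA table

The solvation parameters constrain, but do not fix, the per-type
reference areas.  The packaged values (C 36, N/O 100, N⁺ 20, O⁻ 36,
S 40 Å²) are chosen so that every normalized magnitude |HP_t| falls in
the interval [0.1, 0.4] h-bond units (the C and N⁺ entries give
HP = −0.108 and +0.113 respectively).  The table is plain config and can
be overridden wholesale.

## Protonation and atom typing

Structures must be all-atom (explicit hydrogens); hydrogen-free input is
rejected unless the caller opts into template-based donor detection.
Titratable groups are assigned formal charge signs from a pKa table at
the run pH: bases (His, Lys, Arg, N-terminus) are +1 on their charged
moiety atoms when pH < pKa, acids (Asp, Glu, free Cys, C-terminus) are −1
when pH > pKa.  Packaged default pKa values (Asp 3.9, Glu 4.2, Cys 8.3,
His 6.0, Lys 10.5, Arg 12.5, N-ter 8.0, C-ter 3.6) apply when the user
table — e.g. one derived from constant-pH simulations — has no entry for
a residue.  Disulfide-bonded cysteines (SG–SG < 2.5 Å) never titrate.
Only formally ionized groups carry nonzero signs; partial-charge signing
of all atoms is deliberately out of scope, keeping the electrostatic term
to its dominant, unambiguous contributions.

Donor hydrogens are inferred geometrically: a hydrogen bonds to the
nearest heavy atom within 1.25 Å (1.45 Å when that atom is sulfur, since
S–H bonds are longer); a hydrogen with no such neighbor is an error
(orphan).  Van der Waals radii come from a Bondi-style element table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å), user-overridable; every
cutoff scales with sigma, so the radius choice is transparent.

## The search

One unit is fixed with its geometric center at the origin.  The mobile
unit starts at a uniformly random orientation on a uniformly random
direction (the *docking axis*) at a center separation equal to the sum of
the two bounding radii (measured to atom surfaces) plus 2 Å — guaranteed
clash-free.  Each Monte Carlo step proposes, with equal probability,
either a rotation of the mobile unit about its own center (angle uniform
up to `rot_max`, default 15°) or a translation along the docking axis
(displacement uniform within ±`trans_max`, default 1.5 Å).  Because
rotations preserve the center and translations stay on the center line,
the mobile center remains on its initial ray for the whole run — each run
explores one random encounter direction, and directional diversity comes
from the ensemble.  The separation is bounded above by its initial value
(a reflecting wall) so the walker cannot drift away along the flat
zero-energy plateau.

Acceptance is Metropolis on F with geometric cooling from `t_start`
(default 2.0) to `t_end` (default 0.05) h-bond units over `n_steps`
(default 50 000).  The returned complex is the best-F pose visited, with
its pure interface energy U, contact and clash counts, and the full
per-pair interaction list.  `MCSchedule.n_restarts` optionally splits the
step budget into independent annealing cycles (fresh axis and orientation
each) keeping the global best; the default of 1 preserves the
one-encounter-per-run semantics, while restarts > 1 turn a run into a
small basin-hopping search — useful when a single optimized complex,
rather than an encounter ensemble, is wanted.  Empirically the success of
a cycle is limited mostly by its approach ray, not by chain length, so
restarts improve hard landscapes where longer chains do not.

`ensemble_dock` draws conformer pairs uniformly with replacement from the
two pools, derives a per-run seed from the master seed with a
counter-based splitter (results are independent of execution order), and
appends complexes until the running mean and standard deviation of the
binding energy are both stable: |Δmean| and |Δstd| over the last `window`
(default 50) additions below `tol` (default 0.02) × current std, with at
least the target minimum of members, or until the target maximum
(defaults 1000–1500 for dimers, 1000 for tetramers).  Tetramer mode is
the same call with pools of dimers re-read as rigid units.

## Ensemble statistics

* **Binding-energy density**: Gaussian KDE with Silverman bandwidth
  (overridable) on a uniform grid spanning the sample range ± 3
  bandwidths; the mode `E_M` is the grid argmax, and a zero-variance
  sample degenerates to a point mass at the common value.
* **Contact probability map**: a residue–residue contact exists in a
  member when at least one qualifying atom pair of those residues is
  within its type-specific cutoff (clashes never qualify); multiple atom
  pairs count once per member; the map entry is the member count divided
  by the ensemble size.
* **Hot-spots**: contacts ranked by ensemble frequency (ties broken by
  ascending residue identifiers), the top 50 retained; each residue's
  hot-spot probability is the fraction of members in which it
  participates, on either side of the interface, in at least one of those
  top contacts.  Per-member participation is used because it gives the
  probability a single, clear sample space; a per-contact averaging
  variant is computable from the same map.
* **Representative conformer**: the member whose binding energy is
  nearest `E_M` (ties to the earliest member).

Residues are identified as `chain:number` with the author numbering of
the source PDB.

## Synthetic structures

The fixture generator builds idealized polypeptides: a planar zig-zag
backbone (bond lengths N–CA 1.46, CA–C 1.52, C–N 1.33, C=O 1.23, N–H
1.0 Å; ±30° alternation), schematic side chains for ten residue types
raised out of the backbone plane on alternating sides, polar hydrogens
only, and an optional in-plane curl ("blob") for compact shapes.  A
planted patch rewrites a chosen residue range to a donor, charged or
hydrophobic type with known ground truth.  These toys are chemically
plausible (bond lengths within 10% of standard, no internal clashes) but
carry no real secondary structure, rotamers, packing density or
conformational diversity — tests passing on them validate the energy
bookkeeping, the search machinery and the statistics, not biological
realism of predictions on real proteins.

Three independent oracles back the test suite: a naive all-pairs double
loop for the interface energy (the accelerated KD-tree and jitted
evaluations must match it to 1e-9; totals use compensated summation so
swapping the two units is exactly symmetric), an exhaustive 6-DOF grid
search (capped at 10⁷ poses) for the docking optimum, and
planted-contact ensembles with known hot-spots for the analysis layer.

## Problem sizes and numerical choices

The default test and demonstration scales are chosen for a single CPU:
toy monomers of 4–55 residues, ensembles of tens to ~100 members with
2 000–45 000 MC steps per run, grid oracles at 0.5–1.0 Å / 45–60°
resolution.  The convergence tolerance/window defaults (0.02 / 50) are
engine defaults, not claims about any particular system; looser
tolerances are appropriate for small demonstration ensembles whose
binding-energy spread is wide.  Boundary conventions (half-open wells),
tie-breaks (earliest member, ascending residue identifiers) and the
highest-occupancy altloc rule are fixed so that every pipeline output is
bit-reproducible from (inputs, config, master seed).

## Known limitations

* Rigid bodies only: no side-chain repacking, no relaxation; force-field
  post-processing of ensembles is an external step by design.
* Translations confined to the encounter ray make a single run a local
  optimizer around one approach direction; statistics are meaningful at
  the ensemble level (or with restarts).
* The square wells have no angular terms, so h-bond counts are upper
  bounds relative to geometry-aware definitions.
* The electrostatic term sees only formal charges at fixed protonation;
  no dielectric screening, no titration coupling between partners.
* Toy fixtures do not emulate real folds or conformational ensembles;
  conclusions about real systems require user-supplied conformers.
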