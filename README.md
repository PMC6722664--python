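# swdock — square-well Monte Carlo ensemble docking

`swdock` is a rigid-body protein–protein docking engine for studying the
*statistics* of protein association — which regions of two molecules
stick together, how strongly, and which residues act as hot-spots that
nucleate dimerization and aggregation.  It was built for the
aggregation-modelling setting (e.g. amyloidogenic variants of
beta-2-microglobulin, where one asks how folding intermediates at a given
pH self-associate into dimers and dimers into tetramers), but it runs on
any all-atom PDB conformers.

Instead of producing a single "best" complex, the engine docks many
randomly paired, randomly oriented conformers and analyzes the resulting
ensemble: the probability density of the binding energy and its mode
`E_M`, an intermolecular probability map (IPM) of every residue–residue
contact, and per-residue hot-spot probabilities within the most frequent
contacts.

## The cost function

The interface energy of a pose sums three square-well pair potentials
over all intermolecular atom pairs (Å for distances; energies in
*h-bond units*, one hydrogen bond = −1 ≙ 3 kcal/mol):

| term | pairs | wells |
|------|-------|-------|
| hydrogen bond | donor–acceptor (D, A ∈ {N, O, S}; D carries an H) | −1 for σ ≤ r < 3.2 Å |
| electrostatic | formally charged atoms at the run pH | ±0.4 for σ < r < 1.4σ, ±0.12 for 1.4σ ≤ r < 2.3σ |
| hydropathy | like-class side-chain heavy atoms | HP_i + HP_j for r < 1.6 (r_i + r_j) |

σ is the sum of the two van der Waals radii (the hard core); pairs with
r < σ are clashes, counted and penalized in the Monte Carlo objective
`F = U + n_clashes`.  Per-atom hydropathy values are
`HP_t = −s_t·SASA_t/n_t`, normalized so one h-bond = 1; with the packaged
atomic solvation parameters (C +18, N/O −7, N⁺ −34, O⁻ −20,
S +18 cal Å⁻² mol⁻¹) every |HP_t| lies in [0.1, 0.4].  Protonation of
titratable groups is assigned from pKa values (user-supplied, e.g. from
constant-pH simulations, with packaged defaults) at the chosen pH.
See `docs/methods.md` for the full model.

## Worked example

Dock two 20-residue synthetic monomers (no input files needed) and
analyze the ensemble:

```python
from swdock import (
    EnergyParameters, FixtureSpec, MCSchedule, make_toy_unit, prepare_unit,
    ensemble_dock, binding_energy_density, hotspot_probabilities,
    representative_conformer,
)

params = EnergyParameters()
monomer_a = prepare_unit(
    make_toy_unit(FixtureSpec(n_residues=20, seed=1, geometry="blob")),
    ph=7.2, params=params)
monomer_b = prepare_unit(
    make_toy_unit(FixtureSpec(n_residues=20, seed=2, geometry="blob")),
    ph=7.2, params=params)

ensemble = ensemble_dock(
    [monomer_a], [monomer_b], params, MCSchedule(n_steps=8000),
    target=(30, 60), tol=0.1, window=15, rng_seed=7, ph=7.2)

density = binding_energy_density(ensemble)
hotspots = hotspot_probabilities(ensemble, subset_size=50)
rep = representative_conformer(ensemble, density)
print(f"members: {len(ensemble.members)}  converged: {ensemble.converged}")
print(f"mode E_M: {density.mode:.2f} h-bond units")
print(f"representative complex: U = {rep.binding_energy:.2f}, "
      f"{rep.n_contacts} contacts, {rep.n_clashes} clashes")
for residue, p in hotspots.ranked()[:3]:
    print(f"  {residue}  P = {p:.2f}")
```

Output (about two minutes on one CPU):

```
members: 38  converged: True
mode E_M: -8.10 h-bond units
representative complex: U = -7.87, 38 contacts, 2 clashes
  A:3  P = 0.47
  A:5  P = 0.39
  A:7  P = 0.39
```

The ensemble converged at 38 members (running mean and spread of the
binding energy stable); the most likely binding energy is about −8
h-bond units (≈ −24 kcal/mol on the calibration scale); residue 3 of the
first monomer participates in a top-50 contact in 47% of complexes — the
leading hot-spot of this toy interface.

The same pipeline runs from the shell on directories of PDB conformers:

```bash
swdock fixtures --spec fixtures.yaml --out toys/           # optional toys
swdock dock --fixed-pool poolA/ --mobile-pool poolB/ \
            --ph 7.2 --seed 7 --out ensemble.pdb
swdock analyze --ensemble ensemble.pdb \
               --energies ensemble.energies.tsv --top 50 --out analysis/
```

`dock` writes a multi-model PDB (one MODEL per complex, binding energy in
REMARK lines) plus a TSV of energies/contacts/clashes; `analyze` writes
the density table, the IPM matrix, the ranked hot-spot table and the
representative conformer.  `--mode tetramer` docks pre-formed dimers as
rigid units.

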