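# Default parameter tables for the square-well docking model.
# Every value here can be overridden by a user config file.

# Element van der Waals radii, Angstrom (Bondi-style).
vdw_radii:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  H: 1.20

# Atomic solvation parameters s_t, cal A^-2 mol^-1.
# Types: C (apolar carbon), N/O (neutral polar N or O), N+ (cationic N),
# O- (anionic O), S (sulfur).
solvation:
  C: 18.0
  N/O: -7.0
  N+: -34.0
  O-: -20.0
  S: 18.0

# Reference solvent-accessible surface areas per atom type, A^2, chosen so
# that the normalized per-atom hydropathy magnitudes |HP_t| fall in [0.1, 0.4].
sasa:
  C: 36.0
  N/O: 100.0
  N+: 20.0
  O-: 36.0
  S: 40.0

# Default pKa values used when a residue has no entry in a user pKa table.
# NTER / CTER are the chain termini.
pka_defaults:
  ASP: 3.9
  GLU: 4.2
  CYS: 8.3
  HIS: 6.0
  LYS: 10.5
  ARG: 12.5
  NTER: 8.0
  CTER: 3.6

# acid: carries -1 on the moiety atoms when pH > pKa
# base: carries +1 on the moiety atoms when pH < pKa
titration_rules:
  ASP: acid
  GLU: acid
  CYS: acid
  HIS: base
  LYS: base
  ARG: base
  NTER: base
  CTER: acid

# Atoms that carry the formal charge of each ionized group.
charge_moieties:
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
  CYS: [SG]
  HIS: [ND1, NE2]
  LYS: [NZ]
  ARG: [NE, NH1, NH2]
  NTER: [N]
  CTER: [OXT, O]

# Nitrogen atoms treated as h-bond acceptors when they carry no hydrogen.
acceptor_nitrogens:
  HIS: [ND1, NE2]
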