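"""Square-well pair potentials and the rigid-interface energy function.

The cost function combines three piecewise-constant intermolecular
potentials evaluated on donor/acceptor, charged and hydropathy-typed atoms:

* hydrogen bond: a single attractive well of unit depth between the
  hard-core distance ``sigma`` (sum of the two van der Waals radii) and a
  3.2 Angstrom cutoff;
* electrostatics: a double well between charged groups, magnitude
  ``e_el1`` for ``sigma < r < 1.4 sigma`` and ``e_el2`` for
  ``1.4 sigma <= r < 2.3 sigma``, repulsive for like signs and attractive
  for opposite signs;
* hydropathy: below 160% of the summed van der Waals radii, two
  hydrophobic (hydrophilic) side-chain atoms contribute the sum of their
  per-atom hydropathy values, which is negative (positive).

All energies are expressed in "h-bond units": the depth of one hydrogen
bond is -1 and is calibrated to 3 kcal/mol.  Pairs closer than ``sigma``
are clashes; they contribute no well energy but are counted and penalized
by the Monte Carlo objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._data import load_defaults

__all__ = [
    "EnergyParameters",
    "PairInteraction",
    "hbond_energy",
    "electrostatic_energy",
    "hydropathy_parameter",
    "hydropathy_energy",
    "interface_energy",
    "max_interaction_cutoff",
]

# hydropathy class codes shared with the numba kernel
HP_NONE, HP_PHOBIC, HP_PHILIC = 0, 1, 2


@dataclass
class EnergyParameters:
    """Every constant of the triad cost function.

    Defaults reproduce the published model: unit-depth h-bond well up to
    3.2 A calibrated to 3 kcal/mol, first electrostatic well calibrated to
    the 1.2 kcal/mol surface salt-bridge free energy (0.4 h-bond units),
    second well at 30% of the first, wells spanning sigma..1.4 sigma..2.3
    sigma, and a hydropathy cutoff at 1.6x the summed vdW radii.
    """

    e_hb: float = -1.0
    hb_cutoff: float = 3.2
    e_hb_kcal: float = 3.0
    salt_bridge_kcal: float = 1.2
    e_el1: float | None = None
    e_el2: float | None = None
    el_well1_scale: float = 1.4
    el_cutoff_scale: float = 2.3
    hp_cutoff_scale: float = 1.6
    solvation_table: dict = field(default_factory=dict)
    sasa_table: dict = field(default_factory=dict)
    n_t: float = 2.0
    clash_weight: float = 1.0
    # include hydrophobic-hydrophilic cross pairs in the hydropathy sum
    mixed_hydropathy: bool = False

    def __post_init__(self) -> None:
        defaults = load_defaults()
        if not self.solvation_table:
            self.solvation_table = dict(defaults["solvation"])
        if not self.sasa_table:
            self.sasa_table = dict(defaults["sasa"])
        if self.e_el1 is None:
            self.e_el1 = self.salt_bridge_kcal / self.e_hb_kcal
        if self.e_el2 is None:
            self.e_el2 = 0.3 * self.e_el1
        if self.hb_cutoff <= 0:
            raise ValueError("hb_cutoff must be positive")
        if not self.el_cutoff_scale > self.el_well1_scale > 1.0:
            raise ValueError("need el_cutoff_scale > el_well1_scale > 1")

    @classmethod
    def from_config(cls, mapping: dict | None) -> "EnergyParameters":
        """Build parameters from a (possibly partial) config mapping."""
        mapping = dict(mapping or {})
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown energy parameters: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PairInteraction:
    """One intermolecular atom pair contributing to the interface."""

    i: int  # atom index in the fixed/first unit
    j: int  # atom index in the mobile/second unit
    kind: str  # hbond | electrostatic | hydropathy | clash
    r: float
    sigma: float
    energy: float
    res_a: str = ""  # residue identifier "chain:number" on the first unit
    res_b: str = ""
    atom_a: str = ""
    atom_b: str = ""


def hbond_energy(r: float, sigma: float, params: EnergyParameters) -> float:
    """Hydrogen-bond square well for a donor-acceptor pair.

    Returns ``e_hb`` (default -1) for ``sigma <= r < hb_cutoff`` and 0
    beyond the cutoff.  The hard-core region ``r < sigma`` is a clash and
    is scored by the pair dispatcher, not here; if ``sigma >= hb_cutoff``
    the attractive well is empty.
    """
    if r < 0:
        raise ValueError("negative distance")
    if sigma <= r < params.hb_cutoff:
        return params.e_hb
    return 0.0


def electrostatic_energy(
    r: float, sigma: float, sign_i: int, sign_j: int, params: EnergyParameters
) -> float:
    """Double square well between two formally charged atoms.

    Magnitude ``e_el1`` in the first well (``sigma < r < 1.4 sigma``) and
    ``e_el2`` in the second (``1.4 sigma <= r < 2.3 sigma``); positive for
    like charges, negative for opposite charges.
    """
    if r < 0:
        raise ValueError("negative distance")
    if sign_i == 0 or sign_j == 0:
        raise ValueError("electrostatic_energy requires nonzero charge signs")
    s = 1.0 if sign_i * sign_j > 0 else -1.0
    if sigma < r < params.el_well1_scale * sigma:
        return s * params.e_el1
    if params.el_well1_scale * sigma <= r < params.el_cutoff_scale * sigma:
        return s * params.e_el2
    return 0.0


def hydropathy_parameter(atom_type: str, params: EnergyParameters) -> float:
    """Normalized per-atom hydropathy value HP_t, in h-bond units.

    HP_t = -s_t * SASA_t / n_t with s_t in cal A^-2 mol^-1 and SASA_t in
    A^2, converted to kcal/mol and normalized by the h-bond calibration
    energy.  Hydrophobic types (s_t > 0) get negative HP_t.
    """
    try:
        s_t = params.solvation_table[atom_type]
        sasa_t = params.sasa_table[atom_type]
    except KeyError as exc:
        raise KeyError(f"unknown hydropathy atom type: {atom_type}") from exc
    kcal = -s_t * sasa_t / params.n_t / 1000.0
    return kcal / params.e_hb_kcal


def hydropathy_energy(atom_i, atom_j, r: float, params: EnergyParameters) -> float:
    """Hydropathy square well between two typed side-chain heavy atoms.

    Returns ``hp_i + hp_j`` when the pair is within ``hp_cutoff_scale``
    times the sum of their vdW radii and both atoms share a hydropathy
    class (or ``mixed_hydropathy`` is enabled), else 0.
    """
    for atom in (atom_i, atom_j):
        if atom.hydropathy_class == "none" or atom.hp_value is None:
            raise ValueError(f"atom without hydropathy value: {atom!r}")
    if atom_i.hydropathy_class != atom_j.hydropathy_class and not params.mixed_hydropathy:
        return 0.0
    if r < params.hp_cutoff_scale * (atom_i.vdw_radius + atom_j.vdw_radius):
        return atom_i.hp_value + atom_j.hp_value
    return 0.0


def max_interaction_cutoff(unit_a, unit_b, params: EnergyParameters) -> float:
    """Largest pair distance at which any potential can be nonzero."""
    max_sigma = (
        max(a.vdw_radius for a in unit_a.atoms)
        + max(b.vdw_radius for b in unit_b.atoms)
    )
    return max(
        params.hb_cutoff,
        params.el_cutoff_scale * max_sigma,
        params.hp_cutoff_scale * max_sigma,
    )


def _pair_terms(a, b, r: float, params: EnergyParameters):
    """Evaluate every potential for one intermolecular atom pair.

    Returns (kinds, energies, is_clash).  This is the single dispatch rule
    shared (by construction, and checked by tests) with the accelerated
    kernel: a pair below the hard core is a clash and contributes no well
    energy; otherwise each potential for which both atoms qualify
    contributes independently.
    """
    sigma = a.vdw_radius + b.vdw_radius
    if r < sigma:
        return ["clash"], [0.0], True
    kinds: List[str] = []
    energies: List[float] = []
    if (a.donor and b.acceptor) or (a.acceptor and b.donor):
        e = hbond_energy(r, sigma, params)
        if e != 0.0:
            kinds.append("hbond")
            energies.append(e)
    if a.charge_sign != 0 and b.charge_sign != 0:
        e = electrostatic_energy(r, sigma, a.charge_sign, b.charge_sign, params)
        if e != 0.0:
            kinds.append("electrostatic")
            energies.append(e)
    if a.hydropathy_class != "none" and b.hydropathy_class != "none":
        if a.hydropathy_class == b.hydropathy_class or params.mixed_hydropathy:
            e = hydropathy_energy(a, b, r, params)
            if e != 0.0:
                kinds.append("hydropathy")
                energies.append(e)
    return kinds, energies, False


def interface_energy(
    unit_a,
    unit_b,
    params: EnergyParameters,
    coords_a: np.ndarray | None = None,
    coords_b: np.ndarray | None = None,
) -> Tuple[float, List[PairInteraction], int, int]:
    """Total interface energy of Eq-style summation over all pairs.

    Candidate pairs are pruned with a KD-tree at the global maximum
    cutoff; each surviving pair is scored with the scalar well functions.
    Optional ``coords_a``/``coords_b`` override the stored coordinates
    (used to score a rigid pose without copying the unit).

    Returns ``(U, interactions, n_contacts, n_clashes)`` where ``U`` sums
    the three potentials over all intermolecular pairs, ``n_contacts``
    counts pairs within at least one type-specific cutoff and
    ``n_clashes`` counts pairs below their hard core.
    """
    if unit_a is unit_b or set(map(id, unit_a.atoms)) & set(map(id, unit_b.atoms)):
        raise ValueError("units share atoms")
    for unit in (unit_a, unit_b):
        for atom in unit.atoms:
            if atom.vdw_radius is None or (not atom.is_hydrogen and atom.vdw_radius <= 0):
                raise ValueError("unit has atoms without assigned radii")

    xa = unit_a.coords() if coords_a is None else np.asarray(coords_a, dtype=float)
    xb = unit_b.coords() if coords_b is None else np.asarray(coords_b, dtype=float)
    cutoff = max_interaction_cutoff(unit_a, unit_b, params)
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=cutoff)

    n_contacts = 0
    n_clashes = 0
    interactions: List[PairInteraction] = []
    for i, js in enumerate(pairs):
        a = unit_a.atoms[i]
        for j in sorted(js):
            b = unit_b.atoms[j]
            dx = xa[i, 0] - xb[j, 0]
            dy = xa[i, 1] - xb[j, 1]
            dz = xa[i, 2] - xb[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            kinds, energies, is_clash = _pair_terms(a, b, r, params)
            if is_clash:
                n_clashes += 1
                interactions.append(
                    PairInteraction(
                        i, j, "clash", r, a.vdw_radius + b.vdw_radius, 0.0,
                        a.residue_id, b.residue_id, a.name, b.name,
                    )
                )
                continue
            if kinds:
                n_contacts += 1
            for kind, e in zip(kinds, energies):
                interactions.append(
                    PairInteraction(
                        i, j, kind, r, a.vdw_radius + b.vdw_radius, e,
                        a.residue_id, b.residue_id, a.name, b.name,
                    )
                )
    # fsum makes the total independent of pair enumeration order, so
    # interface_energy(A, B) == interface_energy(B, A) exactly
    U = math.fsum(p.energy for p in interactions)
    return U, interactions, n_contacts, n_clashes


def interactions_table(interactions: Sequence[PairInteraction]):
    """Energy breakdown as a pandas DataFrame (one row per interaction)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "res_a": [p.res_a for p in interactions],
            "atom_a": [p.atom_a for p in interactions],
            "res_b": [p.res_b for p in interactions],
            "atom_b": [p.atom_b for p in interactions],
            "kind": [p.kind for p in interactions],
            "r": [p.r for p in interactions],
            "sigma": [p.sigma for p in interactions],
            "energy": [p.energy for p in interactions],
        }
    )
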