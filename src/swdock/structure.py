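"""All-atom structure handling: PDB I/O, radii, protonation and atom typing.

A :class:`StructureUnit` is the rigid body of the docking engine: an
ordered list of typed atoms.  Typing proceeds in three explicit stages —
``assign_radii`` (van der Waals radii per element), ``assign_protonation``
(formal charge signs on ionized groups given a pH and pKa table) and
``classify_atoms`` (h-bond donors/acceptors and hydropathy classes).
``prepare_unit`` chains the three with package defaults.

Residues are identified everywhere as ``chain:number`` using the author
numbering of the source PDB file.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import gemmi
import numpy as np

from ._data import load_defaults
from .energy import EnergyParameters, hydropathy_parameter

__all__ = [
    "AtomRecord",
    "StructureUnit",
    "ProtonationModel",
    "read_structure",
    "assign_radii",
    "assign_protonation",
    "classify_atoms",
    "prepare_unit",
    "write_ensemble",
]

BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}
BACKBONE_H = {"H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3"}
# maximum D-H covalent bond length used to infer donor hydrogens
# (S-H bonds are ~1.34 A, so sulfur gets a longer leash)
COVALENT_H_MAX = 1.25
COVALENT_SH_MAX = 1.45
DISULFIDE_MAX = 2.5


@dataclass
class AtomRecord:
    """One all-atom entry with coordinates and interaction roles."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    coords: np.ndarray
    vdw_radius: float | None = None
    is_side_chain: bool = False
    is_hydrogen: bool = False
    donor: bool = False
    acceptor: bool = False
    charge_sign: int = 0
    hydropathy_class: str = "none"
    hp_value: float | None = None

    @property
    def residue_id(self) -> str:
        return f"{self.chain_id}:{self.residue_index}"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates on atom {self.serial}")


@dataclass
class StructureUnit:
    """An ordered, typed atom list used as a rigid docking unit."""

    atoms: List[AtomRecord]
    unit_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not any(not a.is_hydrogen for a in self.atoms):
            raise ValueError(f"unit {self.unit_id!r} has no non-hydrogen atoms")

    @property
    def residue_count(self) -> int:
        return len({(a.chain_id, a.residue_index) for a in self.atoms})

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def center(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def bounding_radius(self) -> float:
        """Max distance from the geometric center to any atom surface."""
        x = self.coords()
        d = np.linalg.norm(x - x.mean(axis=0), axis=1)
        radii = np.array([a.vdw_radius or 0.0 for a in self.atoms])
        return float(np.max(d + radii))

    def copy(self) -> "StructureUnit":
        return StructureUnit(
            [copy.copy(a) for a in self.atoms], self.unit_id, self.source
        )

    def with_coords(self, coords: np.ndarray) -> "StructureUnit":
        new = self.copy()
        for atom, xyz in zip(new.atoms, np.asarray(coords, dtype=float)):
            atom.coords = xyz.copy()
        return new

    def residues(self) -> List[tuple]:
        """Ordered unique (chain_id, residue_index, residue_name)."""
        seen = []
        last = None
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.residue_name)
            if key != last:
                if key not in seen:
                    seen.append(key)
                last = key
        return seen


@dataclass
class ProtonationModel:
    """pH plus a pKa lookup for the titratable groups.

    ``pka_table`` may key on a specific residue (``"A:51"``), a residue
    type (``"HIS"``) or a terminus (``"NTER"``/``"CTER"``); specific keys
    win.  Missing entries fall back to the packaged defaults.
    """

    pH: float
    pka_table: Dict[str, float] = field(default_factory=dict)
    rules: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must lie in [0, 14]")
        defaults = load_defaults()
        if not self.rules:
            self.rules = dict(defaults["titration_rules"])
        self._defaults = defaults["pka_defaults"]

    def pka(self, residue_id: str, kind: str) -> float:
        """pKa for a residue instance; ``kind`` is a type or terminus key."""
        if residue_id in self.pka_table:
            return self.pka_table[residue_id]
        if kind in self.pka_table:
            return self.pka_table[kind]
        if kind in self._defaults:
            return self._defaults[kind]
        raise KeyError(f"no pKa for titratable group {kind} at {residue_id}")


def _infer_element(name: str, residue_name: str) -> str:
    """Element from a PDB atom name when the element column is blank."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():  # e.g. 1HB2
        return "H"
    # within amino-acid residues single-letter elements dominate; the
    # first alphabetic character is the element (CA -> C, OD1 -> O ...)
    return stripped[0].upper()


def read_structure(
    path: str | Path,
    model_index: int = 1,
    unit_id: str | None = None,
    require_hydrogens: bool = True,
) -> StructureUnit:
    """Read one model of a PDB file as a :class:`StructureUnit`.

    Keeps protein ATOM/HETATM records (waters and non-protein heteroatoms
    are dropped), resolves elements from the element column or the atom
    name, keeps the highest-occupancy alternate location, and requires
    explicit hydrogens unless ``require_hydrogens=False`` (in which case
    donor detection must rely on a template; see ``classify_atoms``).
    ``model_index`` is 1-based, matching PDB MODEL numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if not 1 <= model_index <= len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index - 1]

    atoms: List[AtomRecord] = []
    serial = 0
    for chain in model:
        n_protein = 0
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            n_protein += 1
            # highest-occupancy altloc per atom name
            best: Dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                serial += 1
                el = atom.element.name
                if atom.element == gemmi.Element("X") or not el:
                    el = _infer_element(atom.name, residue.name)
                is_h = el == "H" or el == "D"
                name = atom.name
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element="H" if is_h else el,
                        residue_name=residue.name,
                        residue_index=residue.seqid.num,
                        chain_id=chain.name or "A",
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_hydrogen=is_h,
                        is_side_chain=(
                            name not in BACKBONE_H if is_h else name not in BACKBONE_HEAVY
                        ),
                    )
                )
        if chain.get_polymer() is not None and n_protein == 0 and len(list(chain)) > 0:
            # chain contained only waters/ligands: fine, just skip it
            continue
    if not atoms:
        raise ValueError(f"{path}: no protein atoms in model {model_index}")
    if require_hydrogens and not any(a.is_hydrogen for a in atoms):
        raise ValueError(
            f"{path}: structure has no hydrogens; the model is all-atom "
            "(pass require_hydrogens=False to fall back to template donors)"
        )
    return StructureUnit(atoms, unit_id or path.stem, f"{path}#model{model_index}")


def assign_radii(
    unit: StructureUnit, radii_table: Optional[Dict[str, float]] = None
) -> StructureUnit:
    """Set per-element van der Waals radii (defaults: Bondi-style table)."""
    table = radii_table or load_defaults()["vdw_radii"]
    for atom in unit.atoms:
        try:
            atom.vdw_radius = float(table[atom.element])
        except KeyError as exc:
            raise KeyError(
                f"element {atom.element!r} (atom {atom.name}) missing from radii table"
            ) from exc
    return unit


def _residue_groups(unit: StructureUnit):
    groups: Dict[tuple, List[AtomRecord]] = {}
    order: List[tuple] = []
    for atom in unit.atoms:
        key = (atom.chain_id, atom.residue_index)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(atom)
    return order, groups


def _is_disulfide(atom: AtomRecord, unit: StructureUnit) -> bool:
    if atom.name != "SG":
        return False
    for other in unit.atoms:
        if other is atom or other.name != "SG":
            continue
        if np.linalg.norm(atom.coords - other.coords) < DISULFIDE_MAX:
            return True
    return False


def assign_protonation(unit: StructureUnit, model: ProtonationModel) -> StructureUnit:
    """Place formal charge signs on ionized groups at the model's pH.

    Bases (His, Lys, Arg, N-terminus) are +1 on their moiety atoms when
    pH < pKa; acids (Asp, Glu, C-terminus, free Cys) are -1 when
    pH > pKa.  Disulfide-bonded cysteines never titrate.  All other
    charge signs are reset to zero.
    """
    defaults = load_defaults()
    moieties = defaults["charge_moieties"]
    order, groups = _residue_groups(unit)
    chains: Dict[str, List[tuple]] = {}
    for key in order:
        chains.setdefault(key[0], []).append(key)

    for atom in unit.atoms:
        atom.charge_sign = 0

    def apply(key: tuple, kind: str) -> None:
        residue_atoms = groups[key]
        rule = model.rules.get(kind)
        if rule is None:
            return
        rid = f"{key[0]}:{key[1]}"
        pka = model.pka(rid if kind not in ("NTER", "CTER") else f"{rid}:{kind}", kind)
        if rule == "base":
            charged = model.pH < pka
            sign = 1
        else:
            charged = model.pH > pka
            sign = -1
        if not charged:
            return
        names = moieties[kind]
        targets = [a for a in residue_atoms if a.name in names]
        if kind == "CTER":
            # carboxylate = OXT plus backbone O when OXT is present,
            # else the lone backbone O
            oxt = [a for a in targets if a.name == "OXT"]
            targets = targets if oxt else [a for a in targets if a.name == "O"]
        for a in targets:
            if kind == "CYS" and _is_disulfide(a, unit):
                return
            a.charge_sign = sign

    for key in order:
        resname = groups[key][0].residue_name
        if resname in model.rules and resname in moieties:
            if resname == "CYS" and any(
                _is_disulfide(a, unit) for a in groups[key] if a.name == "SG"
            ):
                continue
            apply(key, resname)
    for chain_keys in chains.values():
        apply(chain_keys[0], "NTER")
        apply(chain_keys[-1], "CTER")
    return unit


def _bonded_hydrogens(unit: StructureUnit) -> Dict[int, List[int]]:
    """Map heavy-atom index -> indices of hydrogens within covalent range.

    Raises on orphan hydrogens (no heavy atom within ``COVALENT_H_MAX``).
    """
    heavy_idx = [i for i, a in enumerate(unit.atoms) if not a.is_hydrogen]
    h_idx = [i for i, a in enumerate(unit.atoms) if a.is_hydrogen]
    bonded: Dict[int, List[int]] = {}
    if not h_idx:
        return bonded
    from scipy.spatial import cKDTree

    xh = np.array([unit.atoms[i].coords for i in h_idx])
    xheavy = np.array([unit.atoms[i].coords for i in heavy_idx])
    tree = cKDTree(xheavy)
    dist, nearest = tree.query(xh, k=1)
    for pos, (d, n) in enumerate(zip(dist, nearest)):
        heavy = unit.atoms[heavy_idx[int(n)]]
        limit = COVALENT_SH_MAX if heavy.element == "S" else COVALENT_H_MAX
        if d > limit:
            atom = unit.atoms[h_idx[pos]]
            raise ValueError(
                f"orphan hydrogen {atom.name} in {atom.residue_id}: "
                f"nearest heavy atom at {d:.2f} A"
            )
        bonded.setdefault(heavy_idx[int(n)], []).append(h_idx[pos])
    return bonded


def classify_atoms(
    unit: StructureUnit,
    params: Optional[EnergyParameters] = None,
    template_donors: bool = False,
) -> StructureUnit:
    """Assign donor/acceptor flags, hydropathy classes and HP values.

    Donors are N/O/S heavy atoms with a covalently bonded hydrogen
    (``template_donors=True`` instead marks every N/O/S that could carry
    one, for hydrogen-free structures).  Acceptors are every O and S plus
    template nitrogens without a bonded hydrogen.  Side-chain heavy atoms
    get a hydropathy type from their element and charge sign — C, S
    hydrophobic; N/O polar; N+ and O- the charged types — and the
    corresponding normalized HP value.  Idempotent.
    """
    params = params or EnergyParameters()
    defaults = load_defaults()
    acceptor_n = defaults["acceptor_nitrogens"]
    bonded = _bonded_hydrogens(unit)

    for i, atom in enumerate(unit.atoms):
        atom.donor = False
        atom.acceptor = False
        atom.hydropathy_class = "none"
        atom.hp_value = None
        if atom.is_hydrogen:
            continue
        has_h = bool(bonded.get(i))
        if atom.element in ("N", "O", "S"):
            if has_h or (template_donors and _could_bear_hydrogen(atom)):
                atom.donor = True
            if atom.element in ("O", "S"):
                atom.acceptor = True
            elif atom.name in acceptor_n.get(atom.residue_name, ()) and not has_h:
                atom.acceptor = True
        if atom.is_side_chain:
            if atom.element == "C":
                atom_type = "C"
            elif atom.element == "S":
                atom_type = "S"
            elif atom.element == "N":
                atom_type = "N+" if atom.charge_sign > 0 else "N/O"
            elif atom.element == "O":
                atom_type = "O-" if atom.charge_sign < 0 else "N/O"
            else:
                continue
            s_t = params.solvation_table.get(atom_type, 0.0)
            atom.hp_value = hydropathy_parameter(atom_type, params)
            if s_t > 0:
                atom.hydropathy_class = "hydrophobic"
            elif s_t < 0:
                atom.hydropathy_class = "hydrophilic"
            else:
                atom.hydropathy_class = "none"
                atom.hp_value = None
    return unit


def _could_bear_hydrogen(atom: AtomRecord) -> bool:
    """Template fallback for hydrogen-free structures."""
    if atom.element == "N":
        return True  # backbone amides, Lys/Arg/His/Trp/termini nitrogens
    if atom.element == "O":
        return atom.name in ("OG", "OG1", "OH")  # Ser/Thr/Tyr hydroxyls
    if atom.element == "S":
        return atom.name == "SG"
    return False


def prepare_unit(
    unit: StructureUnit,
    ph: float = 7.2,
    params: Optional[EnergyParameters] = None,
    pka_table: Optional[Dict[str, float]] = None,
    radii_table: Optional[Dict[str, float]] = None,
    template_donors: bool = False,
) -> StructureUnit:
    """Radii + protonation + classification with package defaults."""
    params = params or EnergyParameters()
    assign_radii(unit, radii_table)
    assign_protonation(unit, ProtonationModel(pH=ph, pka_table=pka_table or {}))
    classify_atoms(unit, params, template_donors=template_donors)
    return unit


# ---------------------------------------------------------------------------
# PDB writing

def _pdb_atom_line(atom: AtomRecord, serial: int, chain_id: str) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
        f"{chain_id:1.1s}{atom.residue_index:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2.2s}"
    )


def _remap_chains(fixed: StructureUnit, mobile: StructureUnit) -> Dict[str, str]:
    """Mobile-chain relabeling when it collides with a fixed chain id."""
    used = {a.chain_id for a in fixed.atoms}
    mapping: Dict[str, str] = {}
    pool = iter("BCDEFGHIJKLMNOPQRSTUVWXYZA0123456789")
    for a in mobile.atoms:
        if a.chain_id in mapping:
            continue
        if a.chain_id in used:
            for candidate in pool:
                if candidate not in used:
                    mapping[a.chain_id] = candidate
                    used.add(candidate)
                    break
        else:
            mapping[a.chain_id] = a.chain_id
            used.add(a.chain_id)
    return mapping


def write_ensemble(ensemble, path: str | Path) -> None:
    """Write a docked ensemble as a multi-model PDB.

    One MODEL per complex: the fixed unit (centered) then the posed
    mobile unit, with the binding energy and bookkeeping in REMARK 250
    lines.  Coordinates round-trip through :func:`read_structure` at the
    PDB format's 0.001 A precision.
    """
    members = getattr(ensemble, "members", ensemble)
    if not members:
        raise ValueError("cannot write an empty ensemble")
    path = Path(path)
    lines: List[str] = []
    for n, member in enumerate(members, start=1):
        fixed = member.fixed_unit
        mobile = member.posed_mobile_unit()
        mapping = _remap_chains(fixed, mobile)
        lines.append(f"MODEL     {n:>4d}")
        lines.append(f"REMARK 250 SWDOCK BINDING ENERGY {member.binding_energy:.6f}")
        lines.append(
            f"REMARK 250 SWDOCK CONTACTS {member.n_contacts} CLASHES {member.n_clashes}"
        )
        lines.append(
            "REMARK 250 SWDOCK FIXED CHAINS "
            + ",".join(sorted({a.chain_id for a in fixed.atoms}))
        )
        serial = 0
        for atom in fixed.atoms:
            serial += 1
            lines.append(_pdb_atom_line(atom, serial, atom.chain_id))
        lines.append(f"TER   {serial + 1:>5d}")
        serial += 1
        for atom in mobile.atoms:
            serial += 1
            lines.append(_pdb_atom_line(atom, serial, mapping[atom.chain_id]))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_unit_pdb(unit: StructureUnit, path: str | Path) -> None:
    """Write a single StructureUnit as a one-model PDB file."""
    path = Path(path)
    lines = []
    for serial, atom in enumerate(unit.atoms, start=1):
        lines.append(_pdb_atom_line(atom, serial, atom.chain_id))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
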