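"""Deterministic toy structures and brute-force oracles.

Toy units are idealized polypeptides: a planar zig-zag backbone with
standard bond lengths and schematic side chains raised out of the
backbone plane, alternating sides.  They are chemically plausible (bond
lengths within 10% of standard values, no internal clashes, explicit
polar hydrogens) but make no claim to real rotamer geometry — they exist
to exercise the typing, energy, search and analysis contracts.

The module also provides the independent oracles used by the test suite:
a naive all-pairs interface energy, an exhaustive rigid-body grid search,
and planted-contact ensembles with known hot-spot ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from ._kernels import kernel_params, pair_objective, unit_arrays
from .docking import DockedComplex, RigidPose
from .energy import (
    EnergyParameters,
    PairInteraction,
    electrostatic_energy,
    hbond_energy,
    hydropathy_energy,
)
from .structure import AtomRecord, StructureUnit

__all__ = [
    "FixtureSpec",
    "make_toy_unit",
    "brute_force_interface_energy",
    "grid_search_dock",
    "make_planted_ensemble",
]

# bond lengths, Angstrom
_B_N_CA = 1.46
_B_CA_C = 1.52
_B_C_N = 1.33
_ZIG_DEG = 30.0

# side-chain templates: local offsets from CA, z pointing away from the
# backbone plane; only polar hydrogens are included
_SIDE_CHAINS: Dict[str, List[Tuple[str, Tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", (0.0, 0.0, 1.53))],
    "SER": [
        ("CB", (0.0, 0.0, 1.53)),
        ("OG", (0.0, 0.7, 2.77)),
        ("HG", (0.0, 1.5, 3.37)),
    ],
    "CYS": [
        ("CB", (0.0, 0.0, 1.53)),
        ("SG", (0.0, 0.8, 3.13)),
        ("HG1", (0.0, 1.9, 3.89)),
    ],
    "LEU": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("CD1", (1.25, 1.5, 3.33)),
        ("CD2", (-1.25, 1.5, 3.33)),
    ],
    "PHE": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("CD1", (1.2, 1.1, 3.5)),
        ("CD2", (-1.2, 1.1, 3.5)),
        ("CE1", (1.2, 1.5, 4.85)),
        ("CE2", (-1.2, 1.5, 4.85)),
        ("CZ", (0.0, 1.8, 5.5)),
    ],
    "LYS": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("CD", (0.0, -0.05, 4.08)),
        ("CE", (0.0, 0.8, 5.33)),
        ("NZ", (0.0, 0.0, 6.51)),
        ("HZ1", (0.95, 0.0, 6.81)),
        ("HZ2", (-0.95, 0.0, 6.81)),
        ("HZ3", (0.0, -0.95, 6.81)),
    ],
    "ARG": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("CD", (0.0, -0.05, 4.08)),
        ("NE", (0.0, 0.75, 5.28)),
        ("HE", (0.9, 0.75, 5.72)),
        ("CZ", (0.0, 0.05, 6.43)),
        ("NH1", (1.15, 0.35, 6.93)),
        ("NH2", (-1.15, 0.35, 6.93)),
        ("HH11", (1.75, 0.9, 7.48)),
        ("HH21", (-1.75, 0.9, 7.48)),
    ],
    "ASP": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("OD1", (1.1, 1.2, 3.33)),
        ("OD2", (-1.1, 1.2, 3.33)),
    ],
    "GLU": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("CD", (0.0, -0.05, 4.08)),
        ("OE1", (1.1, 0.35, 4.58)),
        ("OE2", (-1.1, 0.35, 4.58)),
    ],
    "HIS": [
        ("CB", (0.0, 0.0, 1.53)),
        ("CG", (0.0, 0.8, 2.83)),
        ("ND1", (1.15, 1.1, 3.38)),
        ("CD2", (-1.15, 1.1, 3.38)),
        ("CE1", (0.7, 1.6, 4.4)),
        ("NE2", (-0.7, 1.6, 4.4)),
        ("HE2", (-1.3, 2.15, 4.98)),
    ],
}

_DEFAULT_COMPOSITION = {
    "GLY": 1.0,
    "ALA": 2.0,
    "SER": 1.5,
    "LEU": 1.5,
    "PHE": 1.0,
    "LYS": 1.0,
    "ARG": 0.5,
    "ASP": 1.0,
    "GLU": 0.5,
    "HIS": 0.5,
}

_PATCH_RESIDUE = {
    "hbond": "SER",
    "charge+": "ARG",
    "charge-": "ASP",
    "hydrophobic": "PHE",
}


@dataclass
class FixtureSpec:
    """Recipe for one deterministic toy unit."""

    n_residues: int
    composition: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COMPOSITION))
    planted_patch: Optional[Tuple[int, str, float]] = None  # (1-based residue, kind, strength)
    geometry: str = "rod"  # rod | blob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if not self.composition or all(w <= 0 for w in self.composition.values()):
            raise ValueError("composition weights must include a positive entry")
        unknown = set(self.composition) - set(_SIDE_CHAINS)
        if unknown:
            raise ValueError(f"unsupported residue types: {sorted(unknown)}")
        if self.geometry not in ("rod", "blob"):
            raise ValueError("geometry must be 'rod' or 'blob'")


def _sequence(spec: FixtureSpec, rng: np.random.Generator) -> List[str]:
    names = sorted(spec.composition)
    weights = np.array([max(spec.composition[n], 0.0) for n in names])
    weights = weights / weights.sum()
    seq = [str(rng.choice(names, p=weights)) for _ in range(spec.n_residues)]
    if spec.planted_patch is not None:
        pos, kind, strength = spec.planted_patch
        if kind not in _PATCH_RESIDUE:
            raise ValueError(f"unknown patch kind {kind!r}")
        if not 1 <= pos <= spec.n_residues:
            raise ValueError("patch position outside the chain")
        width = max(1, int(round(strength)))
        for k in range(pos - 1, min(pos - 1 + width, spec.n_residues)):
            seq[k] = _PATCH_RESIDUE[kind]
    return seq


def make_toy_unit(spec: FixtureSpec, unit_id: str | None = None) -> StructureUnit:
    """Build an idealized all-atom unit from a fixture spec.

    The same spec (including seed) always yields bit-identical
    coordinates.  The returned unit is untyped; run
    :func:`swdock.structure.prepare_unit` before docking.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _sequence(spec, rng)
    turn = 0.0
    if spec.geometry == "blob":
        turn = math.radians(min(12.0, 300.0 / spec.n_residues))

    atoms: List[AtomRecord] = []
    serial = 0

    def add(name: str, resname: str, resnum: int, xyz: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        is_h = name.startswith("H") or (name[:1].isdigit() and "H" in name)
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element="H" if is_h else name[0],
                residue_name=resname,
                residue_index=resnum,
                chain_id="A",
                coords=np.asarray(xyz, dtype=float),
                is_hydrogen=is_h,
                is_side_chain=name not in ("N", "CA", "C", "O", "OXT", "H"),
            )
        )

    pos = np.zeros(3)
    heading = 0.0  # in-plane chain direction, radians
    step_parity = 0

    def bond(length: float) -> np.ndarray:
        nonlocal step_parity
        zig = math.radians(_ZIG_DEG) * (1 if step_parity % 2 == 0 else -1)
        step_parity += 1
        ang = heading + zig
        return np.array([math.cos(ang) * length, math.sin(ang) * length, 0.0])

    for k, resname in enumerate(seq):
        resnum = k + 1
        n_pos = pos.copy()
        ca_pos = n_pos + bond(_B_N_CA)
        next_zig_up = step_parity % 2 == 0  # parity of the CA->C bond
        c_pos = ca_pos + bond(_B_CA_C)
        into_n_up = step_parity % 2 == 0  # direction of the C->N(next) bond
        o_off = np.array([0.0, -1.23 if into_n_up else 1.23, 0.0])
        h_off = np.array([0.0, 1.0 if into_n_up else -1.0, 0.0])

        add("N", resname, resnum, n_pos)
        add("H", resname, resnum, n_pos + _rotz(heading) @ h_off)
        add("CA", resname, resnum, ca_pos)
        # side chains alternate above/below the backbone plane
        side = 1.0 if k % 2 == 0 else -1.0
        R = _rotz(heading)
        for name, (lx, ly, lz) in _SIDE_CHAINS[resname]:
            offset = R @ np.array([lx, ly, 0.0]) + np.array([0.0, 0.0, lz * side])
            add(name, resname, resnum, ca_pos + offset)
        add("C", resname, resnum, c_pos)
        add("O", resname, resnum, c_pos + _rotz(heading) @ o_off)
        if k == len(seq) - 1:
            oxt_dir = bond(_B_C_N)  # where the next N would have been
            add("OXT", resname, resnum, c_pos + oxt_dir * (1.25 / _B_C_N))
            pos = c_pos
        else:
            pos = c_pos + bond(_B_C_N)
        heading += turn

    return StructureUnit(atoms, unit_id or f"toy-{spec.seed}", f"fixture:{spec.seed}")


def _rotz(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def brute_force_interface_energy(
    unit_a: StructureUnit,
    unit_b: StructureUnit,
    params: EnergyParameters,
    coords_a: Optional[np.ndarray] = None,
    coords_b: Optional[np.ndarray] = None,
) -> Tuple[float, List[PairInteraction], int, int]:
    """Naive all-pairs double loop over the two units.

    Ground truth for equivalence tests of the accelerated evaluations:
    no neighbor lists, every intermolecular pair is visited and scored
    with the scalar well functions.
    """
    xa = unit_a.coords() if coords_a is None else np.asarray(coords_a, dtype=float)
    xb = unit_b.coords() if coords_b is None else np.asarray(coords_b, dtype=float)
    n_contacts = 0
    n_clashes = 0
    interactions: List[PairInteraction] = []
    for i, a in enumerate(unit_a.atoms):
        for j, b in enumerate(unit_b.atoms):
            dx = xa[i, 0] - xb[j, 0]
            dy = xa[i, 1] - xb[j, 1]
            dz = xa[i, 2] - xb[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            sigma = a.vdw_radius + b.vdw_radius
            if r < sigma:
                n_clashes += 1
                interactions.append(
                    PairInteraction(i, j, "clash", r, sigma, 0.0,
                                    a.residue_id, b.residue_id, a.name, b.name)
                )
                continue
            found = False
            if (a.donor and b.acceptor) or (a.acceptor and b.donor):
                e = hbond_energy(r, sigma, params)
                if e != 0.0:
                    found = True
                    interactions.append(
                        PairInteraction(i, j, "hbond", r, sigma, e,
                                        a.residue_id, b.residue_id, a.name, b.name)
                    )
            if a.charge_sign != 0 and b.charge_sign != 0:
                e = electrostatic_energy(r, sigma, a.charge_sign, b.charge_sign, params)
                if e != 0.0:
                    found = True
                    interactions.append(
                        PairInteraction(i, j, "electrostatic", r, sigma, e,
                                        a.residue_id, b.residue_id, a.name, b.name)
                    )
            if (
                a.hydropathy_class != "none"
                and b.hydropathy_class != "none"
                and (a.hydropathy_class == b.hydropathy_class or params.mixed_hydropathy)
            ):
                e = hydropathy_energy(a, b, r, params)
                if e != 0.0:
                    found = True
                    interactions.append(
                        PairInteraction(i, j, "hydropathy", r, sigma, e,
                                        a.residue_id, b.residue_id, a.name, b.name)
                    )
            if found:
                n_contacts += 1
    U = math.fsum(p.energy for p in interactions)
    return U, interactions, n_contacts, n_clashes


def grid_search_dock(
    fixed: StructureUnit,
    mobile: StructureUnit,
    params: EnergyParameters,
    resolution: Tuple[float, float] = (0.5, 45.0),
    max_poses: int = 10_000_000,
) -> DockedComplex:
    """Exhaustive 6-DOF enumeration; returns the minimal-objective pose.

    Translations run on a cubic grid covering every separation at which
    any potential can act, rotations on a z-y-z Euler grid, plus one
    far-separated reference pose (objective exactly 0).  Intended as a
    test oracle on small units; raises if the grid exceeds ``max_poses``.
    """
    trans_res, rot_res = resolution
    fixed_c = fixed.with_coords(fixed.coords() - fixed.center())
    mobile_centered = mobile.coords() - mobile.center()
    arrays_f = unit_arrays(fixed_c)
    arrays_m = unit_arrays(mobile)
    kp = kernel_params(params)

    from .energy import max_interaction_cutoff

    gcut = max_interaction_cutoff(fixed_c, mobile, params)
    L = fixed_c.bounding_radius() + mobile.bounding_radius() + gcut
    axis_pts = np.arange(-L, L + 1e-9, trans_res)
    alphas = np.arange(0.0, 360.0, rot_res)
    betas = np.arange(0.0, 180.0 + 1e-9, rot_res)
    gammas = np.arange(0.0, 360.0, rot_res)
    n_rot = len(alphas) * len(betas) * len(gammas)
    # cheap upper bound before materializing anything
    if len(axis_pts) ** 3 * n_rot > 2.2 * max_poses:
        raise ValueError(
            f"grid too large: ~{len(axis_pts) ** 3 * n_rot} poses > {max_poses}"
        )
    grid_pts = [
        np.array([x, y, z])
        for x in axis_pts
        for y in axis_pts
        for z in axis_pts
        if x * x + y * y + z * z <= L * L
    ]
    rotations = [
        Rotation.from_euler("zyz", [al, be, ga], degrees=True)
        for al in alphas
        for be in betas
        for ga in gammas
    ]
    n_poses = len(grid_pts) * len(rotations)
    if n_poses > max_poses:
        raise ValueError(f"grid too large: {n_poses} poses > {max_poses}")

    best = None
    for rot in rotations:
        xr = rot.apply(mobile_centered)
        for t in grid_pts:
            xm = xr + t
            U, ncont, nclash = pair_objective(
                arrays_f[0], *arrays_f[1:], xm, *arrays_m[1:], kp
            )
            F = U + params.clash_weight * nclash
            if best is None or F < best[0]:
                quat = rot.as_quat()
                best = (F, quat / np.linalg.norm(quat), t.copy())
    # far-separated reference pose: zero contacts, zero clashes, F = 0
    far = np.array([L + gcut + 1.0, 0.0, 0.0])
    if best is None or best[0] > 0.0:
        best = (0.0, np.array([0.0, 0.0, 0.0, 1.0]), far)

    F, quat, t = best
    pose = RigidPose(rotation=quat, translation=t)
    from .energy import interface_energy

    U_full, interactions, ncont, nclash = interface_energy(
        fixed_c, mobile, params, coords_b=pose.apply(mobile_centered)
    )
    return DockedComplex(
        fixed_source=fixed.source or fixed.unit_id,
        mobile_source=mobile.source or mobile.unit_id,
        pose=pose,
        binding_energy=U_full,
        n_contacts=ncont,
        n_clashes=nclash,
        interactions=interactions,
        objective=U_full + params.clash_weight * nclash,
        fixed_unit=fixed_c,
        mobile_unit=mobile,
    )


def make_planted_ensemble(
    n_members: int,
    sticky_residue: int = 7,
    background_rate: float = 0.1,
    seed: int = 0,
    planted_rate: float = 0.8,
    n_residues: int = 20,
):
    """Synthetic ensemble with a known hot-spot, for analysis tests.

    Each member carries a contact involving residue ``A:<sticky_residue>``
    with probability ``planted_rate`` (random partner on the other unit)
    and, independently for every other residue, a background contact with
    probability ``background_rate``.  Binding energies are normal draws,
    so the ensemble exercises the density and hot-spot paths end to end.
    """
    from .docking import ComplexEnsemble

    if n_members < 10:
        raise ValueError("n_members must be >= 10")
    if not 0.0 <= background_rate <= 1.0 or not 0.0 <= planted_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    if background_rate >= planted_rate:
        raise ValueError("background_rate must be below the planted rate")
    if not 1 <= sticky_residue <= n_residues:
        raise ValueError("sticky residue outside the chain")
    rng = np.random.default_rng(seed)
    identity = RigidPose(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3))
    members = []
    for _ in range(n_members):
        interactions: List[PairInteraction] = []
        if rng.random() < planted_rate:
            partner = int(rng.integers(1, n_residues + 1))
            interactions.append(
                PairInteraction(0, 0, "hbond", 3.0, 2.9, -1.0,
                                f"A:{sticky_residue}", f"B:{partner}", "O", "N")
            )
        for res in range(1, n_residues + 1):
            if res == sticky_residue:
                continue
            if rng.random() < background_rate:
                partner = int(rng.integers(1, n_residues + 1))
                interactions.append(
                    PairInteraction(0, 0, "hbond", 3.0, 2.9, -1.0,
                                    f"A:{res}", f"B:{partner}", "O", "N")
                )
        members.append(
            DockedComplex(
                fixed_source="synthetic",
                mobile_source="synthetic",
                pose=identity,
                binding_energy=float(rng.normal(-10.0, 2.0)),
                n_contacts=len(interactions),
                n_clashes=0,
                interactions=interactions,
            )
        )
    trace = []
    for n in range(1, n_members + 1):
        arr = np.array([m.binding_energy for m in members[:n]])
        trace.append((n, float(arr.mean()), float(arr.std())))
    return ComplexEnsemble(
        members=members,
        convergence_trace=trace,
        converged=True,
        pH=7.2,
        seed=seed,
        target_range=(n_members, n_members),
    )
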