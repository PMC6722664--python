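"""Rigid-body Monte Carlo pose search and ensemble accumulation.

One unit is held fixed with its geometric center at the origin; the
mobile unit performs random rotations about its own center and random
translations along the instantaneous docking axis (the line joining the
two centers).  Poses are scored with the square-well interface objective
``F = U + clash_weight * n_clashes`` under Metropolis acceptance with a
geometric annealing schedule, and the best pose visited is kept.

``ensemble_dock`` repeats the search over randomly selected conformer
pairs until the running mean and standard deviation of the binding
energy both converge, producing a :class:`ComplexEnsemble`.  Per-run
seeds are derived from the master seed with a counter-based splitter, so
every member is reproducible independently of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from ._kernels import kernel_params, pair_objective, unit_arrays
from .energy import EnergyParameters, PairInteraction, interface_energy
from .structure import StructureUnit

__all__ = [
    "RigidPose",
    "MCSchedule",
    "DockedComplex",
    "ComplexEnsemble",
    "initial_placement",
    "propose_move",
    "mc_dock",
    "ensemble_dock",
]


@dataclass
class RigidPose:
    """Orientation (unit quaternion, scipy xyzw order) plus the position
    of the mobile unit's center."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        norm = float(np.linalg.norm(self.rotation))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("quaternion is not normalized")
        self.rotation = self.rotation / norm

    def apply(self, centered_coords: np.ndarray) -> np.ndarray:
        """Transform coordinates given relative to the mobile center."""
        return Rotation.from_quat(self.rotation).apply(centered_coords) + self.translation

    def inverse_apply(self, coords: np.ndarray) -> np.ndarray:
        return Rotation.from_quat(self.rotation).inv().apply(coords - self.translation)


@dataclass
class MCSchedule:
    """Annealing schedule and move sizes for one MC run.

    ``n_restarts`` splits the step budget into independent annealing
    cycles, each from a fresh random placement (new docking axis and
    orientation); the best pose over all cycles is returned.  The default
    is a single cycle — one random encounter per run.
    """

    n_steps: int = 50_000
    t_start: float = 2.0
    t_end: float = 0.05
    rot_max: float = 15.0  # degrees
    trans_max: float = 1.5  # Angstrom
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.t_start <= 0 or self.t_end <= 0:
            raise ValueError("temperatures must be positive")
        if self.rot_max < 0 or self.trans_max < 0:
            raise ValueError("step sizes must be non-negative")
        if not 1 <= self.n_restarts <= self.n_steps:
            raise ValueError("n_restarts must be in [1, n_steps]")

    @property
    def steps_per_cycle(self) -> int:
        return max(1, self.n_steps // self.n_restarts)

    def temperature(self, k: int) -> float:
        """Geometric cooling within one cycle; k counts from 0."""
        per = self.steps_per_cycle
        if per == 1:
            return self.t_start
        frac = min(k, per - 1) / (per - 1)
        return self.t_start * (self.t_end / self.t_start) ** frac


@dataclass
class DockedComplex:
    """One rigid pose of a mobile unit against a fixed unit."""

    fixed_source: str
    mobile_source: str
    pose: RigidPose
    binding_energy: float
    n_contacts: int
    n_clashes: int
    interactions: List[PairInteraction] = field(default_factory=list)
    objective: float = 0.0
    fixed_unit: Optional[StructureUnit] = None
    mobile_unit: Optional[StructureUnit] = None
    acceptance_rate: Optional[float] = None
    objective_trace: Optional[np.ndarray] = None

    def posed_mobile_unit(self) -> StructureUnit:
        if self.mobile_unit is None:
            raise ValueError("synthetic complex carries no mobile unit")
        centered = self.mobile_unit.coords() - self.mobile_unit.center()
        return self.mobile_unit.with_coords(self.pose.apply(centered))


@dataclass
class ComplexEnsemble:
    """Converged collection of docked complexes with its convergence trace."""

    members: List[DockedComplex]
    convergence_trace: List[Tuple[int, float, float]]
    converged: bool
    pH: float = 7.2
    seed: int = 0
    target_range: Tuple[int, int] = (0, 0)

    def energies(self) -> np.ndarray:
        return np.array([m.binding_energy for m in self.members], dtype=float)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def initial_placement(
    fixed: StructureUnit, mobile: StructureUnit, rng_seed=0
) -> RigidPose:
    """Random orientation on a random docking axis, clash-free.

    Assumes the fixed unit is centered at the origin.  The mobile center
    is placed at (sum of the two bounding radii, measured to the atom
    surfaces) + 2 A, which guarantees no pair is inside its hard core.
    """
    rng = _as_rng(rng_seed)
    for unit in (fixed, mobile):
        x = unit.coords()
        if len(unit.atoms) > 1 and float(
            np.max(np.linalg.norm(x - x.mean(axis=0), axis=1))
        ) < 1e-9:
            raise ValueError(f"degenerate unit {unit.unit_id!r}: all atoms coincident")
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    separation = fixed.bounding_radius() + mobile.bounding_radius() + 2.0
    return RigidPose(rotation=quat, translation=axis * separation)


def propose_move(
    pose: RigidPose, step: Tuple[float, float] | MCSchedule, rng
) -> RigidPose:
    """One random rotation (about the mobile center) or translation
    (along the docking axis), each with probability one half."""
    if isinstance(step, MCSchedule):
        rot_max, trans_max = step.rot_max, step.trans_max
    else:
        rot_max, trans_max = step
    if rot_max < 0 or trans_max < 0:
        raise ValueError("step sizes must be non-negative")
    rng = _as_rng(rng)
    if rng.random() < 0.5:
        axis = rng.normal(size=3)
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        angle = rng.uniform(0.0, math.radians(rot_max))
        dq = Rotation.from_rotvec(axis * angle)
        quat = (dq * Rotation.from_quat(pose.rotation)).as_quat()
        quat = quat / np.linalg.norm(quat)
        return RigidPose(rotation=quat, translation=pose.translation.copy())
    direction = pose.translation.copy()
    nrm = np.linalg.norm(direction)
    if nrm < 1e-12:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
    else:
        direction /= nrm
    delta = rng.uniform(-trans_max, trans_max)
    return RigidPose(
        rotation=pose.rotation.copy(), translation=pose.translation + delta * direction
    )


def mc_dock(
    fixed: StructureUnit,
    mobile: StructureUnit,
    params: Optional[EnergyParameters] = None,
    schedule: Optional[MCSchedule] = None,
    rng_seed=0,
    keep_trace: bool = False,
) -> DockedComplex:
    """Anneal the mobile unit's pose and return the best complex visited.

    Metropolis acceptance on F = U + clash_weight * n_clashes with the
    geometric temperature schedule; the recorded ``binding_energy`` is
    the pure interface energy U of the best pose.  The center separation
    is bounded above by its initial value (a reflecting wall), so the
    search cannot drift off to infinity along the flat zero-energy
    plateau before the units meet.
    """
    params = params or EnergyParameters()
    schedule = schedule or MCSchedule()
    rng = _as_rng(rng_seed)

    fixed_c = fixed.with_coords(fixed.coords() - fixed.center())
    arrays_f = unit_arrays(fixed_c)
    mobile_centered = mobile.coords() - mobile.center()
    arrays_m = unit_arrays(mobile)
    kp = kernel_params(params)

    def objective(pose: RigidPose):
        xm = pose.apply(mobile_centered)
        U, ncont, nclash = pair_objective(
            arrays_f[0], *arrays_f[1:], xm, *arrays_m[1:], kp
        )
        return U + params.clash_weight * nclash, U, ncont, nclash

    best = None
    n_accepted = 0
    n_proposed = 0
    trace_list: List[float] = [] if keep_trace else None

    for _cycle in range(schedule.n_restarts):
        pose = initial_placement(fixed_c, mobile, rng)
        max_separation = float(np.linalg.norm(pose.translation))
        F, U, ncont, nclash = objective(pose)
        if best is None or F < best[0]:
            best = (F, pose, U, ncont, nclash)
        for k in range(schedule.steps_per_cycle):
            T = schedule.temperature(k)
            n_proposed += 1
            candidate = propose_move(pose, schedule, rng)
            if np.linalg.norm(candidate.translation) > max_separation:
                if keep_trace:
                    trace_list.append(best[0])
                continue
            Fc, Uc, ncc, nclc = objective(candidate)
            dF = Fc - F
            if dF <= 0 or rng.random() < math.exp(-dF / T):
                pose, F, U, ncont, nclash = candidate, Fc, Uc, ncc, nclc
                n_accepted += 1
                if F < best[0]:
                    best = (F, pose, U, ncont, nclash)
            if keep_trace:
                trace_list.append(best[0])
    trace = np.array(trace_list) if keep_trace else None

    F, pose, _, _, _ = best
    xm = pose.apply(mobile_centered)
    U_full, interactions, ncont, nclash = interface_energy(
        fixed_c, mobile, params, coords_b=xm
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
        acceptance_rate=n_accepted / max(n_proposed, 1),
        objective_trace=trace,
    )


def ensemble_dock(
    pool_a: Sequence[StructureUnit],
    pool_b: Sequence[StructureUnit],
    params: Optional[EnergyParameters] = None,
    schedule: Optional[MCSchedule] = None,
    target: Tuple[int, int] = (1000, 1500),
    tol: float = 0.02,
    window: int = 50,
    rng_seed: int = 0,
    ph: float = 7.2,
) -> ComplexEnsemble:
    """Accumulate docked complexes over random conformer pairs until the
    running mean and standard deviation of the binding energy converge.

    Stops once both |delta mean| and |delta std| over the last ``window``
    additions drop below ``tol * std`` (with at least ``target[0]``
    members), or at ``target[1]`` members.  Tetramer assembly is the same
    call with pools of dimers read back as rigid units.
    """
    if not pool_a or not pool_b:
        raise ValueError("conformer pools must be non-empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not (target[1] >= target[0] >= 2):
        raise ValueError("need target max >= min >= 2")
    rng_seed = int(rng_seed)
    if rng_seed < 0:
        raise ValueError("rng_seed must be non-negative")
    params = params or EnergyParameters()
    schedule = schedule or MCSchedule()

    members: List[DockedComplex] = []
    energies: List[float] = []
    trace: List[Tuple[int, float, float]] = []
    converged = False
    for k in range(target[1]):
        pair_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2, k]))
        ia = int(pair_rng.integers(len(pool_a)))
        ib = int(pair_rng.integers(len(pool_b)))
        run_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1, k]))
        member = mc_dock(pool_a[ia], pool_b[ib], params, schedule, run_rng)
        members.append(member)
        energies.append(member.binding_energy)
        arr = np.array(energies)
        mean, std = float(arr.mean()), float(arr.std())
        trace.append((len(members), mean, std))
        if len(members) >= max(target[0], window + 1):
            n0 = len(members) - window - 1
            _, mean0, std0 = trace[n0]
            scale = std if std > 0 else 1.0
            if abs(mean - mean0) <= tol * scale and abs(std - std0) <= tol * scale:
                converged = True
                break
    return ComplexEnsemble(
        members=members,
        convergence_trace=trace,
        converged=converged,
        pH=ph,
        seed=rng_seed,
        target_range=target,
    )
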