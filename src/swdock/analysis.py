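"""Ensemble statistics: binding-energy density, contact maps, hot-spots.

Given a converged ensemble of docked complexes, this module computes the
probability density of the binding energy and its mode E_M (the most
likely binding energy), the intermolecular probability map (IPM) giving
the formation probability of every residue-residue contact across the
ensemble, the per-residue hot-spot probabilities restricted to the most
frequent contacts, and the representative conformer whose binding energy
is nearest the mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "EnergyDensity",
    "ContactProbabilityMap",
    "HotspotTable",
    "binding_energy_density",
    "contact_probability_map",
    "hotspot_probabilities",
    "representative_conformer",
    "member_contacts",
]


@dataclass
class EnergyDensity:
    """Kernel density estimate of the binding-energy distribution."""

    sample: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    mode: float  # E_M, the most likely binding energy
    bandwidth: float
    degenerate: bool = False


@dataclass
class ContactProbabilityMap:
    """Residue-by-residue intermolecular contact probabilities."""

    residues_a: List[str]
    residues_b: List[str]
    P: np.ndarray

    def probability(self, res_a: str, res_b: str) -> float:
        return float(
            self.P[self.residues_a.index(res_a), self.residues_b.index(res_b)]
        )


@dataclass
class HotspotTable:
    """Per-residue interaction probability within the top contacts."""

    probabilities: Dict[str, float]
    subset_size: int = 50
    subset_contacts: List[Tuple[Tuple[str, str], int]] = field(default_factory=list)

    def ranked(self) -> List[Tuple[str, float]]:
        """Residues by decreasing probability, identifier ascending on ties."""
        return sorted(self.probabilities.items(), key=lambda kv: (-kv[1], kv[0]))


def _residue_sort_key(rid: str):
    chain, _, num = rid.partition(":")
    try:
        return (chain, int(num))
    except ValueError:
        return (chain, num)


def binding_energy_density(
    ensemble, bandwidth: Optional[float] = None, n_grid: int = 512
) -> EnergyDensity:
    """Gaussian KDE of the ensemble's binding energies and its mode E_M.

    Uses the Silverman bandwidth unless overridden; the density is
    evaluated on a uniform grid spanning the sample range extended by
    three bandwidths.  A zero-variance sample yields a degenerate density
    with E_M equal to the common value.
    """
    sample = np.asarray(
        ensemble if isinstance(ensemble, (list, np.ndarray)) else ensemble.energies(),
        dtype=float,
    )
    if sample.size < 2:
        raise ValueError("need at least 2 binding energies for a density")
    if np.std(sample) == 0.0:
        value = float(sample[0])
        grid = np.array([value])
        return EnergyDensity(sample, grid, np.array([np.inf]), value, 0.0, True)
    kde = gaussian_kde(sample, bw_method="silverman" if bandwidth is None else None)
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / sample.std(ddof=1))
    bw = float(kde.factor * sample.std(ddof=1))
    grid = np.linspace(sample.min() - 3 * bw, sample.max() + 3 * bw, n_grid)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    return EnergyDensity(sample, grid, density, mode, bw)


def member_contacts(member) -> set:
    """Residue-residue contacts of one complex, each counted once.

    A contact is any qualifying intermolecular interaction within its
    type-specific cutoff; clashes do not qualify.
    """
    return {
        (p.res_a, p.res_b) for p in member.interactions if p.kind != "clash"
    }


def _contact_counts(members) -> Dict[Tuple[str, str], int]:
    counts: Dict[Tuple[str, str], int] = {}
    for member in members:
        for contact in member_contacts(member):
            counts[contact] = counts.get(contact, 0) + 1
    return counts


def contact_probability_map(ensemble) -> ContactProbabilityMap:
    """Probability of every intermolecular residue-residue contact.

    An entry is the number of ensemble members in which at least one
    qualifying atom pair joins the two residues, divided by the ensemble
    size (multiple atom pairs within a member count once).
    """
    members = getattr(ensemble, "members", ensemble)
    if not members:
        raise ValueError("empty ensemble")
    counts = _contact_counts(members)
    residues_a = sorted({c[0] for c in counts}, key=_residue_sort_key)
    residues_b = sorted({c[1] for c in counts}, key=_residue_sort_key)
    P = np.zeros((len(residues_a), len(residues_b)))
    index_a = {r: i for i, r in enumerate(residues_a)}
    index_b = {r: i for i, r in enumerate(residues_b)}
    for (ra, rb), n in counts.items():
        P[index_a[ra], index_b[rb]] = n / len(members)
    return ContactProbabilityMap(residues_a, residues_b, P)


def hotspot_probabilities(ensemble, subset_size: int = 50) -> HotspotTable:
    """Per-residue interaction probability within the most frequent contacts.

    Contacts are ranked by ensemble frequency (ties broken by ascending
    residue identifiers) and the top ``subset_size`` retained; each
    residue's probability is the fraction of ensemble members in which it
    participates in at least one subset contact, on either side of the
    interface.
    """
    members = getattr(ensemble, "members", ensemble)
    if not members:
        raise ValueError("empty ensemble")
    counts = _contact_counts(members)
    if not counts:
        raise ValueError("ensemble contains no intermolecular contacts")
    ranked = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], _residue_sort_key(kv[0][0]), _residue_sort_key(kv[0][1])),
    )
    subset = ranked[: min(subset_size, len(ranked))]
    subset_set = {c for c, _ in subset}
    probabilities: Dict[str, float] = {}
    residues = sorted(
        {r for c in subset_set for r in c}, key=_residue_sort_key
    )
    for residue in residues:
        n_part = sum(
            1
            for member in members
            if any(
                c in subset_set and residue in c for c in member_contacts(member)
            )
        )
        probabilities[residue] = n_part / len(members)
    return HotspotTable(probabilities, subset_size, subset)


def representative_conformer(ensemble, density: EnergyDensity):
    """The member whose binding energy is nearest the mode E_M.

    Exact ties go to the earliest member.
    """
    members = getattr(ensemble, "members", ensemble)
    if not members:
        raise ValueError("empty ensemble")
    best_i = min(
        range(len(members)),
        key=lambda i: (abs(members[i].binding_energy - density.mode), i),
    )
    return members[best_i]
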