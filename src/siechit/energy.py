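"""Intermolecular screened Coulomb and Lennard-Jones energies.

These are the endpoint interaction terms of the SIE function: the Coulomb
sum is screened by the constant solute dielectric D_in, and the 12-6
Lennard-Jones term uses Rmin-based parameters with Lorentz-Berthelot-style
combination (Rmin_ij = Rmin_i/2 + Rmin_j/2, eps_ij = sqrt(eps_i eps_j)).
Sums run over all receptor x ligand cross pairs with no cutoff by default;
the MD engine's neighbour-list cutoff is irrelevant to endpoint scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .atoms import AtomSelection, SelectionError

__all__ = [
    "COULOMB_K",
    "PairEnergyResult",
    "coulomb_energy",
    "lennard_jones_energy",
    "pair_energies",
]

#: Coulomb constant in kcal * A / (mol * e^2), AMBER convention.
COULOMB_K = 332.0716


@dataclass(frozen=True)
class PairEnergyResult:
    coulomb: float  # kcal/mol
    vdw: float      # kcal/mol
    n_pairs: int


def _check_pair(receptor: AtomSelection, ligand: AtomSelection) -> None:
    if receptor.system is not ligand.system:
        raise SelectionError("receptor and ligand must select from the same system")
    if not receptor.disjoint(ligand):
        raise SelectionError("receptor and ligand selections overlap")
    for sel in (receptor, ligand):
        bad = [a.name for a in sel.atoms() if not a.parameterized]
        if bad:
            raise ValueError(f"unparameterized atoms in selection: {bad[:5]}")


def _distances(
    receptor: AtomSelection, ligand: AtomSelection, frame: np.ndarray | None
) -> np.ndarray:
    r = cdist(receptor.coords(frame), ligand.coords(frame))
    if np.any(r == 0.0):
        raise ValueError("singular geometry: receptor-ligand pair at zero distance")
    return r


def coulomb_energy(
    receptor: AtomSelection,
    ligand: AtomSelection,
    d_in: float = 2.25,
    frame: np.ndarray | None = None,
    cutoff: float | None = None,
) -> float:
    """Screened intermolecular Coulomb energy, kcal/mol.

    E_C = sum_ij k q_i q_j / (D_in r_ij) over all cross pairs.
    """
    if d_in <= 0:
        raise ValueError("d_in must be positive")
    _check_pair(receptor, ligand)
    r = _distances(receptor, ligand, frame)
    qq = np.outer(receptor.charges(), ligand.charges())
    contrib = COULOMB_K * qq / (d_in * r)
    if cutoff is not None:
        contrib = np.where(r <= cutoff, contrib, 0.0)
    return float(contrib.sum())


def lennard_jones_energy(
    receptor: AtomSelection,
    ligand: AtomSelection,
    frame: np.ndarray | None = None,
    cutoff: float | None = None,
) -> float:
    """Intermolecular 12-6 Lennard-Jones energy, kcal/mol.

    E_vdw = sum_ij eps_ij [(Rmin_ij / r)^12 - 2 (Rmin_ij / r)^6].
    """
    _check_pair(receptor, ligand)
    r = _distances(receptor, ligand, frame)
    eps_r = np.array([a.lj_epsilon for a in receptor.atoms()])
    eps_l = np.array([a.lj_epsilon for a in ligand.atoms()])
    rmin_r = np.array([a.lj_rmin_half for a in receptor.atoms()])
    rmin_l = np.array([a.lj_rmin_half for a in ligand.atoms()])
    eps_ij = np.sqrt(np.outer(eps_r, eps_l))
    rmin_ij = rmin_r[:, None] + rmin_l[None, :]
    s6 = (rmin_ij / r) ** 6
    contrib = eps_ij * (s6 * s6 - 2.0 * s6)
    if cutoff is not None:
        contrib = np.where(r <= cutoff, contrib, 0.0)
    return float(contrib.sum())


def pair_energies(
    receptor: AtomSelection,
    ligand: AtomSelection,
    d_in: float = 2.25,
    frame: np.ndarray | None = None,
    cutoff: float | None = None,
) -> PairEnergyResult:
    """Both intermolecular terms in one pass."""
    return PairEnergyResult(
        coulomb=coulomb_energy(receptor, ligand, d_in, frame, cutoff),
        vdw=lennard_jones_energy(receptor, ligand, frame, cutoff),
        n_pairs=len(receptor) * len(ligand),
    )
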