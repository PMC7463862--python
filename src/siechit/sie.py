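"""The solvated interaction energy (SIE) scoring function.

SIE is an endpoint binding free-energy estimator:

    dG_bind = alpha * [ E_C(D_in) + dG_RF(rho, D_in) + E_vdw
                        + gamma * dMSA(rho) ] + C

with the calibrated global parameters alpha = 0.1048, D_in = 2.25,
rho = 1.1, gamma = 0.0129 kcal/(mol A^2), C = -2.89 kcal/mol. The four
bracketed terms are the screened intermolecular Coulomb energy, the
reaction-field change upon binding, the intermolecular Lennard-Jones
energy, and the cavity (surface-area) term. Trajectory scoring averages
per-snapshot components and reports mean +/- SEM per term.

Note the cavity term gamma * dMSA sits INSIDE the alpha bracket: this is
the reading under which the published per-term components recombine to the
published totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .atoms import AtomSelection, Trajectory
from .energy import COULOMB_K, pair_energies
from .solvation import GridSpec, delta_msa, delta_reaction_field

__all__ = [
    "SIEParameters",
    "SIEComponents",
    "TrajectorySIE",
    "combine_sie",
    "cavity_term",
    "score_snapshot",
    "score_trajectory",
    "score_component_table",
    "load_component_table",
    "default_component_table",
    "TERM_ORDER",
]

log = logging.getLogger(__name__)

TERM_ORDER = [
    "inter_vdw",
    "inter_coulomb",
    "reaction_field",
    "cavity",
    "constant",
    "total",
]


@dataclass(frozen=True)
class SIEParameters:
    """Global constants of the SIE function (published calibration)."""

    alpha: float = 0.1048          # dimensionless global scaling
    d_in: float = 2.25             # solute interior dielectric
    rho: float = 1.1               # dielectric-boundary radius scaling
    gamma: float = 0.0129          # cavity coefficient, kcal/(mol A^2)
    constant_c: float = -2.89      # offset, kcal/mol
    d_solv: float = 78.5           # solvent dielectric
    coulomb_k: float = COULOMB_K   # kcal A / (mol e^2)
    probe: float = 1.4             # surface probe radius, A
    n_surface_points: int = 960


@dataclass(frozen=True)
class SIEComponents:
    """Per-snapshot term breakdown, kcal/mol. ``cavity`` is already
    gamma * dMSA; ``total`` satisfies the combination identity."""

    inter_vdw: float
    inter_coulomb: float
    reaction_field: float
    cavity: float
    constant: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in TERM_ORDER}


def combine_sie(
    inter_vdw: float,
    inter_coulomb: float,
    reaction_field: float,
    cavity: float,
    params: SIEParameters | None = None,
) -> float:
    """alpha * (E_C + dG_RF + E_vdw + gamma*dMSA) + C, kcal/mol.

    ``cavity`` must already be the gamma-scaled surface term.
    """
    params = params or SIEParameters()
    terms = (inter_vdw, inter_coulomb, reaction_field, cavity)
    if not all(math.isfinite(t) for t in terms):
        raise ValueError(f"non-finite SIE component in {terms}")
    return params.alpha * sum(terms) + params.constant_c


def cavity_term(delta_msa_value: float, params: SIEParameters | None = None) -> float:
    """gamma * dMSA, kcal/mol."""
    params = params or SIEParameters()
    if not math.isfinite(delta_msa_value):
        raise ValueError("non-finite dMSA")
    return params.gamma * delta_msa_value


def score_snapshot(
    receptor: AtomSelection,
    ligand: AtomSelection,
    params: SIEParameters | None = None,
    grid: GridSpec | None = None,
    frame: np.ndarray | None = None,
) -> SIEComponents:
    """All SIE terms for one complex snapshot.

    The receptor and ligand selections must partition the complex system.
    """
    params = params or SIEParameters()
    pair = pair_energies(receptor, ligand, d_in=params.d_in, frame=frame)
    rf = delta_reaction_field(
        receptor, ligand,
        d_in=params.d_in, d_solv=params.d_solv, rho=params.rho,
        grid=grid, frame=frame,
    )
    dmsa = delta_msa(
        receptor, ligand,
        probe=params.probe, rho=params.rho,
        n_points=params.n_surface_points, frame=frame,
    )
    cav = cavity_term(dmsa, params)
    total = combine_sie(pair.vdw, pair.coulomb, rf, cav, params)
    return SIEComponents(
        inter_vdw=pair.vdw,
        inter_coulomb=pair.coulomb,
        reaction_field=rf,
        cavity=cav,
        constant=params.constant_c,
        total=total,
    )


@dataclass(frozen=True)
class TrajectorySIE:
    """Per-frame components plus per-term mean and standard error of the
    mean (SEM = sample stddev / sqrt(n); 0 by convention when n = 1)."""

    frames: list[SIEComponents]
    mean: dict[str, float]
    sem: dict[str, float]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        """Term table (rows: terms; columns: mean, sem)."""
        return pd.DataFrame(
            {"mean": self.mean, "sem": self.sem},
            index=pd.Index(TERM_ORDER, name="term"),
        )


def _aggregate(per_frame: list[SIEComponents]) -> TrajectorySIE:
    n = len(per_frame)
    if n == 1:
        log.info("single-frame trajectory: SEM reported as 0 by convention")
    mean: dict[str, float] = {}
    sem: dict[str, float] = {}
    for term in TERM_ORDER:
        values = np.array([getattr(c, term) for c in per_frame])
        mean[term] = float(values.mean())
        sem[term] = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return TrajectorySIE(frames=per_frame, mean=mean, sem=sem)


def score_trajectory(
    traj: Trajectory,
    receptor: AtomSelection,
    ligand: AtomSelection,
    params: SIEParameters | None = None,
    grid: GridSpec | None = None,
    stride: int = 1,
) -> TrajectorySIE:
    """Score every ``stride``-th frame and aggregate to mean +/- SEM."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    per_frame = [
        score_snapshot(receptor, ligand, params, grid, frame=f)
        for f in traj.frames[::stride]
    ]
    return _aggregate(per_frame)


# --------------------------------------------------- components-only scoring

def load_component_table(path: str | Path) -> pd.DataFrame:
    """Read a term table (TSV; rows inter_vdw, inter_coulomb,
    reaction_field, cavity; one column per complex)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="term")
    missing = [t for t in TERM_ORDER[:4] if t not in df.index]
    if missing:
        raise ValueError(f"component table {path}: missing rows {missing}")
    return df


def default_component_table() -> pd.DataFrame:
    """The published per-term components for the three chitinase 1198
    complexes, shipped as worked-example input."""
    with resources.as_file(
        resources.files("siechit") / "data" / "sie_components_chitinase1198.tsv"
    ) as p:
        return load_component_table(p)


def score_component_table(
    components: pd.DataFrame, params: SIEParameters | None = None
) -> pd.DataFrame:
    """Apply the SIE combination to each column of a pre-computed term
    table; returns the table extended with constant and total rows."""
    params = params or SIEParameters()
    out = components.copy()
    totals = {}
    for col in components.columns:
        totals[col] = combine_sie(
            components.at["inter_vdw", col],
            components.at["inter_coulomb", col],
            components.at["reaction_field", col],
            components.at["cavity", col],
            params,
        )
    out.loc["constant"] = params.constant_c
    out.loc["total"] = pd.Series(totals)
    return out.loc[TERM_ORDER]
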