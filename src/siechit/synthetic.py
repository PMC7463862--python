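"""Seeded generators for toy parameterized complexes and mock trajectories.

The toy complex emulates the binding-site geometry the analysis assumes: a
rigid receptor "pocket" — a ring of neutral/charged pseudo-atoms plus one
aspartate carboxylate fixed at residue number 440 — facing a linear chain
of pseudo-GlcNAc units (residue name NAG, numbered sequentially from the
nonreducing end, i.e. unit 1 is the nonreducing terminus). Each
pseudo-sugar is a 4-atom caricature (ring-center carbon C1, acetamido
nitrogen N2, amide oxygen O7, hydroxyl oxygen O3), not real carbohydrate
topology; that is sufficient for every term the package computes.

One designed contact — the amide nitrogen of a chosen sugar unit against
the nearer carboxylate oxygen (OD2) of Asp440 — is placed at a specified
distance. Mock trajectories redraw that contact distance i.i.d. from a
truncated normal (d > 0) along the fixed contact axis while every other
atom is perturbed by i.i.d. Gaussian jitter, so the contact-distance
distribution (and hence RDF peak position and hydrogen-bond occupancy) is
known exactly by construction. Everything is deterministic for a given
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .atoms import MolecularSystem, ParameterizedAtom, Trajectory, select
from .params import assign_parameters, default_parameter_table

__all__ = [
    "ToyComplexSpec",
    "build_toy_complex",
    "generate_trajectory",
    "study_conditions",
]

_SUGAR_SPACING = 5.0   # A between consecutive pseudo-GlcNAc units
_POCKET_RADIUS = 7.0   # A, pocket ring radius
_POCKET_Y = -3.0       # A, pocket ring plane below the carboxylate


@dataclass(frozen=True)
class ToyComplexSpec:
    """Study-condition parameters of the generator.

    Defaults mirror the short-oligomer condition: a trimer chain contacting
    Asp440 through its second unit at a 2.8 A donor-acceptor distance
    (within the 3.0 A hydrogen-bond criterion), with 0.1 A contact spread
    and small thermal jitter on all other atoms.
    """

    n_sugar_units: int = 3
    pocket_atoms: int = 8
    contact_unit: int = 2
    contact_distance_mean: float = 2.8   # A
    contact_distance_sd: float = 0.1     # A
    jitter_sd: float = 0.05              # A, all non-contact atoms
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.contact_unit <= self.n_sugar_units:
            raise ValueError("contact_unit must lie within the sugar chain")
        if self.contact_distance_sd < 0 or self.jitter_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.contact_distance_mean <= 0:
            raise ValueError("contact distance must be positive")
        if self.pocket_atoms < 2:
            raise ValueError("pocket needs at least two ring atoms")


def build_toy_complex(spec: ToyComplexSpec) -> MolecularSystem:
    """Deterministic toy pocket-oligosaccharide complex, fully
    parameterized from the shipped table.

    Chain A holds the pocket (ring residues POC 501.., carboxylate ASP
    440 with OD2 at the origin); chain B holds NAG residues 1..n from the
    nonreducing end. The contact unit's N2 sits exactly
    ``contact_distance_mean`` from OD2 along +y.
    """
    atoms: list[ParameterizedAtom] = []

    def add(name: str, element: str, pos, chain: str, resname: str, resnum: int) -> None:
        atoms.append(
            ParameterizedAtom(
                name=name, element=element, position=np.array(pos, dtype=float),
                residue_id=(chain, resname, resnum),
            )
        )

    # Asp440 carboxylate: OD2 at the origin is the contact reference
    add("CG", "C", (0.0, -1.25, 0.0), "A", "ASP", 440)
    add("OD1", "O", (1.08, -1.85, 0.0), "A", "ASP", 440)
    add("OD2", "O", (0.0, 0.0, 0.0), "A", "ASP", 440)

    # pocket ring in the y = _POCKET_Y plane, alternating neutral/charged
    for i in range(spec.pocket_atoms):
        angle = 2.0 * np.pi * i / spec.pocket_atoms
        pos = (
            _POCKET_RADIUS * np.cos(angle),
            _POCKET_Y,
            _POCKET_RADIUS * np.sin(angle),
        )
        name = "CQ" if i % 2 else "CP"
        add(name, "C", pos, "A", "POC", 501 + i)

    # linear pseudo-GlcNAc chain along x; unit 1 = nonreducing end
    d0 = spec.contact_distance_mean
    for unit in range(1, spec.n_sugar_units + 1):
        x = (unit - spec.contact_unit) * _SUGAR_SPACING
        add("N2", "N", (x, d0, 0.0), "B", "NAG", unit)
        add("C1", "C", (x, d0 + 1.45, 0.0), "B", "NAG", unit)
        add("O7", "O", (x + 1.20, d0 + 2.05, 0.0), "B", "NAG", unit)
        add("O3", "O", (x - 1.20, d0 + 2.05, 0.55), "B", "NAG", unit)

    system = MolecularSystem(atoms, tag=f"toy-{spec.n_sugar_units}mer-u{spec.contact_unit}")
    return assign_parameters(system, default_parameter_table())


def _contact_indices(system: MolecularSystem, spec: ToyComplexSpec) -> tuple[int, int]:
    """(index of reference OD2, index of the contact unit's N2)."""
    od2 = select(system, f"resid 440 and name OD2")
    n2 = select(
        system,
        f"resname NAG and resid {spec.contact_unit} and name N2",
    )
    return int(od2.indices[0]), int(n2.indices[0])


def generate_trajectory(
    complex_system: MolecularSystem, spec: ToyComplexSpec, n_frames: int
) -> Trajectory:
    """Mock MD trajectory with an exactly-known contact-distance law.

    Per frame the designed contact distance is drawn from
    Normal(contact_distance_mean, contact_distance_sd) truncated at d > 0
    and imposed along the fixed +y contact axis (the reference OD2 and the
    contact N2 are the only unjittered atoms); all other atoms receive
    i.i.d. Normal(0, jitter_sd) displacements. Reproducible for a given
    spec.seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    i_od2, i_n2 = _contact_indices(complex_system, spec)
    base = complex_system.coords
    axis = np.array([0.0, 1.0, 0.0])

    if spec.contact_distance_sd > 0:
        a = (0.0 - spec.contact_distance_mean) / spec.contact_distance_sd
        dist = stats.truncnorm.rvs(
            a, np.inf,
            loc=spec.contact_distance_mean,
            scale=spec.contact_distance_sd,
            size=n_frames,
            random_state=rng,
        )
    else:
        dist = np.full(n_frames, spec.contact_distance_mean)

    frames = []
    for t in range(n_frames):
        coords = base.copy()
        if spec.jitter_sd > 0:
            coords += rng.normal(0.0, spec.jitter_sd, size=coords.shape)
        coords[i_od2] = base[i_od2]
        coords[i_n2] = base[i_od2] + dist[t] * axis
        frames.append(coords)
    return Trajectory(complex_system, frames)


def study_conditions(seed: int = 0) -> dict[str, ToyComplexSpec]:
    """The three emulated study conditions, keyed like the component table.

    Oligomer length and contact unit follow the three reported complexes;
    each condition's designed contact-distance mode is the RDF peak
    position reported for it (12-mer/unit-2: 2.75 A; 12-mer/unit-3:
    2.25 A; trimer/unit-2: 3.25 A).
    """
    return {
        "glcnac12_unit2": ToyComplexSpec(
            n_sugar_units=12, contact_unit=2, contact_distance_mean=2.75,
            contact_distance_sd=0.1, jitter_sd=0.05, seed=seed,
        ),
        "glcnac12_unit3": ToyComplexSpec(
            n_sugar_units=12, contact_unit=3, contact_distance_mean=2.25,
            contact_distance_sd=0.1, jitter_sd=0.05, seed=seed + 1,
        ),
        "glcnac3_unit2": ToyComplexSpec(
            n_sugar_units=3, contact_unit=2, contact_distance_mean=3.25,
            contact_distance_sd=0.1, jitter_sd=0.05, seed=seed + 2,
        ),
    }
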