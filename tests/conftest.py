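"""Shared fixtures: toy systems, random parameterized complexes, oracles."""

import numpy as np
import pytest

from siechit.atoms import MolecularSystem, ParameterizedAtom, select
from siechit.synthetic import ToyComplexSpec, build_toy_complex, generate_trajectory


def make_atom(
    name="C1",
    element="C",
    pos=(0.0, 0.0, 0.0),
    residue=("A", "LIG", 1),
    charge=0.0,
    eps=0.1,
    rmin_half=1.9,
    radius=1.7,
):
    return ParameterizedAtom(
        name=name,
        element=element,
        position=np.array(pos, dtype=float),
        residue_id=residue,
        charge=charge,
        lj_epsilon=eps,
        lj_rmin_half=rmin_half,
        boundary_radius=radius,
    )


def random_two_group_system(rng, n_receptor=8, n_ligand=6, spread=6.0):
    """Random parameterized system split into receptor chain A / ligand
    chain B, with a minimum pair separation so LJ stays finite."""
    while True:
        coords = rng.uniform(-spread, spread, size=(n_receptor + n_ligand, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() > 1.0:
            break
    atoms = []
    for i, c in enumerate(coords):
        chain = "A" if i < n_receptor else "B"
        atoms.append(
            make_atom(
                name=f"X{i}",
                pos=c,
                residue=(chain, "RES", i + 1),
                charge=float(rng.uniform(-0.8, 0.8)),
                eps=float(rng.uniform(0.05, 0.3)),
                rmin_half=float(rng.uniform(1.2, 2.0)),
                radius=float(rng.uniform(1.2, 1.9)),
            )
        )
    system = MolecularSystem(atoms, tag="random")
    return system, select(system, "chain A"), select(system, "chain B")


def brute_force_energies(receptor, ligand, d_in, k=332.0716):
    """O(N^2) double-loop Coulomb and Lennard-Jones oracle."""
    ec = 0.0
    ev = 0.0
    for ai in receptor.atoms():
        for aj in ligand.atoms():
            r = float(np.linalg.norm(ai.position - aj.position))
            ec += k * ai.charge * aj.charge / (d_in * r)
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            ev += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    return ec, ev


@pytest.fixture
def toy_spec():
    return ToyComplexSpec(
        n_sugar_units=3,
        contact_unit=2,
        contact_distance_mean=2.75,
        contact_distance_sd=0.1,
        jitter_sd=0.05,
        seed=11,
    )


@pytest.fixture
def toy_complex(toy_spec):
    return build_toy_complex(toy_spec)


@pytest.fixture
def toy_trajectory(toy_spec, toy_complex):
    return generate_trajectory(toy_complex, toy_spec, n_frames=50)
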