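"""Poisson reaction field against Born/Kirkwood closed forms; surface area
against sphere/cap closed forms; binding-difference sign properties."""

import math

import numpy as np
import pytest
from scipy.special import eval_legendre

from siechit.atoms import MolecularSystem, select
from siechit.energy import COULOMB_K
from siechit.solvation import (
    GridSpec,
    born_reaction_field,
    delta_msa,
    delta_reaction_field,
    molecular_surface_area,
    reaction_field_energy,
)
from conftest import make_atom

DIN, DSOLV = 2.25, 78.5


def ion(q=1.0, radius=2.0, pos=(0.0, 0.0, 0.0)):
    return MolecularSystem(
        [make_atom(name="ION", pos=pos, charge=q, radius=radius)], tag="ion"
    )


def kirkwood_reaction_field(charges, positions, a, d_in, d_solv, lmax=40):
    """Analytic multipole-expansion oracle for charges inside a spherical
    cavity of radius a."""
    positions = np.asarray(positions, dtype=float)
    rs = np.linalg.norm(positions, axis=1)
    total = 0.0
    for ell in range(lmax + 1):
        f = (ell + 1) * (d_solv - d_in) / (d_in * ((ell + 1) * d_solv + ell * d_in))
        s = 0.0
        for qi, pi, ri in zip(charges, positions, rs):
            for qj, pj, rj in zip(charges, positions, rs):
                ct = 1.0 if ri * rj == 0 else float(np.dot(pi, pj) / (ri * rj))
                s += qi * qj * (ri * rj / a**2) ** ell * eval_legendre(ell, ct)
        total += f * s
    return -COULOMB_K / (2.0 * a) * total


class TestReactionField:
    def test_born_ion_within_five_percent(self):
        exact = born_reaction_field(1.0, 2.0, DIN, DSOLV)
        assert exact == pytest.approx(-35.84, abs=0.01)
        grid = GridSpec(spacing=0.5, padding=6.0)
        numeric = reaction_field_energy(ion(), d_in=DIN, d_solv=DSOLV, rho=1.0, grid=grid)
        assert abs(numeric - exact) / abs(exact) < 0.05

    def test_no_dielectric_contrast_gives_zero(self):
        grid = GridSpec(spacing=0.7, padding=6.0)
        e = reaction_field_energy(ion(), d_in=DIN, d_solv=DIN, rho=1.0, grid=grid)
        assert abs(e) < 1e-3

    def test_off_center_charges_match_kirkwood(self):
        # two charges in a 2 A cavity defined by a neutral central atom
        charges = [1.0, -0.5]
        positions = [(0, 0, 0.5), (0, 0, -0.5)]
        atoms = [make_atom(name="CAV", residue=("A", "ION", 1), charge=0.0, radius=2.0)]
        for i, (q, p) in enumerate(zip(charges, positions)):
            atoms.append(
                make_atom(name=f"Q{i}", pos=p, residue=("A", "ION", 1), charge=q, radius=0.4)
            )
        system = MolecularSystem(atoms)
        exact = kirkwood_reaction_field(charges, positions, 2.0, DIN, DSOLV)
        numeric = reaction_field_energy(
            system, d_in=DIN, d_solv=DSOLV, rho=1.0, grid=GridSpec(spacing=0.4, padding=6.0)
        )
        assert abs(numeric - exact) / abs(exact) < 0.08

    def test_quadratic_in_charge_scaling(self):
        grid = GridSpec(spacing=0.7, padding=6.0)
        e1 = reaction_field_energy(ion(q=0.5), rho=1.0, grid=grid)
        e2 = reaction_field_energy(ion(q=1.0), rho=1.0, grid=grid)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-3)

    def test_translation_invariance_within_discretization_noise(self):
        grid = GridSpec(spacing=0.7, padding=6.0)
        e0 = reaction_field_energy(ion(), rho=1.0, grid=grid)
        e1 = reaction_field_energy(ion(pos=(0.31, 0.17, -0.23)), rho=1.0, grid=grid)
        assert abs(e1 - e0) / abs(e0) < 0.02


class TestDeltaReactionField:
    def grid(self):
        return GridSpec(spacing=1.0, padding=6.0)

    def test_separated_neutral_partners_give_zero(self):
        """Non-interacting limit: net-neutral (dipolar) partners 100 A
        apart contribute nothing to the binding reaction field. (For
        net-charged partners the reaction field legitimately carries the
        solvent-screening correction to the 1/r pair interaction, which
        is only cancelled by the screened-Coulomb term.)"""
        atoms = [
            make_atom(name="A1", pos=(0, 0, 0), residue=("A", "REC", 1), charge=0.5, radius=1.8),
            make_atom(name="A2", pos=(2, 0, 0), residue=("A", "REC", 2), charge=-0.5, radius=1.8),
            make_atom(name="B1", pos=(100, 0, 0), residue=("B", "LIG", 3), charge=0.5, radius=1.8),
            make_atom(name="B2", pos=(102, 0, 0), residue=("B", "LIG", 4), charge=-0.5, radius=1.8),
        ]
        system = MolecularSystem(atoms)
        d = delta_reaction_field(
            select(system, "chain A"), select(system, "chain B"),
            rho=1.0, grid=self.grid(),
        )
        assert abs(d) < 0.05  # solver tolerance scale

    def test_desolvation_penalty_is_positive(self):
        # charged probe docked into a neutral two-atom pocket
        atoms = [
            make_atom(name="P1", pos=(-2.4, 0, 0), residue=("A", "REC", 1), charge=0.0, radius=1.8),
            make_atom(name="P2", pos=(2.4, 0, 0), residue=("A", "REC", 2), charge=0.0, radius=1.8),
            make_atom(name="Q1", pos=(0, 0.5, 0), residue=("B", "LIG", 3), charge=1.0, radius=1.6),
        ]
        system = MolecularSystem(atoms)
        d = delta_reaction_field(
            select(system, "chain A"), select(system, "chain B"),
            rho=1.0, grid=GridSpec(spacing=0.5, padding=6.0),
        )
        assert d > 0

    def test_bound_toy_complex_penalty_positive(self, toy_complex):
        """Binding a polar ligand into the pocket loses solvation: the
        reaction-field change is positive, as for all three reported
        chitinase complexes."""
        d = delta_reaction_field(
            select(toy_complex, "chain A"), select(toy_complex, "chain B"),
            grid=self.grid(),
        )
        assert d > 0


class TestSurfaceArea:
    def test_single_sphere_area(self):
        system = MolecularSystem([make_atom(radius=1.7)])
        rho, probe = 1.1, 1.4
        sa = molecular_surface_area(system, probe=probe, rho=rho, n_points=960)
        exact = 4 * math.pi * (1.7 * rho + probe) ** 2
        assert sa.total == pytest.approx(exact, rel=0.005)

    def test_disjoint_spheres_add(self):
        atoms = [
            make_atom(name="A1", pos=(0, 0, 0), residue=("A", "X", 1), radius=1.5),
            make_atom(name="B1", pos=(100, 0, 0), residue=("A", "X", 2), radius=1.8),
        ]
        system = MolecularSystem(atoms)
        sa = molecular_surface_area(system, probe=1.4, rho=1.0)
        assert sa.total == pytest.approx(sa.per_atom.sum(), rel=1e-12)
        each = [
            molecular_surface_area(
                MolecularSystem([a]), probe=1.4, rho=1.0
            ).total
            for a in atoms
        ]
        assert sa.total == pytest.approx(sum(each), rel=1e-12)

    def test_two_overlapping_spheres_match_cap_formula(self):
        r1 = r2 = 2.0  # inflated radii: unit spheres, rho=1, probe=1
        d = 2.5
        atoms = [
            make_atom(name="A1", pos=(0, 0, 0), residue=("A", "X", 1), radius=1.0),
            make_atom(name="B1", pos=(d, 0, 0), residue=("A", "X", 2), radius=1.0),
        ]
        system = MolecularSystem(atoms)
        sa = molecular_surface_area(system, probe=1.0, rho=1.0, n_points=4000)
        h1 = r1 - (d * d + r1 * r1 - r2 * r2) / (2 * d)
        h2 = r2 - (d * d + r2 * r2 - r1 * r1) / (2 * d)
        exact = 4 * math.pi * r1**2 - 2 * math.pi * r1 * h1
        exact += 4 * math.pi * r2**2 - 2 * math.pi * r2 * h2
        assert sa.total == pytest.approx(exact, rel=0.01)

    def test_deterministic_for_fixed_n_points(self, toy_complex):
        a = molecular_surface_area(toy_complex)
        b = molecular_surface_area(toy_complex)
        np.testing.assert_array_equal(a.per_atom, b.per_atom)


class TestDeltaMSA:
    def test_separated_partners_zero(self):
        atoms = [
            make_atom(name="A1", pos=(0, 0, 0), residue=("A", "X", 1)),
            make_atom(name="B1", pos=(100, 0, 0), residue=("B", "Y", 2)),
        ]
        system = MolecularSystem(atoms)
        d = delta_msa(select(system, "chain A"), select(system, "chain B"))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_contacting_complex_buries_area(self, toy_complex):
        """Burial on binding: negative surface-area change, matching the
        sign of the reported cavity terms."""
        d = delta_msa(
            select(toy_complex, "chain A"), select(toy_complex, "chain B")
        )
        assert d < 0
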