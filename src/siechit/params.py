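"""Per-atom physical parameter assignment from a plain-text TSV table.

The table maps either an exact (residue name, atom name) pair or an element
fallback (rows with residue ``*`` and atom ``*``) to partial charge (e),
Lennard-Jones well depth (kcal/mol), LJ minimum-energy half-distance (A) and
dielectric-boundary radius (A). Lookup precedence: exact (residue, atom)
match first, then element fallback, else a missing-parameter error.

The shipped table (``data/atom_parameters.tsv``) is a minimal
self-consistent set — carboxylate O/C, amide N, ring/aliphatic C, hydroxyl
O, water — sufficient for the toy pocket/oligosaccharide systems the
package generates; a full force-field import is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .atoms import MolecularSystem, ParameterizedAtom

__all__ = [
    "AtomParameters",
    "ParameterTable",
    "load_parameter_table",
    "default_parameter_table",
    "assign_parameters",
    "MissingParameterError",
]


class MissingParameterError(KeyError):
    """No (residue, atom) entry and no element fallback for an atom."""


@dataclass(frozen=True)
class AtomParameters:
    charge: float
    lj_epsilon: float
    lj_rmin_half: float
    boundary_radius: float


@dataclass(frozen=True)
class ParameterTable:
    by_residue_atom: dict[tuple[str, str], AtomParameters]
    by_element: dict[str, AtomParameters]

    def lookup(self, atom: ParameterizedAtom) -> AtomParameters:
        _, resname, _ = atom.residue_id
        exact = self.by_residue_atom.get((resname, atom.name))
        if exact is not None:
            return exact
        fallback = self.by_element.get(atom.element.upper())
        if fallback is not None:
            return fallback
        raise MissingParameterError(
            f"no parameters for atom {atom.name!r} (residue {resname!r}, "
            f"element {atom.element!r}) and no element fallback"
        )


_COLUMNS = ["residue", "atom", "element", "charge", "lj_epsilon", "lj_rmin_half", "boundary_radius"]


def load_parameter_table(path: str | Path) -> ParameterTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"residue": str, "atom": str, "element": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table {path}: missing columns {missing}")
    by_ra: dict[tuple[str, str], AtomParameters] = {}
    by_el: dict[str, AtomParameters] = {}
    for row in df.itertuples(index=False):
        p = AtomParameters(
            charge=float(row.charge),
            lj_epsilon=float(row.lj_epsilon),
            lj_rmin_half=float(row.lj_rmin_half),
            boundary_radius=float(row.boundary_radius),
        )
        if row.residue == "*" and row.atom == "*":
            by_el[str(row.element).upper()] = p
        else:
            by_ra[(str(row.residue), str(row.atom))] = p
    return ParameterTable(by_ra, by_el)


def default_parameter_table() -> ParameterTable:
    """The parameter set shipped with the package."""
    with resources.as_file(
        resources.files("siechit") / "data" / "atom_parameters.tsv"
    ) as p:
        return load_parameter_table(p)


def assign_parameters(
    system: MolecularSystem, table: ParameterTable, strict: bool = True
) -> MolecularSystem:
    """Return a new system with every atom parameterized from the table.

    Idempotent: re-applying the same table reproduces the same parameters.
    With ``strict=False`` unmatched atoms are left as-is instead of raising.
    """
    new_atoms = []
    for atom in system.atoms:
        try:
            p = table.lookup(atom)
        except MissingParameterError:
            if strict:
                raise
            new_atoms.append(replace(atom, position=atom.position.copy()))
            continue
        new_atoms.append(
            replace(
                atom,
                position=atom.position.copy(),
                charge=p.charge,
                lj_epsilon=p.lj_epsilon,
                lj_rmin_half=p.lj_rmin_half,
                boundary_radius=p.boundary_radius,
            )
        )
    return MolecularSystem(new_atoms, tag=system.tag)
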