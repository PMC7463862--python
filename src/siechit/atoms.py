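"""Domain types: parameterized atoms, molecular systems, trajectories, selections.

All coordinates are in Angstrom, charges in elementary charge units (e),
energies in kcal/mol. Residues are addressed by the author numbering read
from the PDB (no re-indexing), so the catalytic aspartate of chitinase 1198
is addressed as residue 440 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ParameterizedAtom",
    "MolecularSystem",
    "Trajectory",
    "AtomSelection",
    "select",
    "SelectionError",
]

#: (chain id, residue name, residue number)
ResidueId = tuple[str, str, int]


class SelectionError(ValueError):
    """Raised for empty, overlapping or out-of-range atom selections."""


@dataclass
class ParameterizedAtom:
    """One atom with coordinates and per-atom physical parameters.

    Physical parameters (charge, Lennard-Jones well depth ``lj_epsilon`` and
    minimum-energy half-distance ``lj_rmin_half``, dielectric-boundary radius
    before the global rho scaling) are NaN placeholders until a parameter
    table is applied; energetic routines refuse unparameterized atoms.
    """

    name: str
    element: str
    position: np.ndarray
    residue_id: ResidueId
    charge: float = math.nan
    lj_epsilon: float = math.nan
    lj_rmin_half: float = math.nan
    boundary_radius: float = math.nan

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        for attr in ("lj_epsilon", "lj_rmin_half", "boundary_radius"):
            v = getattr(self, attr)
            if not math.isnan(v):
                if attr == "lj_epsilon" and v < 0:
                    raise ValueError(f"atom {self.name}: lj_epsilon must be >= 0")
                if attr != "lj_epsilon" and v <= 0:
                    raise ValueError(f"atom {self.name}: {attr} must be > 0")

    @property
    def parameterized(self) -> bool:
        return not any(
            math.isnan(v)
            for v in (self.charge, self.lj_epsilon, self.lj_rmin_half, self.boundary_radius)
        )


@dataclass
class MolecularSystem:
    """An ordered collection of atoms with a free-text tag.

    Invariant: a (chain, residue number) pair maps to exactly one residue
    name — an atom cannot belong to two residues.
    """

    atoms: list[ParameterizedAtom]
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a MolecularSystem needs at least one atom")
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            chain, resname, resnum = a.residue_id
            key = (chain, resnum)
            if seen.setdefault(key, resname) != resname:
                raise ValueError(
                    f"residue {key} has inconsistent names "
                    f"({seen[key]!r} vs {resname!r})"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def boundary_radii(self) -> np.ndarray:
        return np.array([a.boundary_radius for a in self.atoms], dtype=float)

    @property
    def parameterized(self) -> bool:
        return all(a.parameterized for a in self.atoms)

    def require_parameterized(self) -> None:
        bad = [a.name for a in self.atoms if not a.parameterized]
        if bad:
            raise ValueError(
                f"system {self.tag!r}: {len(bad)} unparameterized atom(s), "
                f"e.g. {bad[:5]}; apply assign_parameters first"
            )

    def subset(self, indices: Sequence[int], tag: str = "") -> "MolecularSystem":
        """New system holding copies of the selected atoms, original order."""
        idx = sorted(int(i) for i in indices)
        return MolecularSystem(
            [replace(self.atoms[i], position=self.atoms[i].position.copy()) for i in idx],
            tag=tag or self.tag,
        )


@dataclass
class Trajectory:
    """A topology plus per-frame coordinates (same atom count and order)."""

    topology: MolecularSystem
    frames: list[np.ndarray]
    frame_times: list[float] | None = None  # ps

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a Trajectory needs at least one frame")
        n = len(self.topology)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )
        if self.frame_times is not None and len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must match frame count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class AtomSelection:
    """A resolved list of atom indices into a MolecularSystem.

    Selections resolve against the topology, so the same indices address the
    same atoms in every trajectory frame.
    """

    system: MolecularSystem
    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise SelectionError(f"selection {self.expression!r} matched no atoms")
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError("selection indices must be unique")
        if self.indices.min() < 0 or self.indices.max() >= len(self.system):
            raise SelectionError("selection index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def coords(self, frame: np.ndarray | None = None) -> np.ndarray:
        """Coordinates of the selected atoms, from the topology or a frame."""
        base = self.system.coords if frame is None else np.asarray(frame, float)
        return base[self.indices]

    def atoms(self) -> list[ParameterizedAtom]:
        return [self.system.atoms[i] for i in self.indices]

    def charges(self) -> np.ndarray:
        return self.system.charges[self.indices]

    def disjoint(self, other: "AtomSelection") -> bool:
        return not set(self.indices.tolist()) & set(other.indices.tolist())


_FIELDS = ("name", "resname", "resid", "chain", "element")


def _match_clause(atom: ParameterizedAtom, key: str, values: list[str]) -> bool:
    chain, resname, resnum = atom.residue_id
    if key == "name":
        return atom.name in values
    if key == "resname":
        return resname in values
    if key == "resid":
        return str(resnum) in values
    if key == "chain":
        return chain in values
    if key == "element":
        return atom.element.upper() in [v.upper() for v in values]
    raise SelectionError(f"unknown selection keyword {key!r}")


def select(
    system: MolecularSystem,
    expression: str | None = None,
    predicate: Callable[[ParameterizedAtom], bool] | None = None,
    indices: Iterable[int] | None = None,
) -> AtomSelection:
    """Resolve a selection by mini-expression, predicate, or explicit indices.

    The expression grammar is a conjunction of clauses joined by ``and``;
    each clause is a keyword (``name``, ``resname``, ``resid``, ``chain``,
    ``element``) followed by one or more values combined by OR, optionally
    negated with a leading ``not``::

        "resid 440 and name OD1 OD2"
        "resname NAG and name N2"
        "not element H"
    """
    given = sum(x is not None for x in (expression, predicate, indices))
    if given != 1:
        raise SelectionError("give exactly one of expression, predicate, indices")
    if indices is not None:
        return AtomSelection(system, np.fromiter(indices, dtype=int), expression="<indices>")
    if predicate is not None:
        idx = [i for i, a in enumerate(system.atoms) if predicate(a)]
        return AtomSelection(system, np.array(idx, dtype=int), expression="<predicate>")

    assert expression is not None
    clauses: list[tuple[bool, str, list[str]]] = []
    for part in expression.split(" and "):
        tokens = part.split()
        if not tokens:
            raise SelectionError(f"empty clause in {expression!r}")
        negate = False
        if tokens[0] == "not":
            negate = True
            tokens = tokens[1:]
        if not tokens or tokens[0] not in _FIELDS:
            raise SelectionError(
                f"clause must start with one of {_FIELDS}, got {part!r}"
            )
        key, values = tokens[0], tokens[1:]
        if not values:
            raise SelectionError(f"keyword {key!r} needs at least one value")
        clauses.append((negate, key, values))

    idx = [
        i
        for i, a in enumerate(system.atoms)
        if all(_match_clause(a, k, v) != neg for neg, k, v in clauses)
    ]
    return AtomSelection(system, np.array(idx, dtype=int), expression=expression)
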