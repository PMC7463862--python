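"""PDB and multi-model PDB input/output.

Reading and writing go through gemmi; a light pre-scan of ATOM/HETATM
records supplies line-numbered diagnostics for malformed coordinate or
numbering fields (gemmi itself is forgiving). MODEL/ENDMDL blocks are
interpreted as trajectory frames. HETATM and ATOM are treated identically;
alternate locations other than blank/'A' are dropped with a warning.

Coordinates are Angstrom; files written in nm can be read with
``coordinates_in_nm=True`` which rescales by 10 on input.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import gemmi
import numpy as np

from .atoms import MolecularSystem, ParameterizedAtom, Trajectory

__all__ = ["read_pdb", "write_pdb", "PDBParseError", "PDBStructureError"]

log = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """A malformed ATOM/HETATM record; the message names the line number."""


class PDBStructureError(ValueError):
    """Structurally inconsistent file (e.g. models with differing atoms)."""


def _prescan(text: str) -> None:
    """Validate the fixed-column numeric fields of every coordinate record."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        for colspan, label in (
            ((30, 38), "x"), ((38, 46), "y"), ((46, 54), "z"),
        ):
            fieldtxt = line[colspan[0]:colspan[1]]
            try:
                value = float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: cannot parse {label} coordinate {fieldtxt!r}"
                ) from None
            if not math.isfinite(value):
                raise PDBParseError(f"line {lineno}: non-finite {label} coordinate")
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: cannot parse residue number {line[22:26]!r}"
            ) from None


def _model_to_atoms(model: gemmi.Model, scale: float) -> list[ParameterizedAtom]:
    atoms: list[ParameterizedAtom] = []
    dropped = 0
    for chain in model:
        for res in chain:
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    dropped += 1
                    continue
                atoms.append(
                    ParameterizedAtom(
                        name=at.name,
                        element=at.element.name.strip(),
                        position=scale * np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_id=(chain.name, res.name, res.seqid.num),
                    )
                )
    if dropped:
        log.warning("dropped %d alternate-location atoms (altloc not blank/'A')", dropped)
    return atoms


def read_pdb(
    path: str | Path, coordinates_in_nm: bool = False, tag: str | None = None
) -> MolecularSystem | Trajectory:
    """Read a PDB file into a MolecularSystem, or a Trajectory when the file
    carries multiple MODEL blocks.

    The returned atoms have name/element/residue identity but NaN physical
    parameters; apply :func:`siechit.params.assign_parameters` before any
    energetics.
    """
    path = Path(path)
    text = path.read_text()
    _prescan(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBStructureError(f"{path}: no models found")
    scale = 10.0 if coordinates_in_nm else 1.0
    label = tag if tag is not None else path.stem

    first = _model_to_atoms(st[0], scale)
    if not first:
        raise PDBStructureError(f"{path}: no atoms found")
    if len(st) == 1:
        return MolecularSystem(first, tag=label)

    frames = []
    for i, model in enumerate(st):
        atoms = _model_to_atoms(model, scale)
        if len(atoms) != len(first):
            raise PDBStructureError(
                f"{path}: model {i + 1} has {len(atoms)} atoms, "
                f"model 1 has {len(first)}"
            )
        frames.append(np.array([a.position for a in atoms]))
    return Trajectory(MolecularSystem(first, tag=label), frames)


_COORD_LIMIT = 10000.0  # PDB %8.3f field range


def _build_structure(system: MolecularSystem, frames: list[np.ndarray]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = system.tag or "siechit"
    for imodel, frame in enumerate(frames, start=1):
        if np.any(np.abs(frame) >= _COORD_LIMIT):
            raise ValueError(
                f"model {imodel}: coordinates exceed the PDB %8.3f field range"
            )
        model = st.add_model(gemmi.Model(str(imodel)))
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple[str, int], gemmi.Residue] = {}
        for atom, pos in zip(system.atoms, frame):
            chain_id, resname, resnum = atom.residue_id
            if chain_id not in chain_map:
                # gemmi add_* copy their argument: keep the stored reference
                chain_map[chain_id] = model.add_chain(gemmi.Chain(chain_id))
            key = (chain_id, resnum)
            if key not in res_map:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, " ")
                res.het_flag = "A"
                res_map[key] = chain_map[chain_id].add_residue(res)
            at = gemmi.Atom()
            at.name = atom.name
            at.element = gemmi.Element(atom.element or "X")
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            at.b_iso = 0.0
            res_map[key].add_atom(at)
    return st


def write_pdb(obj: MolecularSystem | Trajectory, path: str | Path) -> None:
    """Write a system (single model) or trajectory (MODEL/ENDMDL blocks).

    Output is deterministic: no timestamps, fixed column formatting, so two
    writes of the same object are byte-identical.
    """
    if isinstance(obj, Trajectory):
        system, frames = obj.topology, obj.frames
    else:
        system, frames = obj, [obj.coords]
    st = _build_structure(system, frames)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())
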