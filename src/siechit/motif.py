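"""GH18 catalytic-motif location and sequence utilities.

Family 18 glycoside hydrolases carry the conserved active-site motif
DXXDXDXE: the last aspartate hydrogen-bonds the acetamido nitrogen of the
substrate GlcNAc and the glutamate is the catalytic acid that cleaves the
glycosidic bond. For a match starting at 1-based position s, the catalytic
residues are the last D at s+5 and the E at s+7 — the convention under
which chitinase 1198's motif places the catalytic aspartate at residue 440.

Coordinates are 1-based throughout. In the PATTERN, 'X' is a wildcard for
any standard residue; in the SEQUENCE, 'X' (unknown residue) matches only
wildcards, never a literal pattern letter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _biopython_mw

__all__ = [
    "MotifMatch",
    "find_motif",
    "catalytic_residues",
    "protein_mw",
    "read_fasta",
    "GH18_MOTIF",
    "SequenceError",
]

GH18_MOTIF = "DXXDXDXE"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Illegal character in a sequence or pattern; names the position."""


@dataclass(frozen=True)
class MotifMatch:
    """A located motif occurrence, 1-based residue coordinates."""

    start: int        # 1-based index of the first motif residue
    matched: str      # the matched substring
    last_asp: int     # 1-based index of the final D of the motif
    glu: int          # 1-based index of the E of the motif


def _validate(seq: str, what: str) -> str:
    # 'X' is legal in both: wildcard in a pattern, unknown residue in a
    # sequence (where it matches only wildcards, never a literal letter)
    seq = seq.upper()
    allowed = AMINO_ACIDS | {"X"}
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise SequenceError(f"illegal character {ch!r} in {what} at position {pos}")
    return seq


def find_motif(sequence: str, pattern: str = GH18_MOTIF) -> list[MotifMatch]:
    """All (possibly overlapping) motif occurrences, ascending by start.

    The default pattern is the GH18 catalytic motif; any pattern over the
    20 one-letter codes plus the 'X' wildcard is accepted, provided it
    contains at least one D before a final-region E so catalytic residues
    are defined.
    """
    sequence = _validate(sequence, "sequence")
    pattern = _validate(pattern, "pattern")
    if not pattern:
        raise SequenceError("empty pattern")
    d_offsets = [i for i, ch in enumerate(pattern) if ch == "D"]
    e_offsets = [i for i, ch in enumerate(pattern) if ch == "E"]
    if not d_offsets or not e_offsets:
        raise SequenceError("pattern must contain literal D and E positions")
    last_d, last_e = d_offsets[-1], e_offsets[-1]

    matches: list[MotifMatch] = []
    m = len(pattern)
    for i in range(len(sequence) - m + 1):
        window = sequence[i:i + m]
        ok = all(pch == "X" or sch == pch for pch, sch in zip(pattern, window))
        if ok:
            matches.append(
                MotifMatch(
                    start=i + 1,
                    matched=window,
                    last_asp=i + 1 + last_d,
                    glu=i + 1 + last_e,
                )
            )
    return matches


def catalytic_residues(match: MotifMatch) -> tuple[int, int]:
    """(last-Asp index, Glu index) of a motif match, 1-based."""
    return match.last_asp, match.glu


def protein_mw(sequence: str) -> float:
    """Average molecular weight of a protein sequence in Da (residue masses
    plus one water). Empty sequences are rejected."""
    sequence = _validate(sequence, "sequence")
    if not sequence:
        raise SequenceError("empty sequence has no molecular weight")
    if "X" in sequence:
        raise SequenceError("unknown residue 'X' has no defined mass")
    return float(_biopython_mw(sequence, seq_type="protein"))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences from a FASTA file, keyed by record id, order preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
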