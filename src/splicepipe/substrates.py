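"""Substrate polypeptides and their validation.

A substrate is a synthetic polypeptide (typically 13-34 residues) that is
digested in vitro by purified 20S/26S proteasomes.  All downstream
coordinates (product positions, splice-reactant positions) refer to the
substrate sequence, 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

#: The 20 canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_VALID_SEQ = re.compile(rf"^[{AMINO_ACIDS}]+$")


class SubstrateError(ValueError):
    """Raised for empty or non-canonical substrate/peptide sequences."""


def validate_sequence(seq: str, what: str = "sequence") -> str:
    """Return ``seq`` if it is a non-empty string over the canonical alphabet."""
    if not isinstance(seq, str) or not seq:
        raise SubstrateError(f"{what} must be a non-empty string")
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set(AMINO_ACIDS))
        raise SubstrateError(
            f"{what} contains non-canonical characters {bad!r}; "
            f"only the 20 canonical amino-acid letters are allowed"
        )
    return seq


@dataclass(frozen=True)
class Substrate:
    """An identified polypeptide substrate.

    Parameters
    ----------
    substrate_id : str
        Short unique token identifying the substrate within a project.
    sequence : str
        Uppercase amino-acid sequence over the 20 canonical letters.
    name : str
        Free-text name.
    origin : str
        Biological source of the sequence (free text).
    """

    substrate_id: str
    sequence: str
    name: str = ""
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.substrate_id:
            raise SubstrateError("substrate_id must be non-empty")
        validate_sequence(self.sequence, f"substrate {self.substrate_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} outside substrate of length {len(self)}")
        return self.sequence[pos - 1]

    def segment(self, start: int, end: int) -> str:
        """Substring at 1-based inclusive coordinates ``start``..``end``."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(f"segment {start}-{end} outside substrate of length {len(self)}")
        return self.sequence[start - 1 : end]


def read_substrates(path: str | Path) -> list[Substrate]:
    """Read substrates from a FASTA file or a plain-text file.

    FASTA headers are split on ``|``: the first token is the substrate id,
    the second (if present) the name, the third the origin.  Plain-text
    files carry one sequence per line; ids are assigned as ``SUB1``,
    ``SUB2``, ...  Duplicated ids raise :class:`SubstrateError`.
    """
    path = Path(path)
    text = path.read_text()
    subs: list[Substrate] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split("|")
            sid = parts[0].strip() or rec.id
            name = parts[1].strip() if len(parts) > 1 else ""
            origin = parts[2].strip() if len(parts) > 2 else ""
            subs.append(Substrate(sid, str(rec.seq).upper(), name=name, origin=origin))
    else:
        n = 0
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n += 1
            subs.append(Substrate(f"SUB{n}", line.upper()))
    seen: set[str] = set()
    for s in subs:
        if s.substrate_id in seen:
            raise SubstrateError(f"duplicate substrate_id {s.substrate_id!r}")
        seen.add(s.substrate_id)
    return subs


def write_substrates_fasta(substrates: list[Substrate], path: str | Path) -> None:
    """Write substrates as FASTA with ``id|name|origin`` headers."""
    with open(path, "w") as fh:
        for s in substrates:
            fh.write(f">{s.substrate_id}|{s.name}|{s.origin}\n{s.sequence}\n")
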