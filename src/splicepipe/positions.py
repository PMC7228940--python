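"""Substrate-coordinate assignments for peptide products.

Every product is located on its substrate either as one contiguous segment
(a non-spliced peptide, PCP) or as two segments, the splice-reactants, whose
concatenation SR1+SR2 gives the product sequence (a spliced peptide, PSP).
Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .substrates import Substrate


@dataclass(frozen=True, order=True)
class PositionAssignment:
    """Coordinates of a product on its substrate.

    For ``kind == "PCP"`` only ``pcp_start``/``pcp_end`` are set; for
    ``kind == "spliced"`` the four splice-reactant coordinates are set and
    the product reads ``substrate[sr1_start:sr1_end] + substrate[sr2_start:sr2_end]``.
    """

    kind: str  # "PCP" | "spliced"
    pcp_start: int | None = None
    pcp_end: int | None = None
    sr1_start: int | None = None
    sr1_end: int | None = None
    sr2_start: int | None = None
    sr2_end: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "PCP":
            if self.pcp_start is None or self.pcp_end is None:
                raise ValueError("PCP assignment requires pcp_start and pcp_end")
            if not 1 <= self.pcp_start <= self.pcp_end:
                raise ValueError(f"invalid PCP coordinates {self.pcp_start}-{self.pcp_end}")
        elif self.kind == "spliced":
            coords = (self.sr1_start, self.sr1_end, self.sr2_start, self.sr2_end)
            if any(c is None for c in coords):
                raise ValueError("spliced assignment requires all four SR coordinates")
            if not (1 <= self.sr1_start <= self.sr1_end) or not (1 <= self.sr2_start <= self.sr2_end):
                raise ValueError(f"invalid splice-reactant coordinates {coords}")
        else:
            raise ValueError(f"unknown assignment kind {self.kind!r}")

    # --- sort key: PCP (start, end); spliced (sr1, sr2) tuple -------------
    @property
    def coords(self) -> tuple[int, ...]:
        if self.kind == "PCP":
            return (self.pcp_start, self.pcp_end)
        return (self.sr1_start, self.sr1_end, self.sr2_start, self.sr2_end)

    @property
    def product_len(self) -> int:
        if self.kind == "PCP":
            return self.pcp_end - self.pcp_start + 1
        return self.sr1_len + self.sr2_len

    @property
    def sr1_len(self) -> int | None:
        if self.kind != "spliced":
            return None
        return self.sr1_end - self.sr1_start + 1

    @property
    def sr2_len(self) -> int | None:
        if self.kind != "spliced":
            return None
        return self.sr2_end - self.sr2_start + 1

    def splice_category(self) -> str:
        """Geometric category of a spliced assignment.

        * ``cis``     — SR1 strictly before SR2 with at least one intervening
          residue (normal order).
        * ``PCP``     — SR1 immediately followed by SR2 (gap 0, forward); the
          product is indistinguishable from a contiguous substring.
        * ``revCis``  — SR2 ends before SR1 starts (reverse order, gap >= 0).
        * ``trans``   — the splice-reactant intervals overlap, which can only
          arise from two substrate molecules.
        """
        if self.kind != "spliced":
            return "PCP"
        if self.sr2_start > self.sr1_end:
            return "cis" if self.sr2_start - self.sr1_end >= 2 else "PCP"
        if self.sr1_start > self.sr2_end:
            return "revCis"
        return "trans"

    def intervening_len(self) -> int | None:
        """Length of the intervening sequence (cis/revCis only, else None)."""
        cat = self.splice_category()
        if cat == "cis":
            return self.sr2_start - self.sr1_end - 1
        if cat == "revCis":
            return self.sr1_start - self.sr2_end - 1
        return None

    def read_sequence(self, substrate: Substrate) -> str:
        """Reconstruct the product sequence from the substrate."""
        if self.kind == "PCP":
            return substrate.segment(self.pcp_start, self.pcp_end)
        return substrate.segment(self.sr1_start, self.sr1_end) + substrate.segment(
            self.sr2_start, self.sr2_end
        )


def format_positions(assignment: PositionAssignment) -> str:
    """Human-readable positions string: ``"start-end"`` for PCP,
    ``"s1-e1_s2-e2"`` for spliced."""
    if assignment.kind == "PCP":
        return f"{assignment.pcp_start}-{assignment.pcp_end}"
    return (
        f"{assignment.sr1_start}-{assignment.sr1_end}"
        f"_{assignment.sr2_start}-{assignment.sr2_end}"
    )


_POS_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")
# spliced separators tolerated in deposited/exported tables
_SPLICED_SEP_RE = re.compile(r"[_;/]| {1,}")


def parse_positions(text: str) -> PositionAssignment:
    """Parse a positions string back into a :class:`PositionAssignment`.

    Tolerates ``_``, ``;``, ``/`` or whitespace between the two
    splice-reactant ranges.
    """
    m = _POS_RE.match(text)
    if m:
        return PositionAssignment("PCP", pcp_start=int(m.group(1)), pcp_end=int(m.group(2)))
    parts = [p for p in _SPLICED_SEP_RE.split(text.strip()) if p]
    if len(parts) == 2:
        m1, m2 = _POS_RE.match(parts[0]), _POS_RE.match(parts[1])
        if m1 and m2:
            return PositionAssignment(
                "spliced",
                sr1_start=int(m1.group(1)),
                sr1_end=int(m1.group(2)),
                sr2_start=int(m2.group(1)),
                sr2_end=int(m2.group(2)),
            )
    raise ValueError(f"unparseable positions string {text!r}")
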