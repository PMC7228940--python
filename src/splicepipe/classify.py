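"""Classification of observed peptides against their substrate.

Given a peptide sequence and the substrate it was searched against, find
every way the peptide can be explained: as a contiguous substring
(non-spliced, PCP) or as a two-fragment ligation SR1+SR2 (spliced, PSP) in
normal cis, reverse cis or trans geometry.  Explanations follow a fixed
parsimony precedence PCP > cis > revCis > trans: a substring is never
reported as spliced, and a peptide explainable without invoking two
substrate molecules is not called trans.

Classification operates on the plain template sequence; post-translational
modifications are carried as annotations elsewhere and never change the
mapping.  I and L are distinct letters, as written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from .positions import PositionAssignment, format_positions
from .substrates import AMINO_ACIDS, Substrate, validate_sequence

DEFAULT_PRECEDENCE = ("cis", "revCis", "trans")


class UnassignableError(ValueError):
    """Peptide cannot be explained as a substring or any two-fragment
    concatenation of the substrate (distinct from an input error)."""


@dataclass(frozen=True)
class Classification:
    """Product/splice type of a peptide with all coordinate explanations.

    ``explanations`` holds every assignment of the winning precedence class;
    ``canonical`` is the coordinate-lexicographically smallest of them and is
    the one used for positions strings and derived features.
    """

    product_type: str  # "PCP" | "PSP"
    splice_type: str  # "cis" | "revCis" | "trans" | "none"
    explanations: tuple[PositionAssignment, ...]
    canonical: PositionAssignment
    is_full_substrate: bool = False

    def __post_init__(self) -> None:
        if (self.product_type == "PCP") != (self.splice_type == "none"):
            raise ValueError("product_type PCP iff splice_type none")
        if not self.explanations or self.canonical not in self.explanations:
            raise ValueError("canonical must be one of the explanations")

    @property
    def is_spliced(self) -> bool:
        return self.product_type == "PSP"

    @property
    def positions(self) -> str:
        return format_positions(self.canonical)


@dataclass(frozen=True)
class DerivedFeatures:
    """Lengths derived from the canonical assignment only."""

    product_len: int
    sr1_len: int | None = None
    sr2_len: int | None = None
    intervening_len: int | None = None


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All 0-based start offsets of ``needle`` in ``haystack`` (overlapping)."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def classify_peptide(
    pep_seq: str,
    substrate: Substrate,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> Classification:
    """Classify ``pep_seq`` against ``substrate``.

    Returns a :class:`Classification` whose ``explanations`` contain every
    assignment of the winning class; raises :class:`UnassignableError` when
    the peptide cannot be derived from the substrate at all.
    """
    validate_sequence(pep_seq, "peptide")
    seq = substrate.sequence

    pcp_hits = _occurrences(pep_seq, seq)
    if pcp_hits:
        expl = tuple(
            PositionAssignment("PCP", pcp_start=i + 1, pcp_end=i + len(pep_seq))
            for i in pcp_hits
        )
        return Classification(
            product_type="PCP",
            splice_type="none",
            explanations=expl,
            canonical=min(expl, key=lambda a: a.coords),
            is_full_substrate=pep_seq == seq,
        )

    by_class: dict[str, list[PositionAssignment]] = {"cis": [], "revCis": [], "trans": []}
    for k in range(1, len(pep_seq)):
        sr1, sr2 = pep_seq[:k], pep_seq[k:]
        starts1 = _occurrences(sr1, seq)
        if not starts1:
            continue
        starts2 = _occurrences(sr2, seq)
        for i in starts1:
            a1, a2 = i + 1, i + len(sr1)
            for j in starts2:
                b1, b2 = j + 1, j + len(sr2)
                asg = PositionAssignment(
                    "spliced", sr1_start=a1, sr1_end=a2, sr2_start=b1, sr2_end=b2
                )
                cat = asg.splice_category()
                if cat in by_class:  # forward-adjacent would be a substring: unreachable here
                    by_class[cat].append(asg)

    for cls in precedence:
        if by_class[cls]:
            expl = tuple(sorted(by_class[cls], key=lambda a: a.coords))
            return Classification(
                product_type="PSP",
                splice_type=cls,
                explanations=expl,
                canonical=expl[0],
            )
    raise UnassignableError(
        f"peptide {pep_seq!r} is not explainable from substrate {substrate.substrate_id!r}"
    )


def positions_string(c: Classification) -> str:
    """Positions column for the canonical assignment (round-trips via
    :func:`splicepipe.positions.parse_positions`)."""
    return format_positions(c.canonical)


def derive_features(c: Classification) -> DerivedFeatures:
    """Product/splice-reactant/intervening lengths from the canonical
    assignment.  Intervening length is defined for cis (>= 1) and reverse
    cis (>= 0) only."""
    a = c.canonical
    return DerivedFeatures(
        product_len=a.product_len,
        sr1_len=a.sr1_len,
        sr2_len=a.sr2_len,
        intervening_len=a.intervening_len(),
    )


# --- monoisotopic masses ---------------------------------------------------

#: Monoisotopic residue masses for the canonical alphabet (Da).
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}

#: Monoisotopic mass of one water molecule (Da), added once per peptide.
WATER_MASS: float = _pmass.calculate_mass(formula="H2O")


def monoisotopic_mass(pep_seq: str) -> float:
    """Monoisotopic mass of the linear peptide in Da.

    Sum of standard residue masses plus one water; computed on the final
    linear sequence regardless of how many ligations produced it.
    """
    validate_sequence(pep_seq, "peptide")
    return sum(RESIDUE_MASS[c] for c in pep_seq) + WATER_MASS
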