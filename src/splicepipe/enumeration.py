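"""Enumeration of the theoretical product space of a substrate.

The search space used for spectrum matching contains every contiguous
substring of the substrate (non-spliced candidates) plus every ordered
concatenation of two substrings (spliced candidates).  An L-residue
substrate has L(L+1)/2 position-distinct substrings and therefore
[L(L+1)/2]^2 ordered splice-reactant pairs; a 34-mer yields 354,025 pairs,
so everything here is a generator and memory stays O(1) per candidate.

Ligation of three or more fragments is never considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .positions import PositionAssignment, format_positions
from .substrates import Substrate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnumerationConfig:
    """Bounds on the enumerated product space.

    ``None`` means unlimited.  ``min_sr_len`` bounds each splice-reactant;
    ``max_intervening`` bounds the intervening-sequence length of cis and
    reverse-cis candidates.  ``include_full_substrate`` keeps the undigested
    full-length sequence in the space (wanted for searching, usually not for
    product statistics).
    """

    min_product_len: int = 1
    max_product_len: int | None = None
    min_sr_len: int = 1
    max_intervening: int | None = None
    include_full_substrate: bool = True

    def __post_init__(self) -> None:
        if self.min_product_len < 1 or self.min_sr_len < 1:
            raise ValueError("length minima must be >= 1")
        if self.max_product_len is not None and self.max_product_len < self.min_product_len:
            raise ValueError("max_product_len < min_product_len")
        if self.max_intervening is not None and self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")


@dataclass(frozen=True)
class CandidatePeptide:
    """A candidate product: sequence, coordinates and geometric category.

    ``category`` is one of ``PCP``, ``cis``, ``revCis``, ``trans``.  A
    forward-adjacent splice-reactant pair (gap 0) is categorised ``PCP``
    because its product is indistinguishable from a substring; its
    assignment still records the pair (``assignment.kind == "spliced"``).
    """

    sequence: str
    assignment: PositionAssignment
    category: str

    @property
    def is_pcp_equivalent(self) -> bool:
        return self.category == "PCP" and self.assignment.kind == "spliced"


def _substrings(length: int, min_len: int, max_len: int | None) -> Iterator[tuple[int, int]]:
    """1-based inclusive (start, end) pairs in coordinate-lexicographic order."""
    for start in range(1, length + 1):
        hi = length if max_len is None else min(length, start + max_len - 1)
        for end in range(start + min_len - 1, hi + 1):
            yield start, end


def enumerate_pcp(substrate: Substrate, cfg: EnumerationConfig | None = None) -> Iterator[CandidatePeptide]:
    """Yield every contiguous substring of the substrate within length bounds.

    Unconstrained, the number of position-distinct substrings is L(L+1)/2.
    """
    cfg = cfg or EnumerationConfig()
    L = len(substrate)
    for start, end in _substrings(L, cfg.min_product_len, cfg.max_product_len):
        if not cfg.include_full_substrate and start == 1 and end == L:
            continue
        asg = PositionAssignment("PCP", pcp_start=start, pcp_end=end)
        yield CandidatePeptide(substrate.segment(start, end), asg, "PCP")


def enumerate_spliced(
    substrate: Substrate, cfg: EnumerationConfig | None = None
) -> Iterator[CandidatePeptide]:
    """Yield every ordered pair of substrate substrings as SR1+SR2.

    Each pair is labelled by its geometry: ``cis`` (forward, gap >= 1),
    ``PCP`` (forward-adjacent, gap 0: the product is a substring),
    ``revCis`` (SR2 entirely before SR1, gap >= 0) or ``trans``
    (overlapping intervals, only possible across two substrate molecules).
    Exactly two splice-reactants per product, never three.
    """
    cfg = cfg or EnumerationConfig()
    L = len(substrate)
    seq = substrate.sequence
    srs = list(_substrings(L, cfg.min_sr_len, None))
    for a1, a2 in srs:
        sr1 = seq[a1 - 1 : a2]
        for b1, b2 in srs:
            plen = (a2 - a1 + 1) + (b2 - b1 + 1)
            if plen < cfg.min_product_len:
                continue
            if cfg.max_product_len is not None and plen > cfg.max_product_len:
                continue
            asg = PositionAssignment(
                "spliced", sr1_start=a1, sr1_end=a2, sr2_start=b1, sr2_end=b2
            )
            cat = asg.splice_category()
            if cfg.max_intervening is not None:
                iv = asg.intervening_len()
                if iv is not None and iv > cfg.max_intervening:
                    continue
            yield CandidatePeptide(sr1 + seq[b1 - 1 : b2], asg, cat)


def enumerate_search_space(
    substrate: Substrate, cfg: EnumerationConfig | None = None
) -> Iterator[CandidatePeptide]:
    """Non-spliced followed by spliced candidates (the full search space)."""
    yield from enumerate_pcp(substrate, cfg)
    yield from enumerate_spliced(substrate, cfg)


def write_search_fasta(
    candidates: Iterable[CandidatePeptide],
    path: str | Path,
    substrate_id: str = "",
) -> int:
    """Write sequence-unique candidates of one substrate as a FASTA database.

    The header encodes substrate id, category and the coordinates of one
    witness assignment (the coordinate-lexicographically smallest, with
    plain-substring witnesses preferred over splice explanations).  Entries
    are ordered by witness coordinates, so repeated runs are byte-identical.
    Returns the number of entries written.
    """
    witnesses: dict[str, CandidatePeptide] = {}
    for cand in candidates:
        prev = witnesses.get(cand.sequence)
        if prev is None or _witness_key(cand) < _witness_key(prev):
            witnesses[cand.sequence] = cand
    if not witnesses:
        logger.warning("empty candidate stream: writing empty FASTA to %s", path)
    entries = sorted(witnesses.values(), key=_witness_key)
    with open(path, "w") as fh:
        for cand in entries:
            header = f"{substrate_id}|{cand.category}|{format_positions(cand.assignment)}"
            fh.write(f">{header}\n{cand.sequence}\n")
    return len(entries)


def _witness_key(cand: CandidatePeptide) -> tuple:
    # substring witnesses first, then by coordinates
    return (cand.assignment.kind != "PCP", cand.assignment.coords)
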