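"""Removal of peptide-synthesis artifacts.

Substrates are made by solid-phase synthesis, which leaves trace amounts of
truncated/erroneous peptides.  Each substrate is therefore also measured at
0 h digestion or without proteasome; every peptide identified in those
control runs is a synthesis error, not a proteasome product.  At the
productive time points we then remove any non-spliced product whose sequence
equals an artifact, and any spliced product whose sequence equals an
artifact or is a contiguous substring of one (proteasomal trimming of an
artifact yields its substrings, which would otherwise masquerade as spliced
products).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


@dataclass
class ArtifactSet:
    """Distinct control-run peptide sequences for one substrate."""

    substrate_id: str
    sequences: set[str] = field(default_factory=set)
    provenance: list[str] = field(default_factory=list)


def collect_artifacts(control_products: Iterable, substrate_id: str | None = None) -> ArtifactSet:
    """Collect distinct sequences from filtered control-run products.

    ``control_products`` are objects exposing ``sequence`` and
    ``substrate_id`` (e.g. :class:`~splicepipe.filtering.ClassifiedProduct`).
    Mixing substrates without passing an explicit ``substrate_id`` is an
    error; duplicates across technical replicates collapse to one entry.
    """
    seqs: set[str] = set()
    runs: set[str] = set()
    ids: set[str] = set()
    for p in control_products:
        seqs.add(p.sequence)
        ids.add(getattr(p, "substrate_id", "") or "")
        run = getattr(p, "record", None)
        if run is not None:
            runs.add(run.run_id)
    ids.discard("")
    if substrate_id is None:
        if len(ids) > 1:
            raise ValueError(f"control products mix substrates {sorted(ids)}; pass substrate_id")
        substrate_id = next(iter(ids), "")
    elif ids and ids != {substrate_id}:
        raise ValueError(f"control products belong to {sorted(ids)}, not {substrate_id!r}")
    if not seqs:
        logger.warning("empty control set for substrate %r", substrate_id)
    return ArtifactSet(substrate_id, seqs, sorted(runs))


@dataclass
class Removal:
    """A removed product and why."""

    product: object
    reason: str  # "exactMatch" | "substringOfArtifact" | "artifactSubstring"
    artifact: str


def remove_artifacts(
    products: Sequence,
    artifacts: ArtifactSet,
    subsequence_direction: str = "product_in_artifact",
) -> tuple[list, list[Removal]]:
    """Split products into (retained, removed) against an artifact set.

    Non-spliced products are removed only on exact sequence match.  Spliced
    products are additionally removed when their sequence is a contiguous
    substring of an artifact (default direction); set
    ``subsequence_direction="artifact_in_product"`` to instead remove spliced
    products that *contain* an artifact sequence.
    Idempotent; retained and removed partition the input.
    """
    if subsequence_direction not in ("product_in_artifact", "artifact_in_product"):
        raise ValueError(f"unknown subsequence_direction {subsequence_direction!r}")
    sub_ids = {getattr(p, "substrate_id", "") or "" for p in products}
    sub_ids.discard("")
    if artifacts.substrate_id and sub_ids and sub_ids != {artifacts.substrate_id}:
        raise ValueError(
            f"products belong to {sorted(sub_ids)} but artifacts to {artifacts.substrate_id!r}"
        )
    retained: list = []
    removed: list[Removal] = []
    for p in products:
        seq = p.sequence
        if seq in artifacts.sequences:
            removed.append(Removal(p, "exactMatch", seq))
            continue
        if p.is_spliced:
            hit = _substring_hit(seq, artifacts.sequences, subsequence_direction)
            if hit is not None:
                reason = (
                    "substringOfArtifact"
                    if subsequence_direction == "product_in_artifact"
                    else "artifactSubstring"
                )
                removed.append(Removal(p, reason, hit))
                continue
        retained.append(p)
    if removed:
        logger.info(
            "removed %d of %d products as synthesis artifacts (substrate %r)",
            len(removed), len(products), artifacts.substrate_id,
        )
    return retained, removed


def _substring_hit(seq: str, artifacts: set[str], direction: str) -> str | None:
    for art in sorted(artifacts):
        if direction == "product_in_artifact":
            if seq in art:
                return art
        else:
            if art in seq:
                return art
    return None
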