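"""Scan-level disambiguation of ranked PSMs.

Each MS/MS scan either yields exactly one high-confidence peptide or is
discarded.  The decision tree deliberately favours non-spliced over spliced
assignments, to counteract the huge imbalance between the spliced and
non-spliced portions of the search space:

1. If the top rank contains a non-spliced peptide, it is the candidate.
2. If the top rank is spliced and several *distinct* spliced sequences tie
   at the maximal score, the scan is discarded (the spectrum cannot decide).
3. A single top spliced peptide is compared against lower-ranked PSMs:
   a lower-ranked non-spliced peptide within ``rel_margin`` (relative score
   difference (top - other)/top < margin) takes over the assignment; if no
   lower-ranked non-spliced peptide exists at all, the spliced candidate is
   kept only when it out-scores every lower-ranked peptide by at least the
   margin.
4. Whatever candidate survives must pass both score and q-value thresholds
   (strict inequalities), otherwise the scan is unassigned.

Reason codes partition the outcomes: ``topNonSpliced``, ``splicedTieDiscard``,
``marginToNonSpliced``, ``splicedAccepted``, ``splicedMarginFail``,
``thresholdFail`` (plus ``error`` for scans whose processing raised, which is
recorded in the log instead of aborting the batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from .classify import Classification, UnassignableError, classify_peptide
from .io import PSMRecord, ScanGroup
from .substrates import Substrate

logger = logging.getLogger(__name__)

REASON_CODES = (
    "topNonSpliced",
    "splicedTieDiscard",
    "marginToNonSpliced",
    "splicedAccepted",
    "splicedMarginFail",
    "thresholdFail",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the disambiguation tree.

    ``min_ion_score`` and ``max_q`` are strict bounds (score > 20,
    q < 0.05 by default); ``rel_margin`` is the relative ion-score margin
    (default 10%), computed as (top - other) / top.
    """

    min_ion_score: float = 20.0
    max_q: float = 0.05
    rel_margin: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.rel_margin < 1.0:
            raise ValueError("rel_margin must be in (0, 1)")
        if self.min_ion_score < 0:
            raise ValueError("min_ion_score must be >= 0")


@dataclass
class FilterDecision:
    """Outcome for one scan: assigned to one PSM, or discarded with a reason."""

    scan_key: tuple
    outcome: str  # "assigned" | "discarded"
    reason: str
    assigned: PSMRecord | None = None

    def __post_init__(self) -> None:
        if (self.outcome == "assigned") != (self.assigned is not None):
            raise ValueError("assigned record present iff outcome == 'assigned'")


@dataclass
class ClassifiedProduct:
    """An accepted PSM together with its classification."""

    record: PSMRecord
    classification: Classification

    @property
    def sequence(self) -> str:
        return self.record.pep_seq

    @property
    def is_spliced(self) -> bool:
        return self.classification.is_spliced

    @property
    def substrate_id(self) -> str:
        return self.record.substrate_id


def _classifier_for(substrate: Substrate) -> Callable[[str], Classification]:
    cache: dict[str, Classification] = {}

    def classify(seq: str) -> Classification:
        if seq not in cache:
            cache[seq] = classify_peptide(seq, substrate)
        return cache[seq]

    return classify


def resolve_scan(
    group: ScanGroup,
    substrate: Substrate,
    cfg: FilterConfig | None = None,
    classify: Callable[[str], Classification] | None = None,
) -> FilterDecision:
    """Resolve one scan to a single peptide or discard it.

    ``classify`` may be supplied to reuse a classification cache across
    scans; by default each peptide is classified against ``substrate``.
    """
    cfg = cfg or FilterConfig()
    classify = classify or _classifier_for(substrate)
    recs = group.records
    if not recs:
        raise ValueError("empty scan group")

    def passes(rec: PSMRecord, reason: str) -> FilterDecision:
        if rec.ion_score > cfg.min_ion_score and rec.q_value < cfg.max_q:
            return FilterDecision(group.key, "assigned", reason, rec)
        return FilterDecision(group.key, "discarded", "thresholdFail")

    spliced = {r.pep_seq: classify(r.pep_seq).is_spliced for r in recs}

    min_rank = min(r.rank for r in recs)
    top = [r for r in recs if r.rank == min_rank]
    top_ns = [r for r in top if not spliced[r.pep_seq]]
    if top_ns:
        # non-spliced wins any tie at the top rank (conservative bias)
        return passes(max(top_ns, key=lambda r: r.ion_score), "topNonSpliced")

    top_score = max(r.ion_score for r in top)
    tied_seqs = {r.pep_seq for r in top if r.ion_score == top_score}
    if len(tied_seqs) > 1:
        return FilterDecision(group.key, "discarded", "splicedTieDiscard")
    best = next(r for r in top if r.ion_score == top_score)
    if best.ion_score <= 0:
        return FilterDecision(group.key, "discarded", "thresholdFail")

    # lower-ranked competitors; the same sequence with a different coordinate
    # explanation is still the same peptide and is not a competitor
    lower = [r for r in recs if r.rank > min_rank and r.pep_seq != best.pep_seq]
    lower_ns = [r for r in lower if not spliced[r.pep_seq]]
    if lower_ns:
        close = [
            r for r in lower_ns
            if (best.ion_score - r.ion_score) / best.ion_score < cfg.rel_margin
        ]
        if close:
            return passes(max(close, key=lambda r: r.ion_score), "marginToNonSpliced")
        return passes(best, "splicedAccepted")
    if all(
        (best.ion_score - r.ion_score) / best.ion_score >= cfg.rel_margin for r in lower
    ):
        return passes(best, "splicedAccepted")
    return FilterDecision(group.key, "discarded", "splicedMarginFail")


def filter_dataset(
    groups: Iterable[ScanGroup],
    substrate: Substrate,
    cfg: FilterConfig | None = None,
) -> tuple[list[ClassifiedProduct], list[FilterDecision]]:
    """Resolve every scan; per-scan errors go to the decision log, never
    abort the batch.  Returns (accepted products, all decisions)."""
    cfg = cfg or FilterConfig()
    classify = _classifier_for(substrate)
    accepted: list[ClassifiedProduct] = []
    decisions: list[FilterDecision] = []
    for group in groups:
        try:
            decision = resolve_scan(group, substrate, cfg, classify)
        except (UnassignableError, ValueError) as exc:
            logger.warning("scan %s failed: %s", group.key, exc)
            decisions.append(FilterDecision(group.key, "discarded", "error"))
            continue
        decisions.append(decision)
        if decision.outcome == "assigned":
            accepted.append(
                ClassifiedProduct(decision.assigned, classify(decision.assigned.pep_seq))
            )
    return accepted, decisions


def decisions_frame(decisions: list[FilterDecision]) -> pd.DataFrame:
    """Decision log as a DataFrame (serialisable to CSV)."""
    return pd.DataFrame(
        [
            {
                "sampleID": d.scan_key[0],
                "runID": d.scan_key[1],
                "scanNum": d.scan_key[2],
                "outcome": d.outcome,
                "reason": d.reason,
                "pepSeq": d.assigned.pep_seq if d.assigned else "",
                "ionScore": d.assigned.ion_score if d.assigned else "",
            }
            for d in decisions
        ],
        columns=["sampleID", "runID", "scanNum", "outcome", "reason", "pepSeq", "ionScore"],
    )
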