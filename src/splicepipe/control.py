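"""Random control dataset of theoretically possible products.

The null model for sequence-feature comparisons: enumerate every
theoretically possible non-spliced and spliced product of the substrates
(no bounds on product, splice-reactant or intervening length), keep only
those an LC-MS/MS measurement could have detected (length >= 6 residues,
monoisotopic mass <= 7 kDa), and draw a uniform seeded sample per product
type, with the sample size of each stratum matched to the number of
identified products of that substrate and type.  If identification were a
uniform draw from this pool, observed and control feature distributions
would coincide — departures are the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import RESIDUE_MASS, WATER_MASS
from .enumeration import CandidatePeptide, EnumerationConfig, enumerate_pcp, enumerate_spliced
from .substrates import Substrate

logger = logging.getLogger(__name__)

PRODUCT_TYPES = ("PCP", "cis", "revCis", "trans")


@dataclass(frozen=True)
class ControlConfig:
    """Detectability constraints and sampling behaviour.

    ``min_len`` (default 6 residues) and ``max_mass`` (default 7000 Da,
    monoisotopic) mirror the MS acquisition window; ``stratify`` keeps
    per-substrate strata (sampling pooled across substrates when False).
    """

    min_len: int = 6
    max_mass: float = 7000.0
    seed: int | None = None
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_mass <= min(RESIDUE_MASS.values()) + WATER_MASS:
            raise ValueError("max_mass below any peptide mass")


def _prefix_masses(seq: str) -> np.ndarray:
    """prefix[i] = summed residue mass of seq[:i]; O(1) segment masses."""
    masses = np.fromiter((RESIDUE_MASS[c] for c in seq), dtype=float, count=len(seq))
    return np.concatenate([[0.0], np.cumsum(masses)])


def build_candidate_pool(
    substrates: Iterable[Substrate], cfg: ControlConfig | None = None
) -> dict[str, dict[str, list[CandidatePeptide]]]:
    """Unconstrained enumeration filtered to detectable candidates.

    Returns ``pools[substrate_id][product_type] -> list of candidates``.
    Forward-adjacent splice pairs are not pooled separately: their products
    are substrings and already members of the PCP pool.
    """
    cfg = cfg or ControlConfig()
    ecfg = EnumerationConfig()
    pools: dict[str, dict[str, list[CandidatePeptide]]] = {}
    for sub in substrates:
        prefix = _prefix_masses(sub.sequence)
        per_type: dict[str, list[CandidatePeptide]] = {t: [] for t in PRODUCT_TYPES}

        def mass_of(asg) -> float:
            if asg.kind == "PCP":
                return prefix[asg.pcp_end] - prefix[asg.pcp_start - 1] + WATER_MASS
            return (
                prefix[asg.sr1_end] - prefix[asg.sr1_start - 1]
                + prefix[asg.sr2_end] - prefix[asg.sr2_start - 1]
                + WATER_MASS
            )

        for cand in enumerate_pcp(sub, ecfg):
            if len(cand.sequence) >= cfg.min_len and mass_of(cand.assignment) <= cfg.max_mass:
                per_type["PCP"].append(cand)
        for cand in enumerate_spliced(sub, ecfg):
            if cand.category == "PCP":  # adjacent pair: substring, already pooled
                continue
            if len(cand.sequence) >= cfg.min_len and mass_of(cand.assignment) <= cfg.max_mass:
                per_type[cand.category].append(cand)
        pools[sub.substrate_id] = per_type
    return pools


@dataclass
class ControlSample:
    """Seeded random sample of candidates per product type."""

    members: dict[str, list[CandidatePeptide]]
    seed: int | None
    config: ControlConfig
    strata: dict[tuple[str, str], int] = field(default_factory=dict)

    def of_type(self, product_type: str) -> list[CandidatePeptide]:
        return self.members.get(product_type, [])


def sample_control(
    pools: Mapping[str, Mapping[str, Sequence[CandidatePeptide]]],
    observed_counts: Mapping,
    cfg: ControlConfig | None = None,
) -> ControlSample:
    """Uniform seeded sampling, stratified per substrate and product type.

    ``observed_counts`` maps ``(substrate_id, product_type) -> n`` (or
    ``product_type -> n`` when ``cfg.stratify`` is False, in which case the
    per-substrate pools are concatenated first).  Sampling is without
    replacement; when a stratum requests more than its pool holds, sampling
    falls back to with-replacement with a warning.  An empty pool with a
    nonzero request is an error.
    """
    cfg = cfg or ControlConfig()
    rng = np.random.default_rng(cfg.seed)
    members: dict[str, list[CandidatePeptide]] = {t: [] for t in PRODUCT_TYPES}
    strata: dict[tuple[str, str], int] = {}

    if cfg.stratify:
        items = [((sid, ptype), int(n)) for (sid, ptype), n in sorted(observed_counts.items())]
        get_pool = lambda sid, ptype: list(pools[sid][ptype])
    else:
        items = [(("*", ptype), int(n)) for ptype, n in sorted(observed_counts.items())]
        get_pool = lambda _sid, ptype: [c for sid in sorted(pools) for c in pools[sid][ptype]]

    for (sid, ptype), n in items:
        if n == 0:
            continue
        pool = get_pool(sid, ptype)
        if not pool:
            raise ValueError(f"empty candidate pool for stratum ({sid!r}, {ptype!r})")
        replace = n > len(pool)
        if replace:
            logger.warning(
                "stratum (%s, %s): requested %d > pool %d, sampling with replacement",
                sid, ptype, n, len(pool),
            )
        idx = rng.choice(len(pool), size=n, replace=replace)
        members[ptype].extend(pool[i] for i in idx)
        strata[(sid, ptype)] = n
    return ControlSample(members, cfg.seed, cfg, strata)
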