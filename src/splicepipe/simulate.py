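"""Seeded synthetic fixtures with known ground truth.

Generates everything the pipeline consumes — substrates, digestion
products, ranked PSM tables with competitors, and artifact-contaminated
control runs — so that every stage can be tested end-to-end without any
measured data.  Substrates mimic the real study material: 13-34 residue
synthetic polypeptides with human-proteome-like amino-acid composition.
Digestion draws cleavage sites with probability proportional to per-residue
P1 preference weights, which the position-frequency-matrix analysis should
recover after control normalisation; that parameter-recovery loop is the
headline correctness check of the whole pipeline.

The PSM score model is deliberately simple (true hits and competitors from
two normal distributions, q-values monotone in rank): it exercises every
branch of the disambiguation tree, it does not mimic search-engine physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .enumeration import CandidatePeptide
from .io import PSMRecord, ScanGroup
from .positions import PositionAssignment
from .substrates import AMINO_ACIDS, Substrate

#: Approximate amino-acid frequencies of the human reference proteome.
HUMAN_AA_FREQ: dict[str, float] = {
    "A": 0.0702, "C": 0.0230, "D": 0.0474, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0434, "K": 0.0572, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0535, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}

#: Default P1 cleavage-preference weights: graded, favouring polar uncharged
#: (S, T, N, Q) and small (A, G) residues, disfavouring proline — the
#: qualitative preference pattern of 20S proteasomes.  All values distinct
#: so that rank-based recovery checks are well defined.
DEFAULT_P1_WEIGHTS: dict[str, float] = {
    "S": 3.4, "T": 3.1, "N": 2.9, "Q": 2.6, "A": 2.4, "G": 2.2,
    "L": 1.9, "F": 1.7, "Y": 1.5, "M": 1.4, "V": 1.25, "I": 1.1,
    "W": 1.0, "H": 0.9, "K": 0.8, "R": 0.7, "D": 0.6, "E": 0.5,
    "C": 0.45, "P": 0.3,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Lengths and composition mirror the real substrate panel; the score model
    (true hits ~ Normal(40, 8), competitors ~ Normal(25, 8)) is chosen to
    exercise every filter branch.  ``seed`` governs every random draw.
    """

    n_substrates: int = 10
    min_substrate_len: int = 13
    max_substrate_len: int = 34
    aa_freq: Mapping[str, float] | None = None  # None -> HUMAN_AA_FREQ
    p1_weights: Mapping[str, float] | None = None  # None -> DEFAULT_P1_WEIGHTS
    splicing_fraction: float = 0.5
    products_per_substrate: int = 50
    min_product_len: int = 6
    max_product_mass: float = 7000.0
    true_score_mean: float = 40.0
    true_score_sd: float = 8.0
    competitor_score_mean: float = 25.0
    competitor_score_sd: float = 8.0
    n_competitors: int = 3
    artifact_rate: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.splicing_fraction, self.artifact_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")

    def frequencies(self) -> np.ndarray:
        table = dict(self.aa_freq) if self.aa_freq else HUMAN_AA_FREQ
        vec = np.array([table.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
        if vec.sum() <= 0 or (vec < 0).any():
            raise ValueError("degenerate amino-acid frequency table")
        return vec / vec.sum()

    def weights(self) -> dict[str, float]:
        return dict(self.p1_weights) if self.p1_weights else dict(DEFAULT_P1_WEIGHTS)


@dataclass
class ScanTruth:
    """Ground truth for one generated scan."""

    scan_num: int
    true_seq: str
    true_category: str  # PCP | cis | revCis | trans
    assignment: PositionAssignment
    is_artifact: bool = False
    expected_outcome: str = "assigned"


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces, with ground truth."""

    config: SimulationConfig
    substrates: list[Substrate]
    product_records: dict[str, list[PSMRecord]]  # substrate_id -> 20/24 h run PSMs
    control_records: dict[str, list[PSMRecord]]  # substrate_id -> 0 h control PSMs
    truth: dict[str, list[ScanTruth]]
    artifact_sequences: dict[str, list[str]]


def simulate_substrates(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> list[Substrate]:
    """Draw substrates with lengths in [min, max] and letters from the
    configured frequency table."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    freqs = cfg.frequencies()
    letters = np.array(list(AMINO_ACIDS))
    subs = []
    for i in range(cfg.n_substrates):
        length = int(rng.integers(cfg.min_substrate_len, cfg.max_substrate_len + 1))
        seq = "".join(rng.choice(letters, size=length, p=freqs))
        subs.append(Substrate(f"SYN{i + 1:03d}", seq, name=f"synthetic substrate {i + 1}",
                              origin="synthetic"))
    return subs


def _peptide_mass(seq: str) -> float:
    from .classify import monoisotopic_mass

    return monoisotopic_mass(seq)


def simulate_digestion(
    substrate: Substrate, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CandidatePeptide]:
    """Sample digestion products of one substrate.

    Non-spliced products: the C-terminal cleavage position is drawn with
    probability proportional to the P1 weight of the residue at that
    position; the N-terminus is uniform.  Spliced products: the SR1
    C-terminus (the sP1 position) is drawn the same way, the remaining three
    coordinates uniformly; the geometric category follows from the
    coordinates.  Products respect the detectability bounds (length >=
    ``min_product_len``, mass <= ``max_product_mass``).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    w = cfg.weights()
    L = len(substrate)
    site_w = np.array([w[c] for c in substrate.sequence], dtype=float)
    products: list[CandidatePeptide] = []
    min_len = cfg.min_product_len
    if L < min_len:
        raise ValueError(f"substrate shorter than min_product_len={min_len}")

    pcp_positions = np.arange(min_len, L + 1)  # candidate C-termini (1-based)
    pcp_p = site_w[pcp_positions - 1] / site_w[pcp_positions - 1].sum()
    sp1_positions = np.arange(1, L + 1)
    sp1_p = site_w / site_w.sum()

    while len(products) < cfg.products_per_substrate:
        if rng.random() >= cfg.splicing_fraction:
            j = int(rng.choice(pcp_positions, p=pcp_p))
            i = int(rng.integers(1, j - min_len + 2))
            asg = PositionAssignment("PCP", pcp_start=i, pcp_end=j)
            seq = asg.read_sequence(substrate)
            cat = "PCP"
        else:
            j = int(rng.choice(sp1_positions, p=sp1_p))
            a1 = int(rng.integers(1, j + 1))
            b1 = int(rng.integers(1, L + 1))
            b2 = int(rng.integers(b1, L + 1))
            asg = PositionAssignment(
                "spliced", sr1_start=a1, sr1_end=j, sr2_start=b1, sr2_end=b2
            )
            if asg.product_len < min_len:
                continue
            seq = asg.read_sequence(substrate)
            cat = asg.splice_category()
        if _peptide_mass(seq) > cfg.max_product_mass:
            continue
        products.append(CandidatePeptide(seq, asg, cat))
    return products


def _random_candidate(
    substrate: Substrate, cfg: SimulationConfig, rng: np.random.Generator
) -> CandidatePeptide:
    """Uniform-ish random candidate (substring or splice pair) for competitor PSMs."""
    L = len(substrate)
    if rng.random() < 0.5:
        i = int(rng.integers(1, L - cfg.min_product_len + 2))
        j = int(rng.integers(i + cfg.min_product_len - 1, L + 1))
        asg = PositionAssignment("PCP", pcp_start=i, pcp_end=j)
    else:
        a1 = int(rng.integers(1, L + 1))
        a2 = int(rng.integers(a1, L + 1))
        b1 = int(rng.integers(1, L + 1))
        b2 = int(rng.integers(b1, L + 1))
        asg = PositionAssignment("spliced", sr1_start=a1, sr1_end=a2, sr2_start=b1, sr2_end=b2)
        if asg.product_len < cfg.min_product_len:
            return _random_candidate(substrate, cfg, rng)
    return CandidatePeptide(asg.read_sequence(substrate), asg, asg.splice_category())


def simulate_psm_table(
    products: list[CandidatePeptide],
    substrate: Substrate,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
    run_id: str = "R1",
    scan_start: int = 1,
) -> tuple[list[PSMRecord], list[ScanTruth]]:
    """One ranked scan per product: the true hit at rank 1 plus competitor
    candidates at lower ranks with smaller scores and larger q-values."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sample_id = sample_id or f"S_{substrate.substrate_id}"
    records: list[PSMRecord] = []
    truths: list[ScanTruth] = []
    for offset, prod in enumerate(products):
        scan = scan_start + offset
        true_score = max(1.0, float(rng.normal(cfg.true_score_mean, cfg.true_score_sd)))
        true_q = float(rng.uniform(0.001, 0.02))
        records.append(
            PSMRecord(
                scan_num=scan, rank=1, pep_seq=prod.sequence, ion_score=round(true_score, 2),
                q_value=round(true_q, 5), charge=2, sample_id=sample_id, run_id=run_id,
                substrate_id=substrate.substrate_id,
            )
        )
        rank = 1
        seen = {prod.sequence}
        comp_scores = []
        for _ in range(cfg.n_competitors):
            for _attempt in range(20):
                comp = _random_candidate(substrate, cfg, rng)
                if comp.sequence not in seen:
                    break
            else:
                continue
            seen.add(comp.sequence)
            score = float(rng.normal(cfg.competitor_score_mean, cfg.competitor_score_sd))
            score = min(max(0.5, score), true_score - 0.5)
            comp_scores.append((score, comp))
        comp_scores.sort(key=lambda t: -t[0])
        for k, (score, comp) in enumerate(comp_scores):
            rank += 1
            q = min(0.999, true_q + 0.01 * rank + float(rng.uniform(0, 0.005)))
            records.append(
                PSMRecord(
                    scan_num=scan, rank=rank, pep_seq=comp.sequence,
                    ion_score=round(score, 2), q_value=round(q, 5), charge=2,
                    sample_id=sample_id, run_id=run_id, substrate_id=substrate.substrate_id,
                )
            )
        truths.append(ScanTruth(scan, prod.sequence, prod.category, prod.assignment))
    return records, truths


def simulate_artifacts(
    substrate: Substrate, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CandidatePeptide]:
    """Synthesis-error peptides of one substrate.

    Half are truncations (substrings), half deletion variants (prefix +
    suffix with an internal gap, which classify as cis spliced) — the two
    error modes solid-phase synthesis actually produces.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L = len(substrate)
    n = max(1, round(cfg.artifact_rate * cfg.products_per_substrate))
    arts: list[CandidatePeptide] = []
    seen: set[str] = set()
    attempts = 0
    while len(arts) < n and attempts < 200 * n:
        attempts += 1
        if rng.random() < 0.5 or L < cfg.min_product_len + 3:
            i = int(rng.integers(1, max(2, L - cfg.min_product_len + 2)))
            j = min(L, int(rng.integers(i + cfg.min_product_len - 1, L + 1)))
            asg = PositionAssignment("PCP", pcp_start=i, pcp_end=j)
        else:
            # deletion variant: drop an internal block of >= 1 residues
            a2 = int(rng.integers(3, L - 2))
            b1 = int(rng.integers(a2 + 2, L))
            asg = PositionAssignment("spliced", sr1_start=1, sr1_end=a2, sr2_start=b1, sr2_end=L)
            if asg.product_len < cfg.min_product_len:
                continue
        seq = asg.read_sequence(substrate)
        if seq in seen or seq == substrate.sequence:
            continue
        seen.add(seq)
        arts.append(CandidatePeptide(seq, asg, asg.splice_category()))
    return arts


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full synthetic study: substrates, productive-run PSM tables (with
    artifact re-emissions), and 0 h control runs containing the artifacts."""
    rng = np.random.default_rng(cfg.seed)
    substrates = simulate_substrates(cfg, rng)
    product_records: dict[str, list[PSMRecord]] = {}
    control_records: dict[str, list[PSMRecord]] = {}
    truth: dict[str, list[ScanTruth]] = {}
    artifact_sequences: dict[str, list[str]] = {}
    for sub in substrates:
        sid = sub.substrate_id
        products = simulate_digestion(sub, cfg, rng)
        recs, truths = simulate_psm_table(products, sub, cfg, rng)
        arts = simulate_artifacts(sub, cfg, rng)
        artifact_sequences[sid] = sorted(a.sequence for a in arts)

        # control run: artifacts only, confidently identified
        ctrl: list[PSMRecord] = []
        for k, art in enumerate(arts, start=1):
            ctrl.append(
                PSMRecord(
                    scan_num=k, rank=1, pep_seq=art.sequence,
                    ion_score=round(float(rng.normal(50, 4)), 2),
                    q_value=round(float(rng.uniform(0.001, 0.01)), 5), charge=2,
                    sample_id=f"C_{sid}", run_id="CTRL", substrate_id=sid,
                )
            )
        control_records[sid] = ctrl

        # artifacts re-emitted in the productive run (should be removed later),
        # plus a spliced substring of each spliced artifact
        scan = len(products) + 1
        for art in arts:
            extra, extra_truth = simulate_psm_table(
                [art], sub, cfg, rng, scan_start=scan
            )
            extra_truth[0].is_artifact = True
            extra_truth[0].expected_outcome = "removed"
            recs.extend(extra)
            truths.extend(extra_truth)
            scan += 1
            if art.assignment.kind == "spliced" and art.assignment.sr1_len >= 2:
                a = art.assignment
                shaved = PositionAssignment(
                    "spliced", sr1_start=a.sr1_start + 1, sr1_end=a.sr1_end,
                    sr2_start=a.sr2_start, sr2_end=a.sr2_end,
                )
                sub_seq = shaved.read_sequence(sub)
                # only a genuinely spliced (non-substring) trimming product
                # exercises the spliced-substring removal rule
                if (len(sub_seq) >= cfg.min_product_len and sub_seq in art.sequence
                        and sub_seq not in sub.sequence):
                    cand = CandidatePeptide(sub_seq, shaved, shaved.splice_category())
                    extra, extra_truth = simulate_psm_table([cand], sub, cfg, rng, scan_start=scan)
                    extra_truth[0].is_artifact = True
                    extra_truth[0].expected_outcome = "removed"
                    recs.extend(extra)
                    truths.extend(extra_truth)
                    scan += 1
        product_records[sid] = recs
        truth[sid] = truths
    return SyntheticDataset(cfg, substrates, product_records, control_records, truth, artifact_sequences)


# --- engineered decision-table fixture -------------------------------------

#: Substrate with 20 unique letters: every peptide has a unique explanation.
DECISION_SUBSTRATE = Substrate("DTAB", AMINO_ACIDS, name="decision-table substrate")

_NS1 = "ACDEF"     # substring 1-5, non-spliced
_SP1 = "ACDEGH"    # 1-4 + 6-7, cis spliced
_SP2 = "CDEIK"     # 2-4 + 8-9, cis spliced


def _rec(scan: int, rank: int, seq: str, score: float, q: float) -> PSMRecord:
    return PSMRecord(scan_num=scan, rank=rank, pep_seq=seq, ion_score=score, q_value=q,
                     charge=2, sample_id="DT", run_id="R1", substrate_id="DTAB")


def decision_table() -> tuple[Substrate, list[ScanGroup], list[tuple[str, str, str]]]:
    """Twelve hand-constructed scans covering every reason code and both
    boundary conditions (margin exactly 10%, score exactly 20, q exactly
    0.05).  Returns (substrate, scan groups, expected (outcome, reason,
    assigned sequence or "") per scan)."""
    cases: list[tuple[list[PSMRecord], tuple[str, str, str]]] = [
        ([_rec(1, 1, _NS1, 35.0, 0.01)], ("assigned", "topNonSpliced", _NS1)),
        ([_rec(2, 1, _NS1, 19.0, 0.01)], ("discarded", "thresholdFail", "")),
        ([_rec(3, 1, _NS1, 20.0, 0.01)], ("discarded", "thresholdFail", "")),
        ([_rec(4, 1, _NS1, 25.0, 0.05)], ("discarded", "thresholdFail", "")),
        ([_rec(5, 1, _SP1, 40.0, 0.001), _rec(5, 2, _NS1, 38.0, 0.01)],
         ("assigned", "marginToNonSpliced", _NS1)),
        ([_rec(6, 1, _SP1, 40.0, 0.001), _rec(6, 2, _NS1, 36.0, 0.01)],
         ("assigned", "splicedAccepted", _SP1)),  # exactly 10%: not < 10%
        ([_rec(7, 1, _SP1, 40.0, 0.001), _rec(7, 2, _NS1, 30.0, 0.01)],
         ("assigned", "splicedAccepted", _SP1)),
        ([_rec(8, 1, _SP1, 40.0, 0.001), _rec(8, 1, _SP2, 40.0, 0.001)],
         ("discarded", "splicedTieDiscard", "")),
        ([_rec(9, 1, _SP1, 40.0, 0.001), _rec(9, 1, _SP1, 40.0, 0.001),
          _rec(9, 2, _SP2, 20.0, 0.02)],
         ("assigned", "splicedAccepted", _SP1)),  # same sequence twice = one peptide
        ([_rec(10, 1, _SP1, 30.0, 0.001), _rec(10, 2, _SP2, 28.0, 0.02)],
         ("discarded", "splicedMarginFail", "")),
        ([_rec(11, 1, _SP1, 30.0, 0.001), _rec(11, 2, _SP2, 27.0, 0.02)],
         ("assigned", "splicedAccepted", _SP1)),  # exactly 10%: >= margin passes
        ([_rec(12, 1, _SP1, 22.0, 0.001), _rec(12, 2, _NS1, 21.0, 0.2)],
         ("discarded", "thresholdFail", "")),  # reassigned non-spliced fails q
    ]
    groups = [ScanGroup(("DT", "R1", recs[0].scan_num), list(recs)) for recs, _ in cases]
    expected = [exp for _, exp in cases]
    return DECISION_SUBSTRATE, groups, expected
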