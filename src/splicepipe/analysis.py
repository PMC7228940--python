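"""Sequence-feature analytics for identified products.

Covers the downstream characterisation of a product database against its
random control: per-type length distributions (product, splice-reactant,
intervening sequence), two-sample Kolmogorov-Smirnov comparisons with
Bonferroni correction, position frequency matrices (PFMs) around cleavage
and splice sites with control normalisation, and an additive
retention-time model used to sanity-check spliced identifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enumeration import CandidatePeptide
from .positions import PositionAssignment
from .substrates import AMINO_ACIDS, Substrate

PRODUCT_TYPES = ("PCP", "cis", "revCis", "trans")

#: Site positions, N- to C-terminal: four residues before the (cleavage or
#: splice) site and four after it.
SITE_POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")


@dataclass(frozen=True)
class ProductFeature:
    """Minimal product view for feature analytics: geometric category,
    coordinates, and owning substrate."""

    category: str
    assignment: PositionAssignment
    substrate_id: str = ""


def features_from_products(products: Iterable) -> list[ProductFeature]:
    """Adapt accepted, classified products (``ClassifiedProduct``) using the
    canonical assignment.  Non-spliced products map to category ``PCP``."""
    out = []
    for p in products:
        c = p.classification
        cat = "PCP" if c.product_type == "PCP" else c.splice_type
        out.append(ProductFeature(cat, c.canonical, p.substrate_id))
    return out


def features_from_candidates(
    candidates: Iterable[CandidatePeptide], substrate_id: str = ""
) -> list[ProductFeature]:
    """Adapt enumerated/sampled candidates (e.g. a random control sample)."""
    return [ProductFeature(c.category, c.assignment, substrate_id) for c in candidates]


def length_distributions(features: Iterable[ProductFeature]) -> dict[str, dict[str, np.ndarray]]:
    """Empirical length distributions per product type.

    Returns ``{type: {"product_len": ..., "sr1_len": ..., "sr2_len": ...,
    "intervening_len": ...}}``; splice-reactant lengths only for spliced
    types, intervening lengths only for cis and revCis.
    """
    acc: dict[str, dict[str, list[int]]] = {
        t: {"product_len": [], "sr1_len": [], "sr2_len": [], "intervening_len": []}
        for t in PRODUCT_TYPES
    }
    for f in features:
        d = acc[f.category]
        d["product_len"].append(f.assignment.product_len)
        if f.assignment.kind == "spliced":
            d["sr1_len"].append(f.assignment.sr1_len)
            d["sr2_len"].append(f.assignment.sr2_len)
            iv = f.assignment.intervening_len()
            if iv is not None:
                d["intervening_len"].append(iv)
    return {
        t: {k: np.asarray(v, dtype=int) for k, v in d.items()} for t, d in acc.items()
    }


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    adjusted_pvalue: float


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float], family_size: int = 1) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test with Bonferroni adjustment
    (adjusted p = min(1, p * family_size)).

    Uses the asymptotic null distribution (the convention of R's ``ks.test``
    at the sample sizes typical here); the exact small-sample distribution is
    conservative at these n because of the discreteness of D.
    """
    a, b = np.asarray(sample_a, dtype=float), np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires two non-empty samples")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    with np.errstate(divide="ignore"):  # D == 0 divides inside the asymptotic tail
        res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), min(1.0, float(res.pvalue) * family_size))


# --- position frequency matrices ------------------------------------------


@dataclass
class PFM:
    """20 x 8 amino-acid-by-position frequency matrix.

    ``counts[aa, pos]`` are raw tallies; ``position_counts[pos]`` the number
    of contexts contributing to that position (site at a terminus omits the
    out-of-bounds positions rather than padding).  ``freqs`` normalises each
    populated column to sum to 1.
    """

    counts: pd.DataFrame  # index AMINO_ACIDS, columns SITE_POSITIONS

    @property
    def position_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def freqs(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        out = self.counts.astype(float).copy()
        for pos in out.columns:
            if totals[pos] > 0:
                out[pos] = out[pos] / totals[pos]
        return out


def _site_context(f: ProductFeature, substrate: Substrate, site: str) -> list[tuple[str, str]]:
    """(position label, residue) pairs for one product; absent positions omitted.

    ``site="nonSpliced"`` profiles the C-terminal cleavage site of a
    non-spliced product: P4..P1 are its last residues (bounded by the
    product's N-terminus), P1'..P4' the substrate residues after it.
    ``site="spliceSite"`` profiles the junction of a spliced product:
    P4..P1 the last residues of SR1, P1'..P4' the first residues of SR2.
    """
    a = f.assignment
    ctx: list[tuple[str, str]] = []
    if site == "nonSpliced":
        if a.kind != "PCP":
            return []
        for k in range(4):  # P1 is the site residue itself
            pos = a.pcp_end - k
            if pos >= a.pcp_start:
                ctx.append((SITE_POSITIONS[3 - k], substrate.residue(pos)))
        for k in range(1, 5):
            pos = a.pcp_end + k
            if pos <= len(substrate):
                ctx.append((SITE_POSITIONS[3 + k], substrate.residue(pos)))
    elif site == "spliceSite":
        if a.kind != "spliced":
            return []
        for k in range(4):
            pos = a.sr1_end - k
            if pos >= a.sr1_start:
                ctx.append((SITE_POSITIONS[3 - k], substrate.residue(pos)))
        for k in range(4):
            pos = a.sr2_start + k
            if pos <= a.sr2_end:
                ctx.append((SITE_POSITIONS[4 + k], substrate.residue(pos)))
    else:
        raise ValueError(f"unknown site kind {site!r}")
    return ctx


def build_pfm(
    features: Iterable[ProductFeature],
    substrates: Mapping[str, Substrate] | Substrate,
    site: str = "spliceSite",
) -> PFM:
    """Tally residues around cleavage/splice sites into a PFM.

    ``substrates`` maps substrate_id to :class:`Substrate` (or is a single
    substrate used for every feature).
    """
    counts = pd.DataFrame(
        0, index=list(AMINO_ACIDS), columns=list(SITE_POSITIONS), dtype=int
    )
    single = substrates if isinstance(substrates, Substrate) else None
    for f in features:
        sub = single if single is not None else substrates[f.substrate_id]
        for pos_label, residue in _site_context(f, sub, site):
            counts.loc[residue, pos_label] += 1
    return PFM(counts)


def normalize_pfm(observed: PFM, control: PFM) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Element-wise observed/control frequency ratio.

    Cells where both frequencies are zero are set to 1 (no evidence either
    way); cells with zero control but nonzero observed frequency are set to
    +inf and returned in the flag list.
    """
    fo, fc = observed.freqs, control.freqs
    if fo.shape != fc.shape or list(fo.columns) != list(fc.columns):
        raise ValueError("PFM shapes/columns do not match")
    ratio = pd.DataFrame(1.0, index=fo.index, columns=fo.columns)
    flags: list[tuple[str, str]] = []
    for pos in fo.columns:
        for aa in fo.index:
            o, c = fo.at[aa, pos], fc.at[aa, pos]
            if c > 0:
                ratio.at[aa, pos] = o / c
            elif o > 0:
                ratio.at[aa, pos] = np.inf
                flags.append((aa, pos))
            # both zero: stays 1.0
    return ratio, flags


# --- retention-time model --------------------------------------------------


@dataclass
class RTModel:
    """Additive retention-time model: RT = intercept + sum_a coeff_a * count_a
    (+ optional length term)."""

    intercept: float
    coefficients: dict[str, float]
    length_coefficient: float | None
    r_squared: float
    residual_sd: float
    n_train: int


def _design(peptides: Sequence[str], include_length: bool) -> np.ndarray:
    X = np.zeros((len(peptides), 1 + len(AMINO_ACIDS) + (1 if include_length else 0)))
    X[:, 0] = 1.0
    for i, pep in enumerate(peptides):
        for j, aa in enumerate(AMINO_ACIDS):
            X[i, 1 + j] = pep.count(aa)
        if include_length:
            X[i, -1] = len(pep)
    return X


def fit_rt_model(
    peptides: Sequence[str],
    retention_times: Sequence[float],
    include_length: bool = False,
    min_train: int = 25,
) -> RTModel:
    """Least-squares fit of the additive composition model.

    Requires at least ``min_train`` peptides and a full-rank design (every
    amino acid represented, compositions not collinear); otherwise raises
    with advice to supply more training data.  Note the length term is
    collinear with the composition counts and is off by default.
    """
    y = np.asarray(retention_times, dtype=float)
    if len(peptides) != y.size:
        raise ValueError("peptides and retention_times differ in length")
    if len(peptides) < min_train:
        raise ValueError(f"need >= {min_train} training peptides, got {len(peptides)}")
    X = _design(peptides, include_length)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: training peptides do not span composition "
            "space (an amino acid may be absent); provide more training data"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return RTModel(
        intercept=float(beta[0]),
        coefficients={aa: float(beta[1 + j]) for j, aa in enumerate(AMINO_ACIDS)},
        length_coefficient=float(beta[-1]) if include_length else None,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        residual_sd=float(np.sqrt(ss_res / max(1, y.size - X.shape[1]))),
        n_train=y.size,
    )


def predict_rt(model: RTModel, peptides: Sequence[str]) -> np.ndarray:
    """Predicted retention times under the fitted additive model."""
    include_length = model.length_coefficient is not None
    X = _design(peptides, include_length)
    beta = np.concatenate(
        [
            [model.intercept],
            [model.coefficients[aa] for aa in AMINO_ACIDS],
            [model.length_coefficient] if include_length else [],
        ]
    )
    return X @ beta


def residual_summary(
    model: RTModel, peptides: Sequence[str], measured: Sequence[float]
) -> dict[str, float]:
    """Mean/SD of measured-minus-predicted residuals for one product type."""
    resid = np.asarray(measured, dtype=float) - predict_rt(model, peptides)
    return {
        "n": int(resid.size),
        "mean": float(resid.mean()) if resid.size else float("nan"),
        "sd": float(resid.std(ddof=1)) if resid.size > 1 else float("nan"),
    }
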