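"""Feature analytics: length distributions, KS, PFMs, RT model."""

import numpy as np
import pytest

from splicepipe import analysis
from splicepipe.analysis import (PFM, ProductFeature, build_pfm,
                                 features_from_candidates, fit_rt_model,
                                 ks_compare, length_distributions,
                                 normalize_pfm, predict_rt, residual_summary)
from splicepipe.positions import PositionAssignment
from splicepipe.substrates import AMINO_ACIDS, Substrate


def cis_feature(s1, e1, s2, e2, sid="T"):
    return ProductFeature(
        "cis",
        PositionAssignment("spliced", sr1_start=s1, sr1_end=e1, sr2_start=s2, sr2_end=e2),
        sid,
    )


def pcp_feature(s, e, sid="T"):
    return ProductFeature("PCP", PositionAssignment("PCP", pcp_start=s, pcp_end=e), sid)


class TestLengthDistributions:
    def test_single_cis_product(self):
        d = length_distributions([cis_feature(1, 2, 4, 5)])
        assert d["cis"]["sr1_len"].tolist() == [2]
        assert d["cis"]["sr2_len"].tolist() == [2]
        assert d["cis"]["intervening_len"].tolist() == [1]
        assert d["cis"]["product_len"].tolist() == [4]

    def test_pcp_only_input(self):
        d = length_distributions([pcp_feature(1, 5)])
        assert d["PCP"]["product_len"].tolist() == [5]
        for t in ("cis", "revCis", "trans"):
            assert d[t]["product_len"].size == 0

    def test_trans_no_intervening(self):
        f = ProductFeature(
            "trans",
            PositionAssignment("spliced", sr1_start=2, sr1_end=4, sr2_start=3, sr2_end=5),
            "T",
        )
        d = length_distributions([f])
        assert d["trans"]["intervening_len"].size == 0
        assert d["trans"]["sr1_len"].tolist() == [3]


class TestKS:
    def test_self_comparison(self):
        x = np.arange(50, dtype=float)
        res = ks_compare(x, x)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_shifted_distributions_detected(self, rng):
        a = rng.normal(10, 2, size=1000)
        b = rng.normal(11, 2, size=1000)  # shift of one unit
        res = ks_compare(a, b, family_size=30)
        assert res.adjusted_pvalue < 0.05

    def test_bonferroni(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        res = ks_compare(a, b, family_size=10)
        assert res.adjusted_pvalue == pytest.approx(min(1.0, res.pvalue * 10))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0, 2.0])


class TestPFM:
    def test_homopolymer_all_A(self):
        sub = Substrate("H", "AAAAAAAAAAAAA")
        feats = [pcp_feature(2, 6, "H"), pcp_feature(1, 9, "H")]
        pfm = build_pfm(feats, {"H": sub}, site="nonSpliced")
        f = pfm.freqs
        for pos in f.columns:
            if pfm.position_counts[pos] > 0:
                assert f.at["A", pos] == pytest.approx(1.0)

    def test_columns_sum_to_one(self):
        sub = Substrate("T", "ACDEFGHIKLMN")
        feats = [pcp_feature(1, 5, "T"), pcp_feature(3, 8, "T"), pcp_feature(2, 12, "T")]
        pfm = build_pfm(feats, {"T": sub}, site="nonSpliced")
        sums = pfm.freqs.sum(axis=0)
        for pos in pfm.freqs.columns:
            if pfm.position_counts[pos] > 0:
                assert sums[pos] == pytest.approx(1.0, abs=1e-9)

    def test_hand_tallied_toy_set(self):
        """Three products on ACDEFGHIK, tallied by hand."""
        sub = Substrate("T", "ACDEFGHIK")
        feats = [
            pcp_feature(1, 4, "T"),   # P4..P1 = A C D E ; P1'..P4' = F G H I
            pcp_feature(3, 6, "T"),   # P4..P1 = D E F G ; P1'..P3' = H I K, P4' absent
            cis_feature(1, 2, 5, 6, "T"),  # splice site, not counted here
        ]
        pfm = build_pfm(feats, {"T": sub}, site="nonSpliced")
        c = pfm.counts
        assert c.at["E", "P1"] == 1 and c.at["G", "P1"] == 1
        assert c.at["A", "P4"] == 1 and c.at["D", "P4"] == 1
        assert c.at["F", "P1'"] == 1 and c.at["H", "P1'"] == 1
        assert c.at["I", "P4'"] == 1 and pfm.position_counts["P4'"] == 1
        assert pfm.position_counts["P1"] == 2

    def test_splice_site_contexts_bounded_by_reactants(self):
        sub = Substrate("T", "ACDEFGHIK")
        # SR1 = positions 2-3 (len 2): only P2, P1 populated; SR2 = 5-6: P1', P2'
        feats = [cis_feature(2, 3, 5, 6, "T")]
        pfm = build_pfm(feats, {"T": sub}, site="spliceSite")
        assert pfm.position_counts["P4"] == 0 and pfm.position_counts["P3"] == 0
        assert pfm.counts.at["D", "P1"] == 1  # residue at position 3
        assert pfm.counts.at["C", "P2"] == 1
        assert pfm.counts.at["F", "P1'"] == 1
        assert pfm.position_counts["P3'"] == 0

    def test_terminal_cleavage_omits_out_of_bounds(self):
        sub = Substrate("T", "ACDEF")
        feats = [pcp_feature(1, 5, "T")]  # C-terminus at substrate end
        pfm = build_pfm(feats, {"T": sub}, site="nonSpliced")
        assert pfm.position_counts["P1'"] == 0

    def test_normalize_identity(self):
        sub = Substrate("T", "ACDEFGHIK")
        feats = [pcp_feature(1, 4, "T"), pcp_feature(2, 7, "T")]
        pfm = build_pfm(feats, {"T": sub}, site="nonSpliced")
        ratio, flags = normalize_pfm(pfm, pfm)
        assert flags == []
        assert np.allclose(ratio.values, 1.0)

    def test_normalize_ratio_and_flags(self):
        sub = Substrate("T", "ACDEFGHIK")
        obs = build_pfm([pcp_feature(1, 4, "T"), pcp_feature(1, 4, "T")], {"T": sub}, "nonSpliced")
        ctrl = build_pfm([pcp_feature(1, 4, "T"), pcp_feature(3, 6, "T")], {"T": sub}, "nonSpliced")
        ratio, flags = normalize_pfm(obs, ctrl)
        # obs freq of E at P1 = 1.0, ctrl = 0.5 -> ratio 2
        assert ratio.at["E", "P1"] == pytest.approx(2.0)
        # obs has G never at P1 but ctrl does: ratio 0, no flag
        assert ratio.at["G", "P1"] == 0.0
        assert all(np.isinf(ratio.at[aa, pos]) for aa, pos in flags)


class TestRTModel:
    @staticmethod
    def _random_peptides(rng, n, lo=6, hi=20):
        return ["".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(lo, hi)))
                for _ in range(n)]

    def test_zero_noise_exact_recovery(self, rng):
        coef = {aa: float(rng.uniform(-2, 2)) for aa in AMINO_ACIDS}
        peps = self._random_peptides(rng, 120)
        rts = [3.0 + sum(coef[c] for c in p) for p in peps]
        m = fit_rt_model(peps, rts)
        assert m.intercept == pytest.approx(3.0, abs=1e-6)
        for aa in AMINO_ACIDS:
            assert m.coefficients[aa] == pytest.approx(coef[aa], abs=1e-6)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-6)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_rmse(self, rng):
        coef = {aa: float(rng.uniform(-2, 2)) for aa in AMINO_ACIDS}
        peps = self._random_peptides(rng, 500)
        rts = [3.0 + sum(coef[c] for c in p) + rng.normal(0, 1.0) for p in peps]
        m = fit_rt_model(peps, rts)
        rmse = np.sqrt(np.mean([(m.coefficients[aa] - coef[aa]) ** 2 for aa in AMINO_ACIDS]))
        assert rmse < 0.2

    def test_spliced_residuals_match_nonspliced(self, rng):
        """Peptides generated from the same RT model give comparable residual
        spread whether used for training or held out — the validation logic
        applied to spliced identifications."""
        coef = {aa: float(rng.uniform(-2, 2)) for aa in AMINO_ACIDS}
        train = self._random_peptides(rng, 400)
        held = self._random_peptides(rng, 400)
        noise = 0.5
        rt = lambda p: 3.0 + sum(coef[c] for c in p) + rng.normal(0, noise)
        m = fit_rt_model(train, [rt(p) for p in train])
        s_train = residual_summary(m, train, [rt(p) for p in train])
        s_held = residual_summary(m, held, [rt(p) for p in held])
        assert s_held["sd"] == pytest.approx(s_train["sd"], rel=0.25)

    def test_too_few_peptides(self, rng):
        peps = self._random_peptides(rng, 10)
        with pytest.raises(ValueError, match="training peptides"):
            fit_rt_model(peps, np.zeros(10))

    def test_rank_deficient_design(self):
        peps = ["AAAA"] * 30  # single composition: columns collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_rt_model(peps, np.zeros(30))

    def test_predict_matches_manual(self, rng):
        coef = {aa: float(rng.uniform(-1, 1)) for aa in AMINO_ACIDS}
        peps = self._random_peptides(rng, 60)
        m = fit_rt_model(peps, [1.0 + sum(coef[c] for c in p) for p in peps])
        pred = predict_rt(m, ["ACDEFG"])
        manual = m.intercept + sum(m.coefficients[c] for c in "ACDEFG")
        assert pred[0] == pytest.approx(manual)
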