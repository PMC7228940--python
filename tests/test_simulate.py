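"""Synthetic-fixture generator: determinism, composition, ground truth."""

import numpy as np
import pytest

from splicepipe.classify import classify_peptide
from splicepipe.simulate import (HUMAN_AA_FREQ, SimulationConfig,
                                 simulate_artifacts, simulate_dataset,
                                 simulate_digestion, simulate_psm_table,
                                 simulate_substrates)
from splicepipe.substrates import AMINO_ACIDS


class TestSubstrates:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_substrates=5, seed=9)
        a = simulate_substrates(cfg)
        b = simulate_substrates(cfg)
        assert [s.sequence for s in a] == [s.sequence for s in b]

    def test_lengths_in_range(self):
        subs = simulate_substrates(SimulationConfig(n_substrates=50, seed=1))
        assert all(13 <= len(s) <= 34 for s in subs)

    def test_letter_frequencies_near_table(self):
        subs = simulate_substrates(SimulationConfig(n_substrates=1000, seed=2))
        pooled = "".join(s.sequence for s in subs)
        for aa in AMINO_ACIDS:
            emp = pooled.count(aa) / len(pooled)
            assert abs(emp - HUMAN_AA_FREQ[aa]) < 0.02

    def test_degenerate_frequency_table_errors(self):
        cfg = SimulationConfig(aa_freq={aa: 0.0 for aa in AMINO_ACIDS}, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            cfg.frequencies()


class TestDigestion:
    def test_splicing_fraction_zero(self, rng):
        cfg = SimulationConfig(splicing_fraction=0.0, seed=4)
        sub = simulate_substrates(cfg, rng)[0]
        products = simulate_digestion(sub, cfg, rng)
        assert all(p.category == "PCP" for p in products)

    def test_products_respect_bounds(self, rng):
        cfg = SimulationConfig(seed=5, products_per_substrate=100)
        sub = simulate_substrates(cfg, rng)[0]
        for p in simulate_digestion(sub, cfg, rng):
            assert len(p.sequence) >= cfg.min_product_len
            assert p.assignment.read_sequence(sub) == p.sequence

    def test_recorded_class_matches_classifier_when_unique(self, rng):
        """For products with a unique decomposition, the recorded category
        equals what the classifier infers from the sequence alone."""
        cfg = SimulationConfig(seed=6, products_per_substrate=60)
        sub = simulate_substrates(cfg, rng)[0]
        checked = 0
        for p in simulate_digestion(sub, cfg, rng):
            c = classify_peptide(p.sequence, sub)
            got = "PCP" if c.product_type == "PCP" else c.splice_type
            if len(c.explanations) == 1 and c.canonical == p.assignment:
                assert got == p.category
                checked += 1
        assert checked > 0

    def test_uniform_weights_p1_matches_composition(self):
        """With uniform P1 weights the nsP1 residue distribution of generated
        non-spliced products tracks substrate composition at eligible sites."""
        from splicepipe import analysis

        cfg = SimulationConfig(
            seed=7, n_substrates=1, splicing_fraction=0.0,
            products_per_substrate=4000,
            p1_weights={aa: 1.0 for aa in AMINO_ACIDS},
        )
        rng = np.random.default_rng(7)
        sub = simulate_substrates(cfg, rng)[0]
        products = simulate_digestion(sub, cfg, rng)
        feats = analysis.features_from_candidates(products, sub.substrate_id)
        pfm = analysis.build_pfm(feats, sub, site="nonSpliced")
        # eligible C-termini are positions min_len..L, uniform over them
        eligible = sub.sequence[cfg.min_product_len - 1 :]
        expected = {aa: eligible.count(aa) / len(eligible) for aa in AMINO_ACIDS}
        f = pfm.freqs["P1"]
        for aa in AMINO_ACIDS:
            assert abs(f[aa] - expected[aa]) < 0.05


class TestPsmTables:
    def test_true_hit_is_rank_one(self, rng):
        cfg = SimulationConfig(seed=8)
        sub = simulate_substrates(cfg, rng)[0]
        products = simulate_digestion(sub, cfg, rng)
        recs, truths = simulate_psm_table(products, sub, cfg, rng)
        by_scan = {}
        for r in recs:
            by_scan.setdefault(r.scan_num, []).append(r)
        for t in truths:
            top = min(by_scan[t.scan_num], key=lambda r: r.rank)
            assert top.pep_seq == t.true_seq
            assert all(r.ion_score <= top.ion_score for r in by_scan[t.scan_num])

    def test_q_monotone_in_rank(self, rng):
        cfg = SimulationConfig(seed=9)
        sub = simulate_substrates(cfg, rng)[0]
        products = simulate_digestion(sub, cfg, rng)
        recs, _ = simulate_psm_table(products, sub, cfg, rng)
        by_scan = {}
        for r in recs:
            by_scan.setdefault(r.scan_num, []).append(r)
        for scan_recs in by_scan.values():
            scan_recs.sort(key=lambda r: r.rank)
            qs = [r.q_value for r in scan_recs]
            assert qs == sorted(qs)

    def test_dataset_deterministic_csvs(self, tmp_path):
        from splicepipe.io import write_psm_csv

        for sub_dir in ("a", "b"):
            ds = simulate_dataset(SimulationConfig(n_substrates=3, seed=10))
            d = tmp_path / sub_dir
            d.mkdir()
            recs = [r for sid in sorted(ds.product_records) for r in ds.product_records[sid]]
            write_psm_csv(recs, d / "psms.csv")
        assert (tmp_path / "a/psms.csv").read_bytes() == (tmp_path / "b/psms.csv").read_bytes()

    def test_artifacts_unique_and_from_substrate(self, rng):
        cfg = SimulationConfig(seed=11, artifact_rate=0.2)
        sub = simulate_substrates(cfg, rng)[0]
        arts = simulate_artifacts(sub, cfg, rng)
        seqs = [a.sequence for a in arts]
        assert len(seqs) == len(set(seqs))
        for a in arts:
            assert a.assignment.read_sequence(sub) == a.sequence

    def test_every_scan_has_truth(self):
        ds = simulate_dataset(SimulationConfig(n_substrates=2, seed=12))
        for sid, recs in ds.product_records.items():
            scans = {r.scan_num for r in recs}
            truth_scans = {t.scan_num for t in ds.truth[sid]}
            assert scans == truth_scans
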