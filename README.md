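# splicepipe

Identification pipeline for peptides generated by proteasomes in vitro —
both **non-spliced** products of ordinary hydrolysis (PCP) and **spliced**
products (PSP), in which the proteasome ligates two fragments
(splice-reactants) of its substrate into a sequence that never existed in
the parent protein. Spliced peptides contribute to HLA-I immunopeptidomes
and are candidate targets in immunotherapy; characterising the sequence
preferences of hydrolysis and splicing requires a validated product
database, which is what this package builds from digestion search results.

It is aimed at proteomics groups who digest synthetic polypeptide
substrates (typically 13–34 residues) with purified 20S/26S proteasomes,
search the spectra against a custom database of all theoretical products,
and need the downstream computation:

- **Search-space enumeration** — every substring of a substrate and every
  ordered substring pair SR1+SR2, labelled *cis* (forward, intervening gap
  ≥ 1), *reverse cis* (SR2 before SR1), or *trans* (overlapping intervals,
  only explicable by two substrate molecules); exported as a FASTA search
  database. An L-mer yields L(L+1)/2 substrings and (L(L+1)/2)² pairs.
- **Classification** — mapping an observed peptide back onto its substrate
  with all coordinate explanations, under the parsimony precedence
  PCP > cis > revCis > trans.
- **Scan disambiguation** — resolving each MS/MS scan's ranked
  peptide-spectrum matches (PSMs) to at most one high-confidence peptide:
  ion score > 20, q-value < 0.05, a 10% relative score margin protecting
  against spurious spliced assignments, and a deliberate bias toward
  non-spliced explanations.
- **Artifact removal** — peptides identified in 0 h / no-proteasome control
  runs are synthesis errors; they and (for spliced products) their
  substrings are removed from productive time points.
- **Random control** — a seeded, per-substrate/per-type matched sample of
  all theoretically possible products under detectability constraints
  (length ≥ 6, monoisotopic mass ≤ 7 kDa), the null model for all feature
  comparisons.
- **Analytics** — length distributions, Kolmogorov-Smirnov comparisons with
  Bonferroni correction, position frequency matrices around cleavage/splice
  sites (positions P4…P1, P1'…P4') normalised by the random control, and an
  additive retention-time model for validating spliced identifications.
- **Synthetic fixtures** — a seeded generator of substrates, digestions
  with injected cleavage-site preferences, ranked PSM tables and
  artifact-bearing controls, with full ground truth.

The final database uses a fixed 23-column schema (sample and run metadata,
substrate, peptide, scores, classification, positions, charge, PTM) written
as CSV and as a SQL dump. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Classify peptides against the substrate `RTKAWNRQLYPEW` and enumerate its
search space:

```bash
$ printf 'RTKAWNRQLYPEW\n' > substrate.txt
$ splicepipe enumerate --substrate substrate.txt --out space.fasta
SUB1: 7478 unique sequences -> space.fasta

$ printf 'TKAWN\nRTKQLY\nAWNRT\nLYPEWRTK\n' > peps.txt
$ splicepipe classify --substrate substrate.txt --peptides peps.txt --out classified.csv
$ cat classified.csv
pepSeq,productType,spliceType,positions,nExplanations,productLen,sr1Len,sr2Len,interveningLen
TKAWN,PCP,,2-6,1,5,,,
RTKQLY,PSP,cis,1-3_8-10,1,6,3,3,4
AWNRT,PSP,revCis,4-6_1-2,2,5,3,2,1
LYPEWRTK,PSP,revCis,9-13_1-3,1,8,5,3,5
```

`TKAWN` is a substring (positions 2–6): non-spliced. `RTKQLY` needs two
fragments in forward order with four intervening residues: normal cis.
`AWNRT` and `LYPEWRTK` place the second fragment before the first: reverse
cis (with two coordinate explanations found for `AWNRT`; the canonical,
coordinate-smallest one is reported).

A full synthetic run — simulate a study, then execute the pipeline:

```bash
$ splicepipe simulate --seed 42 --out-dir sim
simulated 10 substrates, 2180 product PSMs, 30 control PSMs -> sim
$ cat > cfg.yaml <<EOF
substrates: sim/substrates.fasta
psm_files: [sim/psms.csv]
control_files: [sim/controls.csv]
out_dir: out
seed: 42
EOF
$ splicepipe run --config cfg.yaml
database rows: 496 -> out
```

`out/` then contains `database.csv` (23-column schema), `database.sql`,
`decisions.csv` (per-scan outcome and reason code), `removed.csv`
(artifact removals), `ks_tests.csv`, and the PFM matrices. The run log
records per-substrate stage counts, e.g. for the first substrate:

```json
{"scans": 54, "assigned": 53,
 "discarded_by_reason": {"topNonSpliced": 35, "splicedAccepted": 15,
                         "marginToNonSpliced": 3, "thresholdFail": 1},
 "artifacts": 3, "removed_as_artifact": 2, "retained": 51}
```

54 scans resolved to 53 peptides (one failed the score threshold); 2 of the
assigned peptides matched 0 h control identifications and were removed as
synthesis artifacts, leaving 51 database entries for this substrate.

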