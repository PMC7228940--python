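# Methods

## Problem and scope

Proteasomes release peptides from a substrate in two ways: ordinary
hydrolysis, which yields contiguous fragments (non-spliced peptides, PCP),
and peptide splicing, which ligates two fragments — the splice-reactants —
into a new sequence (spliced peptides, PSP). Splicing can keep the original
N→C order with an intervening gap (normal cis), invert the order (reverse
cis), or combine overlapping fragments, which is only possible if the two
reactants come from two substrate molecules (trans). `splicepipe`
implements the computational side of building a validated product database
from in-vitro digestions of synthetic polypeptide substrates: enumerating
the theoretical product space used as the search database, classifying
observed peptides, disambiguating ranked peptide-spectrum matches (PSMs),
removing peptide-synthesis artifacts, sampling a matched random control,
and computing sequence-feature analytics. It does not run a search engine,
handle spectra, or model the wet-lab chemistry.

## Coordinates and classification

All coordinates are 1-based inclusive positions on the substrate. A
non-spliced product is `start-end`; a spliced product is
`s1-e1_s2-e2` (SR1 then SR2, concatenated to give the sequence). An
L-residue substrate has L(L+1)/2 position-distinct substrings and
(L(L+1)/2)^2 ordered splice-reactant pairs; enumeration is a generator so
memory stays constant per candidate (a 34-mer has 354,025 pairs). A
forward-adjacent pair (gap 0) is treated as PCP-equivalent: its product is
indistinguishable from a substring. A reverse-adjacent pair remains reverse
cis because its product is not a substring.

Classification of an observed sequence searches every substring occurrence
and every two-fragment decomposition, then applies the parsimony precedence
PCP > cis > revCis > trans: a sequence is only called trans when no
single-molecule explanation exists. The relative order of cis over revCis is
a convention (both are single-molecule); it is configurable via the
`precedence` argument of `classify_peptide`. All explanations of the winning
class are retained; the canonical one is the coordinate-lexicographically
smallest tuple, which makes positions strings stable and reproducible.
Derived lengths (product, SR1, SR2, intervening) come from the canonical
assignment only — averaging over alternative explanations would make
features depend on the enumeration of ties. Post-translational modification
annotations are parsed off sequences and carried as `(position, name)`
pairs; they never influence mapping. I and L are distinct letters.
Monoisotopic masses are standard residue masses (pyteomics table) plus one
water on the final linear sequence, regardless of how many ligations formed
it.

## Scan disambiguation

Each MS/MS scan carries all ranked PSMs suggested by the search engine.
The decision tree resolves a scan to at most one peptide and deliberately
favours non-spliced assignments, because spliced candidates outnumber
non-spliced ones in the search space by orders of magnitude:

1. If the top rank contains a non-spliced peptide it is the candidate
   (ties at the top rank therefore go to the non-spliced peptide).
2. A top rank with several *distinct* spliced sequences at the maximal
   score is discarded; the same sequence under different coordinates is one
   peptide.
3. A single top spliced candidate is compared with lower ranks using the
   relative score difference `(top − other)/top` against a 10% margin
   (default). A lower-ranked non-spliced peptide closer than the margin
   takes over the assignment. If no lower-ranked non-spliced peptide exists
   at all, the spliced candidate must beat every lower-ranked peptide by at
   least the margin, otherwise the scan is discarded.
4. The surviving candidate must pass both thresholds — ion score strictly
   above 20 and q-value strictly below 0.05 (defaults) — or the scan is
   unassigned. When the margin rule reassigns to a non-spliced peptide that
   then fails the thresholds, the scan is discarded rather than falling
   back to the spliced candidate, preserving the conservative bias.

The margin base (the top score) is a documented choice; the margin itself,
both thresholds and their strictness are configurable in `FilterConfig`.
One deliberate reading: the spliced-vs-spliced margin in step 3 applies
*only* when no lower-ranked non-spliced peptide exists; a non-spliced
competitor further than the margin leaves the spliced peptide assigned. The
alternative (requiring the margin against all lower-ranked peptides always)
is stricter; we follow the sequenced formulation. Reason codes
(`topNonSpliced`, `splicedTieDiscard`, `marginToNonSpliced`,
`splicedAccepted`, `splicedMarginFail`, `thresholdFail`) partition all
outcomes and are written to the decision log.

## Artifact removal

Solid-phase synthesis leaves erroneous peptides in the substrate stock, so
each substrate is also measured at 0 h or without proteasome; everything
identified there is a synthesis error. At productive time points a
non-spliced product is removed only on exact sequence match with an
artifact. A spliced product is removed on exact match or when its sequence
is a contiguous substring of an artifact: proteasomal trimming of an
artifact yields substrings, and a substring that needs a splicing
explanation would otherwise enter the database as a spurious PSP. The
subsequence rule's direction is genuinely ambiguous in prose; the reverse
direction (artifact contained in product) is available via
`subsequence_direction="artifact_in_product"`. Removal is idempotent and
retained/removed partition the input.

## Random control

The null model enumerates all theoretically possible products without any
length restrictions, then keeps candidates detectable by the acquisition
set-up: at least 6 residues and at most 7000 Da monoisotopic. Sampling is
uniform, seeded, without replacement (falling back to with-replacement with
a warning when a stratum requests more than its pool holds), stratified per
substrate and product type with stratum sizes equal to the observed product
counts — so substrate composition and availability effects are matched
between observed and control sets, and any residual difference in feature
distributions reflects enzyme specificity. Pooled (non-stratified) sampling
is available by flag. PFM normalisation is computed against the stratified
control, consistent with its construction; normalising against a pooled
control is the documented alternative.

## Feature analytics

Length distributions are reported per product type for product,
splice-reactant and intervening lengths (intervening is defined only for
cis, ≥ 1, and reverse cis, ≥ 0). Distribution comparisons use the
two-sample Kolmogorov-Smirnov test with Bonferroni adjustment
(`min(1, p × family)`). The p-value uses the asymptotic null distribution:
at the sample sizes involved the exact small-sample distribution is
conservative (measured null rejection ≈ 3.5% at α = 0.05 versus 4.5–6.2%
for the asymptotic form at n = 200), and the asymptotic form is what R's
`ks.test` applies at these sizes.

Position frequency matrices profile eight positions: P4…P1 before and
P1'…P4' after the site. For non-spliced products the site is the C-terminal
cleavage: P4…P1 are the product's last residues (bounded by its
N-terminus), P1'…P4' the substrate residues following it (bounded by the
substrate C-terminus). For spliced products the site is the splice
junction: P4…P1 the last residues of SR1 and P1'…P4' the first residues of
SR2, each bounded by its reactant. Out-of-bounds positions are omitted
rather than padded, and per-position denominators are tracked, so each
populated column is a true frequency summing to 1. The observed/control
ratio sets 0/0 cells to 1 and flags nonzero/0 cells (+inf). N-terminal
cleavage profiling of non-spliced products is out of scope.

The retention-time model is additive in composition:
`RT = intercept + Σ_a coeff_a · count_a`, fitted by least squares on
non-spliced identifications (≥ 25 peptides, full-rank design required — an
amino acid absent from training raises an error advising more data). A
length term is available but off by default because length equals the sum
of the counts and makes the design collinear. The model predicts RTs of
spliced identifications; residual spread comparable to the non-spliced
training residuals supports their correctness.

## Synthetic data

The generator emulates the study conditions: substrates of 13–34 residues
drawn from human-proteome-like amino-acid frequencies; digestion products
whose cleavage-site (P1/sP1) positions are drawn proportionally to a
20-value preference-weight table; ranked PSM tables with the true hit at
rank 1 plus competitor candidates from the same substrate (scores from two
normal distributions — true ~ N(40, 8), competitors ~ N(25, 8) by default,
chosen to exercise every filter branch — and q-values monotone in rank);
and 0 h control runs containing synthesis artifacts (truncations and
deletion variants, the latter classifying as cis spliced), which are
re-emitted at the productive time point together with spliced trimming
products of spliced artifacts. The default preference weights are a graded
vector favouring S, T, N, Q, A, G and disfavouring P — the qualitative
pattern reported for 20S proteasomes — with all values distinct so
rank-based recovery is well defined.

What the generator does not emulate: spectra and fragment ions, score
physics of any real search engine, ionisation or detectability beyond the
length/mass rule, modification chemistry, inter-substrate digestion
kinetics. Passing tests therefore demonstrate the correctness of the
pipeline's logic and its ability to recover injected sequence preferences,
not search-engine-specific behaviour on measured spectra.

The headline end-to-end check runs 25 substrates × 200 products (5,000
scans, a size chosen to keep the whole suite fast while leaving per-residue
PFM cells well populated) with well-separated score distributions
(true ~ N(45, 4) vs competitors ~ N(18, 4)), and requires Spearman ρ > 0.9
between the control-normalised P1 column and the injected weights, plus
≥ 99% ground-truth filter accuracy.

## Numerical and degenerate-input choices

- Strict threshold inequalities (score > 20, q < 0.05) as documented.
- Relative margin uses the top score as denominator; a non-positive top
  score discards the scan.
- Deterministic ordering everywhere: scan groups by (sample, run, scan),
  records by (rank, −score, sequence), database rows by
  (sampleID, scanNum, rankMS, pepSeq), FASTA entries by witness coordinates
  with substring witnesses preferred. Identical inputs and seed give
  byte-identical outputs.
- Empty candidate streams, empty control runs and empty inputs produce
  empty outputs with warnings, not errors; an empty pool with a nonzero
  sampling request is an error.
- `spliceType` sentinels (`NA`, `none`, `-`, …) read from external CSVs are
  normalised to the empty string for non-spliced rows; positions strings
  accept `_`, `;`, `/` or whitespace separators.

## Known limitations

- Trans products are detected as overlapping decompositions; true
  inter-molecule ligations of non-overlapping fragments are
  indistinguishable from cis and are classified cis by parsimony.
- Classification cost grows with peptide/substrate length as occurrence ×
  split enumeration; fine for ≤ 34-mer substrates, not tuned for proteins.
- The RT model is compositional only; positional effects (e.g. terminal
  residues) are not modelled.
- Three-fragment splicing, decoy generation and spectrum handling are out
  of scope by design.
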