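# Methods

## Scope and data flow

The pipeline consumes (a) a protein-level annotated somatic mutation table
(TSV; MAF-style variant-class spellings are normalized through an explicit
dialect map, unknown spellings are errors), (b) wild-type protein sequences
(FASTA, optionally with CDS for frameshift translation), (c) per-sample MHC
class I allele calls, and (d) peptide–allele affinity predictions, either
from the built-in synthetic predictor or parsed from an external
predictor's tabular output. Read alignment, variant calling, dbSNP lookup,
and HLA typing are upstream of this package: their results arrive as
precomputed columns (RNA read counts, dbSNP/somatic flags, allele lists).

## Filtering funnel

Variants are retained in four fixed stages, in order: somatic evidence;
absence from dbSNP; expression (mutant-allele RNA reads ≥ `min_alt_reads`,
default 1 — the wild-type read count is never gated, since a silenced
wild-type allele with zero reference reads is a legitimate observation);
and variant class (default: missense, in-frame indel, frameshift; nonsense
variants are excluded because premature stops are not expected to yield
class I epitopes, but the class set is configurable). The audit records the
count after every stage so alternative orders can be compared. Filtering is
idempotent and order-preserving.

## Mutant contexts and epitope windows

Protein coordinates are 1-based. A missense variant substitutes one
residue (checked against the wild-type sequence; mismatches are hard
errors). An in-frame indel replaces `ref_aa` by `alt_aa`; its novel set is
the inserted residues plus one flanking residue on each side of the
junction, a convention chosen so that junction-spanning windows are always
enumerated. A frameshift keeps the wild-type prefix up to `position − 1`
and appends the novel tail, taken from `alt_aa` when precomputed or
translated from the CDS in the shifted frame (stopping before the first
stop codon; an open-ended flag marks frames that never terminate). A
frameshift whose shifted frame opens on a stop codon yields no novel
peptide and is excluded downstream. Translating a frameshift from the CDS
requires an explicit indel description (`del:<n>` / `ins:<seq>`); the
package never guesses the register.

Candidate class I epitopes are all 8–11mer windows of the mutant sequence
that overlap at least one novel position, enumerated without duplicates
and sorted by (length, start). An interior missense therefore yields
8+9+10+11 = 38 windows. Window lengths outside 8–11 require an explicit
override flag. Every emitted window differs from the same-coordinate
wild-type substring (guaranteed for missense, asserted in tests for
indels and frameshifts).

## Vaccine-peptide design

The long-peptide design returns
`mut[max(1, p_min − flank) … min(L, p_max + flank)]` with `flank = 14`,
where `p_min`/`p_max` bound the novel positions: a 29mer with the mutation
central for an interior missense. Near a terminus the window is clipped,
never padded (a mutation at residue 4 yields an 18mer). For frameshifts
the peptide is the upstream flank plus the entire novel tail (clipped at
the new C terminus); tails longer than 50 residues are truncated with a
warning, and no right flank is added past the truncation point because the
removed sequence is itself novel. No minimum output length is enforced.

## Affinity interface and thresholds

Affinities are carried exclusively as IC50 in nM; percentile ranks are not
modeled. Binder classification is a strict `<` at the threshold, so
boundary values are non-binders. Three conventional thresholds are
exposed: 100 nM (high-affinity calls, the cohort default), 500 nM (an
alternate moderate cutoff), and 1500 nM (the relaxed vaccine-panel
default). Per mutation, the reported affinity is the minimum over all
(window, allele) pairs; exact ties resolve to the lexicographically
smallest (length, start) window, then the earliest listed allele. Missing
(peptide, allele) predictions are coverage errors, never silently skipped.

The synthetic predictor maps each (peptide, allele, seed) triple through a
stable 64-bit hash to a log-uniform IC50 in [1, 50 000) nM; peptides
containing a planted anchor motif map into [1, 100) nM instead. Hashing
rather than sequential sampling makes the predictor order-independent:
the same pair always receives the same affinity, regardless of batch
composition. External predictor versions are treated as dialect metadata
of the parser (headed TSV, or columnar text with configurable column
indices), not separate code paths.

## Burden model

With a = 0.08 (the literature-derived fraction of predicted high-affinity
binders that prove authentic; exposed as a sensitivity parameter) and N
predicted neoantigens, the expected number of authentic neoantigens is
E = a·N and the probability of at least one is P = 1 − (1 − a)^N. N is the
loci-scaled count `n_raw × total_loci / typed_loci` — scaling precedes the
power, and the real-valued power accepts the resulting non-integer N. The
smallest integer N with P ≥ 0.90 at a = 0.08 is 28; the fraction of a
cohort above the cutoff computed from P agrees exactly with counting
samples at N ≥ 28.

Two counting conventions are first-class, because single-tumor vaccine
design and cohort burden analysis count different things: `per_mutation`
(mutations carrying ≥ 1 sub-threshold window; panel default, threshold
1500 nM, no loci scaling since the mouse alleles are fully typed) and
`per_peptide` (distinct sub-threshold window sequences; cohort default,
threshold 100 nM, ×3 scaling for one typed human locus).
`per_peptide ≥ per_mutation` always.

Cohort medians use the midpoint convention for even cohorts, and the
median is taken over the *scaled* N (whether the original analyses took
their medians before or after scaling is not stated; this package fixes
the convention and documents it here). Reported percentages round
half-up, reproducing 39% and 89% from P = 0.3936 and 0.8948. Samples with
ambiguous allele calls are dropped from cohort analysis with a logged
count. Rank tables order samples by total mutation count descending, ties
broken by sample id.

## Synthetic cohorts

The generator emulates the statistical structure of the study inputs, not
their biology:

* per-sample somatic non-synonymous burden from a negative binomial
  (ovarian-like preset: mean 43, dispersion 8, median ≈ 40 missense) or a
  rounded log-normal (lung-like preset: median 200, σ = 0.5) — the
  negative binomial is the standard overdispersed model for tumor
  mutation burden; the log-normal supplies the heavier tail seen in lung
  cohorts;
* variant classes drawn as 93% missense, 5% nonsense, 1% frameshift, 1%
  in-frame indel;
* each mutation transcribed with probability 42/92 ≈ 0.457 (the expressed
  fraction observed in the murine mutanome); RNA read counts are
  geometric-like, spanning 0 to ~2000 in order of magnitude only;
* each transcribed, epitope-eligible mutation harbors one planted
  sub-threshold window with a calibrated probability (ovarian-like
  0.1218, lung-like 0.1043). Planting is by exact (peptide, allele)
  identity; planted windows draw affinities from [3, 95] nM and all other
  windows from [120, 50 000] nM, so the planted windows are exactly the
  binders;
* one HLA-A allele per sample (allele-level detail is collapsed: the ×3
  extrapolation depends only on typed_loci = 1 of 3, and counting takes a
  minimum over alleles, so a second allele would add cost without
  changing the statistics); ~20% of samples are marked allele-ambiguous
  and dropped by the cohort workflow, as in the human analysis.

Preset parameters were frozen once by `scripts/calibrate_presets.py`,
which solves the analytic compound distribution (burden → Bernoulli
transcription → Bernoulli binder) for the binder probability whose median
raw count is 2 (ovarian-like; ×3 → median N = 6) or 9 (lung-like; ×3 →
27), and additionally requires the empirical cohort median at 200 samples
to be stable to within its binomial sampling error — the requirement that
fixed the lung-like σ at 0.5. The analytic forms (exact thinned negative
binomial; numeric log-normal–binomial mixture) are also exposed for
parameter-recovery tests.

The recorded truth is recounted from the generated affinity table at
generation time, so truth and emitted files cannot drift apart. All
outputs are byte-identical for identical seeds and configs.

A separate constructed fixture mirrors a single-tumor funnel exactly: 92
somatic mutations, 42 with RNA support, 39 non-nonsense, and 17 carrying
one planted window in the intermediate-affinity band [103, 1460] nM (none
below 100 nM, so the high-affinity panel is empty). Because the real
funnel depends on unavailable sequencing data, the fixture asserts the
pipeline's filtering and threshold logic — that it recovers the planted
composition — not that it rediscovers any particular tumor's biology.

What the generator does **not** emulate: real MHC binding motifs or
allele-specific affinity landscapes; linkage between expression and
binding; immune editing or clonality; HLA allele frequencies; germline
variants; multiple binder peptides per mutation (each planted mutation
contributes exactly one, so per-peptide and per-mutation counts coincide
in simulation even though they differ on real predictor output).
Passing recovery tests therefore demonstrates that the counting, scaling,
and probability machinery is correct under a known generative model — not
that the pipeline's predictions are accurate for real tumors.

## Numerical choices and problem sizes

Strict inequalities at all affinity thresholds; half-up integer rounding
for percentages only at the reporting layer (full precision propagates
internally); midpoint median; the likelihood-threshold search starts from
the closed form `⌈log(1−cutoff)/log(1−a)⌉` and verifies with the exact
power to guard against floating-point edge cases; P saturates at 1.0 in
double precision around N ≈ 700 at a = 0.08, where strict monotonicity
necessarily ends. Degenerate inputs fail loudly: empty cohorts, ambiguous
nucleotides, reference mismatches, zero typed loci, and coverage gaps all
raise typed errors.

Simulation-based checks run at 200 samples per preset and a 2000-protein
proteome (~1.4 M affinity calls for the lung-like preset), sizes chosen so
the statistical assertions (median within sampling error, fraction above
cutoff within 3 standard errors of the analytic value) are meaningful
while the whole suite stays fast. The window-enumeration oracle compares
implementation against brute force on 1000 random (protein, mutation)
pairs including frameshifts.

## Known limitations

* Overlapping mutations in one gene are applied one at a time; compound
  haplotypes are not constructed.
* Wild-type-coordinate mapping of windows is meaningful only for missense
  variants (identity mapping).
* No proteome-wide uniqueness screen of mutant peptides, no MHC class II
  (> 11mer) enumeration, and no reimplementation of any neural-network
  predictor: external affinity predictions are consumed by file exchange
  only.
* The authenticity model treats predicted binders as independent
  Bernoulli trials; correlations between peptides of the same mutation
  are ignored (both counting conventions are provided precisely because
  the trial unit is ambiguous).
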