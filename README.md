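# neoburden

Tumor mutanome analysis for neoantigen-targeted immunotherapy: from an
annotated somatic mutation table to per-sample predicted-neoantigen counts,
synthetic-long-peptide vaccine designs, and the probability that a tumor
harbors at least one *authentic* — naturally processed, MHC-presented, and
T-cell-recognized — neoantigen.

The package is aimed at cancer immunologists and computational biologists
studying whether neoantigen vaccines are viable in tumor types with
intermediate or low mutation burdens (e.g. high-grade serous ovarian
carcinoma, HGSC, with a median of roughly 40 missense mutations per tumor)
versus high-burden types (lung carcinomas).

## The model

A tumor's somatic variants pass through a fixed filtering funnel:

    somatic  →  not in dbSNP  →  ≥1 RNA read supporting the mutant allele
             →  epitope-eligible class (missense / in-frame indel / frameshift)

For each retained variant the mutant protein is materialized and every
8–11mer window overlapping a novel residue is scored against the sample's
MHC class I alleles (an external predictor's output is parsed from file; a
seeded synthetic predictor stands in for tests and simulations). A peptide
is called a binder when its predicted IC50 is *strictly* below the
threshold: 100 nM for high-affinity calls, 1500 nM as the relaxed cutoff
used to admit intermediate-affinity candidates to a vaccine panel.

When only one of the organism's class I loci is typed (e.g. HLA-A of
HLA-A/B/C), the raw count n is extrapolated to

    N = n · total_loci / typed_loci        (×3 for HLA-A only)

Empirical studies of viral epitopes found that only a fraction a ≈ 0.08 of
predicted high-affinity binders are authentic epitopes. Treating the N
predicted neoantigens as independent trials,

    E = a · N                  expected authentic neoantigens
    P = 1 − (1 − a)^N          probability of at least one

Vaccine peptides are designed as 29mers with the mutant residue central
(14 wild-type flanking residues per side), clipped — not padded — at
protein termini; a frameshift contributes its full novel C-terminal tail
plus the upstream flank.

## Worked example

```python
from neoburden import (
    expected_authentic, prob_at_least_one, percent_likelihood,
    min_neoantigens_for_likelihood,
)
from neoburden.simulate import make_id8_fixture
from neoburden.workflows import run_panel

for label, N in (("HGSC", 6), ("lung", 27)):
    E = expected_authentic(N, 0.08)
    P = prob_at_least_one(N, 0.08)
    print(f"{label}: N = {N}  E = {E:.2f}  P = {P:.4f}  ({percent_likelihood(P)}%)")
print("smallest N with P >= 0.90:", min_neoantigens_for_likelihood(0.08, 0.90))

fixture = make_id8_fixture(seed=0)
result = run_panel(fixture.mutations, fixture.proteome, fixture.calls,
                   fixture.allele_set)
print("funnel (input -> transcribed -> class-kept -> binders):", result.funnel)
```

prints

```
HGSC: N = 6  E = 0.48  P = 0.3936  (39%)
lung: N = 27  E = 2.16  P = 0.8947  (89%)
smallest N with P >= 0.90: 28
funnel (input -> transcribed -> class-kept -> binders): (92, 42, 39, 17)
```

Reading: with the median HGSC burden of 6 predicted (loci-scaled)
neoantigens, the expected number of authentic ones is below one half and
the tumor has only a 39% chance of containing any — versus 89% at the lung
median of 27. A sample needs at least 28 predicted neoantigens before an
authentic one is more than 90% likely. The last line runs the full panel
workflow on a constructed single-sample mutanome in which 92 somatic
mutations funnel down to 42 transcribed, 39 epitope-eligible, and 17
carrying a predicted binder under the relaxed 1500 nM cutoff.

## Command line

```bash
neoburden simulate --preset hgsc_like --n-samples 200 --seed 1 --out-dir data/
neoburden cohort --mutations data/mutations.tsv --proteome data/proteome.fasta \
    --predictions data/predictions.tsv --alleles data/alleles.tsv --out-dir out/
neoburden simulate --id8-fixture --seed 1 --out-dir panel_data/
neoburden panel --mutations panel_data/mutations.tsv ... --out-dir panel_out/
```

`cohort` writes a per-sample burden table (n_total, n_transcribed,
n_predicted_raw, N, E, P), a rank-ordered table for burden-vs-rank plots,
and a JSON summary (median N, fraction of samples with P ≥ 0.90). `panel`
writes the funnel audit, per-mutation best affinities, and the Table-style
vaccine panel with designed long peptides.

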