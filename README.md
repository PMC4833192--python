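# idpanel

Proband-only gene-panel diagnostics for severe developmental disorders:
rare-variant filtering, inheritance-aware pathogenicity triage, and
carrier-level burden testing (CAST) against a comparison cohort.

## The problem

In cohorts of probands with moderate-to-severe intellectual disability,
trio sequencing (child plus both parents) is the method of choice for
finding de novo causal variants — but parental DNA is often unavailable.
This package implements the proband-only alternative: sequence a panel of
known and candidate disease genes, keep rare coding variants
(MAF < 1% in every reference set), and then

1. **triage** loss-of-function (LoF) variants in *known* disease genes —
   nonsense, frameshift, and essential splice-site changes — as likely
   pathogenic when they fit the gene's inheritance mode (monoallelic,
   biallelic, or X-linked), are absent from control sets (tolerated for
   recessive genes), and sit on the canonical transcript;
2. **triage** missense variants only if previously reported as disease
   causing, through an ordered exclusion checklist (candidate gene,
   control presence, single recessive allele, literature exclusion, a
   better LoF explanation in the same proband, pedigree/phenotype mode
   mismatch);
3. **test carrier burden** with the cohort allelic sums test (CAST):
   collapse each variant category to a per-sample carrier indicator and
   compare carrier counts between the case and comparison cohorts with a
   one-tailed Fisher exact test on the 2×2 table, stratified by
   chromosome class, gene category and variant type, with Bonferroni
   correction over the LoF strata and synonymous variants as negative
   controls.

For carrier counts $a/n_1$ (cases) vs $b/n_2$ (comparison), the CAST
p-value is the hypergeometric tail
$P = \sum_{x \ge a} \binom{n_1}{x}\binom{n_2}{K-x} / \binom{N}{K}$
with $K = a+b$, $N = n_1+n_2$.

Because per-sample cohort data of this kind cannot be redistributed, the
package ships a fully ground-truthed synthetic cohort generator
(`idpanel.simulate`) that reproduces the analysis' statistical structure —
cohort sizes and sex ratios, a 565-gene panel (253 known / 312 candidate),
0.46 LoF and 8 missense-class rare variants per proband, configurable
planted diagnostic fractions — plus deterministic fixtures
(`idpanel.fixtures`) that reproduce the published contingency tables
bit-exactly.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each accepts `--seed`):

```
$ python analysis/01_simulate_cohort.py --seed 1
simulated 25254 variant observations (986 cases, 899 comparison probands)
planted diagnoses: 79 LoF, 30 missense, 3 dual -> union 106 (10.8% of cases)

$ python analysis/03_triage_variants.py
diagnostic yield: 128/986 (13.0%) — 101 via LoF, 27 via reported missense, 0 both
ground-truth recovery: 106/106 planted-diagnosis cases recovered (100.0%)

$ python analysis/04_cast_enrichment.py
any-LoF carriers: 341/986 vs 222/899  P = 1.7e-06
stratified table: 4/10 LoF strata significant after Bonferroni (threshold 0.005)
damaging missense: 284/900 vs 245/899  P = 0.025
```

Reading the output: triage recovers every planted diagnosis (the 3
dual-pathway probands are counted once, via their LoF variant, because the
checklist prefers the LoF explanation); the ~2% of extra diagnoses above
the planted 10.8% are background LoF variants that are genuinely
indistinguishable from causal ones without parental data.  The enrichment
numbers come from the packaged fixtures carrying the published carrier
structure: 34.6% of cases vs 24.7% of comparison probands carry a rare LoF
in a panel gene, and exactly four LoF strata (known-monoallelic SNVs,
autosomal candidate SNVs, and X-linked known SNVs and indels) survive the
corrected threshold, while no synonymous control row is ever flagged.

A `idpanel` console command exposes the same stages
(`simulate`/`filter`/`triage`/`enrich`/`report`), each taking
`--config config.yaml --seed N --out DIR`.

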