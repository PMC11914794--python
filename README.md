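# neoprio

Neoepitope candidate prioritization and screening for tumor
immunology: a long overlapping-peptide selection strategy driven by
somatic-variant expression evidence, a class-I minimal-epitope
selection strategy driven by binding-metric thresholds, the
ELISpot/Fluorospot analysis that scores both experimentally, and the
exact statistics used to compare them — all runnable end to end on
synthetic cohorts with known ground truth.

## Who this is for

Groups designing personalised neoantigen screens from tumor/normal
exome + tumor RNA sequencing, who need a reproducible, testable
implementation of candidate selection and screen analysis rather than a
collection of one-off scripts. Nothing here calls external predictors
or aligners: binding predictions are consumed as tables (or mocked
deterministically), and variant calling/HLA typing happen upstream.

## The two selection strategies

**Expression-ranked long peptides (IPV).** Somatic missense variants
are kept when they satisfy six conjunctive filters on read evidence:
tumor DNA VAF ≥ 2%; a missense protein annotation; tumor VAF ≥ normal
VAF; ≥ 1 supporting RNA read; normal VAF ≤ 5% and tumor VAF ≥ 5%;
≥ 10× DNA coverage in both tumor and normal. Survivors are ranked
lexicographically by RNA VAF ↓, TPM ↓, tumor genotype priority ↑
(hom-alt best). Each top variant yields two overlapping 20-mers with
the mutant residue at peptide positions 6 and 15, covering every
possible class I and most class II epitopes without requiring the
patient's HLA type.

**Threshold-filtered short peptides (TESLA-style).** The same variants
are expanded into every mutation-spanning 8–12-mer and filtered on
five strict thresholds: best predicted IC50 < 68 nM across the
patient's alleles, predicted complex stability > 1.7 h, source-gene
abundance > 10 TPM, agretopicity (mutant/wild-type IC50 on the same
allele) < 0.1, and foreignness > 10⁻¹⁶. Foreignness is the TCR
recognition-probability score
`R = S/(1+S)`, `S = Σₑ exp(−k·(a − s(p,e)))`, where `s` is the best
gapless BLOSUM62 local-alignment score of the candidate against a
reference set of known immunogenic epitopes (defaults `a = 26`,
`k = 4.87`). Passing candidates are ranked by ascending IC50.

**Screen analysis.** Raw spot counts are averaged over replicates,
converted to SFC / 10⁶ PBMC, background-subtracted against pooled
media+DMSO wells, and called positive when net SFC strictly exceeds
100. Pool-level calls are compared with a two-sided Fisher's exact
test (probability-mass convention); percentile-rank metrics (per-donor
midrank percentiles of TPM, DNA VAF, RNA VAF and their sum) are
compared between immunogenic and non-immunogenic candidates with the
Mann-Whitney U test.

## Worked example

```bash
neoprio simulate --seed 7 --outdir fixtures --patients 2 --variants-per-patient 8
neoprio prioritize --variants fixtures/variants.tsv --out ranked.tsv
neoprio design --ranked ranked.tsv --proteins fixtures/proteins.fasta \
    --out peptides.tsv --mock-predictor 7
neoprio screen --plates fixtures/plates.csv --out calls.tsv
neoprio compare --calls calls.tsv --out report.tsv
```

`ranked.tsv` (selected columns) for the first patient:

```
patient_id  gene      hgvs_protein  rna_alt  tpm     ipv_rank  tpm_pctile  rna_vaf_pctile
P01         P01_G007  p.Gln132Asp   26       147.45  1         93.75       93.75
P01         P01_G004  p.Arg10Ser    19       24.88   2         68.75       81.25
P01         P01_G006  p.His114Ala   15       11.63   3         18.75       68.75
```

The top-ranked variant combines the highest RNA VAF with the highest
expression; the percentile columns are its per-donor standing on each
ranking metric. `calls.tsv` then shows the plate analysis — e.g.

```
patient_id  stimulus  cytokine  sfc_per_million  background_sfc  net_sfc  positive
P01         ipv_long  IFNg      380.0            25.0            355.0    1
```

a pool well averaging 38 spots at 100,000 cells/well is 380 SFC/10⁶,
and 355 net SFC over background is well above the 100-SFC positivity
bar. In the library, the headline exact test is one call:

```python
>>> from neoprio import Contingency2x2, fisher_exact_two_sided
>>> fisher_exact_two_sided(Contingency2x2(5, 6, 0, 11))
0.03508771929824561
```

i.e. five positive responses out of eleven long-peptide pools against
zero out of eleven short-peptide pools is significant at p ≈ 0.035.

## Layout

| module | role |
| --- | --- |
| `neoprio.io` | TSV/CSV/FASTA readers and writers, validated records |
| `neoprio.prioritize` | six-filter variant selection, ranking, percentiles |
| `neoprio.design` | 20-mer and 8–12-mer candidate construction |
| `neoprio.tesla` | class-I metrics, thresholds, foreignness, mock predictor |
| `neoprio.screen` | SFC normalization, positivity calls, deconvolution |
| `neoprio.stats` | Fisher exact, Mann-Whitney, contingency construction |
| `neoprio.simulate` | seeded synthetic cohorts, plates, reference epitopes |
| `neoprio.pipeline` / `neoprio.cli` | orchestration and the `neoprio` command |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
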