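# Methods

This note records the models implemented, the defaults chosen where a
published description was silent, and what the synthetic cohorts do and
do not establish about real data.

## Variant filtering and ranking

The six selection criteria are applied conjunctively, exactly as
listed, even though the 2% tumor-VAF criterion is implied by the 5%
one; both flags are reported separately so a filter report shows each
predicate's own behaviour. Boundary values are inclusive on both sides
of criterion 5 (normal VAF ≤ 5%, tumor VAF ≥ 5%). A variant with zero
normal-sample VAF passes the tumor/normal ratio criterion: the ratio is
undefined but the variant is maximally tumor-associated. "Tumor variant
frequency" in criterion 1 is read as tumor **DNA** VAF. Zero read
depth yields VAF 0 with an explicit flag rather than an error, so
uncovered sites fail quietly on evidence rather than crashing a batch.

Only single-residue missense substitutions are accepted by the HGVS
parser at this stage (one- or three-letter codes); nonsense,
frameshift, synonymous and indel classes are rejected because the
peptide designs center a single mutant residue.

Ranking is a stable lexicographic sort — RNA VAF descending, TPM
descending, genotype priority ascending (hom-alt = 1, het = 2,
hom-ref = 3) — with input order as the final tie-break, making output
deterministic for identical inputs. The percentile-rank columns
(per-donor midrank percentiles, `(rank − 0.5)/n × 100`, ties sharing
the mean rank) are reporting outputs, not part of the sort key. The
midrank definition was chosen because it is symmetric (mean exactly 50
on tie-free data) and invariant under monotone transforms.

## Peptide design

The two 20-mers place the mutant residue at positions 6 and 15, so
their union spans mutation ± 14 and their intersection mutation ± 5.
Windows that would cross a protein terminus are shifted minimally to
fit while keeping length 20 (`clamped = True`, mutant offset
recomputed); if both windows clamp to the same start only one candidate
is emitted, and a protein shorter than 20 residues yields itself as the
single candidate. The 8–12-mer enumeration is restricted to
mutation-spanning windows: non-spanning windows are wild-type sequence
and cannot be neoepitopes. Candidates containing U or X are dropped
with a warning because binding predictors reject them.

The short-binder pool selects, among all mutation-spanning 8–12-mers
inside the two 20-mers, the top n unique sequences by best (minimum)
IC50 across the patient's alleles, ties broken by length then
alphabetically. IC50 rather than percentile rank was chosen as the
selection score, with the tie-break making the choice total.
Lengthening a short candidate picks the containing 20-mer; when both
contain it, the one whose mutant residue is most central within the
short peptide's span wins, ties to the offset-6 design.

## Class-I metrics

Binding affinity and stability come from a predictor interface: either
a precomputed table keyed by (peptide, allele) or a deterministic mock.
The wild-type peptide for agretopicity is scored on the **mutant's**
best allele, so the ratio compares presentation of the same ligand pair
on one HLA molecule. Thresholds (IC50 < 68 nM, stability > 1.7 h,
TPM > 10, agretopicity < 0.1, foreignness > 10⁻¹⁶) are all strict, and
a candidate lacking a stability prediction fails that criterion with an
explicit `stability_missing` flag rather than passing silently.

Foreignness uses the TCR recognition-probability form: the best
gapless (ungapped Smith-Waterman) BLOSUM62 local alignment score `s`
against each reference epitope enters `S = Σₑ exp(−k (a − s))`,
`R = S/(1+S)`, with displacement `a = 26` and steepness `k = 4.87` as
defaults; both are configurable and echoed into the run manifest. `R`
is evaluated as a logistic of a log-sum-exp so near-identical matches
cannot overflow, and is capped strictly below 1. The reference epitope
set is an explicit input — results depend on its contents, and no
canonical snapshot is bundled.

The post-filter ranking key is ascending best IC50 (ties: descending
foreignness, then sequence); no published key exists for this step, so
the choice is isolated in one function.

## Screen analysis

Counts are converted as `raw × 10⁶ / cells_per_well` (×10 at the
standard 100,000 cells/well), replicates are averaged per condition,
and the background is the pooled mean of **all** media and DMSO wells
of the same patient/cytokine (the pooling rule is a design choice; both
raw values are retained in output). Positivity is strict: net SFC must
exceed the threshold (default 100), so a net of exactly 100 is
negative. Negative nets are reported as computed, not clipped. A PHA
positive-control condition that fails to clear the threshold marks the
group's calls `QC-warn` without dropping data, since no published
exclusion rule exists. Deconvolution simply re-applies the positivity
call to each member stimulus of a positive pool; an empty result is
valid and meaningful.

## Statistics

The two-sided Fisher p-value uses the probability-mass convention (sum
of all tables with the observed margins whose probability does not
exceed the observed table's), delegated to `scipy.stats.fisher_exact`
and verified in the test suite against an independent
integer-arithmetic enumeration oracle for totals ≤ 60. This convention
reproduces the published pool-comparison p-values (0.035, 0.011, 0.16,
0.21, 1) from their printed counts. Notably, the published
long-vs-short IL-5 value of 0.048 is reproduced by the counts
[[5,13],[0,15]] — i.e. 18 long-pool tests — not by the 19-test margins
of the published summary table; the comparison module computes from
whatever calls it is given and hard-codes nothing.

Mann-Whitney uses the exact null distribution when the pooled sample
is tie-free with n ≤ 16, otherwise the normal approximation with tie
and continuity corrections. Significance is reported at p ≤ 0.05 with
no multiple-testing correction, matching the comparison design.

## Synthetic cohorts

The generator emulates the *structure* of a tumor/normal sequencing
study: random uniform-composition proteins with one implanted missense
SNV each; tumor VAF = floor + (1 − floor)·Beta(2, 8) with a 5% floor
(called somatic variants are reported above the callable threshold);
normal contamination VAF 1%; DNA depths uniform 50–200×, RNA 20–100×;
alt counts binomial at the sampled VAF; TPM log-normal (meanlog 3,
sdlog 1.5 — median ≈ 20 TPM with a realistic multi-decade spread for
expressed genes). A configurable fraction (default 25%) of variants is
designated immunogenic and receives a ×4 TPM shift, encoding the
observation that recognized variants tend to come from highly
expressed genes. Plates draw Poisson spot counts: background 3
spots/well, +30 spots/well for stimuli containing an immunogenic
member (≈ 300 net SFC at 100,000 cells/well), PHA at 100. Default
scale is 4 patients × 20 variants — desk-scale but structurally
faithful; hundreds of variants per patient are reachable by config.

All randomness flows from one seed through named substreams
(proteins / evidence / plates / epitopes), so regenerating one artifact
never perturbs another and outputs are byte-identical per seed.

What the generator does **not** model: mutational signatures, linked
transcript isoforms, HLA allele frequencies, inter-replicate
overdispersion beyond Poisson, or any real relationship between
peptide sequence and immunogenicity (the mock predictor is a hash, not
a model). Passing end-to-end tests therefore demonstrates pipeline
correctness and statistical calibration under the stated noise model,
not predictive validity on patient material — per-patient biological
outcomes (which genes deconvolute as positive, response magnitudes)
depend on real samples and are out of reach at desk scale.

## Problem sizes and determinism

The seeded study in `scripts/acceptance.py` uses 50 cohorts of
4 × 20 variants for the power estimate of the TPM percentile
comparison (measured power ≈ 0.86–0.98 across master seeds), 50 null
cohorts (400 pool calls) for the false-positive rate, and one full
dual-pipeline run. The mock predictor derives IC50 (log-uniform
1–50,000 nM) and stability (uniform 0.1–10 h) from an FNV-1a hash of
seed|peptide|allele, making every prediction platform-independent and
reproducible without any external model.

## Known limitations

- The optional VCF reader expects SnpEff-style `ANN` fields and
  per-sample `AD`/`DP`; other caller dialects need conversion to the
  canonical TSV, which is the contract.
- Only missense SNVs are designed; frameshift/stop-loss neo-ORFs and
  splice products are out of scope.
- Gene-level TPM stands in for transcript-level abundance; the variant
  table's gene id is the join key to the protein FASTA.
- Foreignness with a gapped aligner, or alternative reference
  snapshots, would change scores; both are deliberate inputs, not
  constants.
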