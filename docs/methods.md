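# Methods

## Problem and model

Somatic variants in cell-free DNA (cfDNA) whole-exome data occur at low
allele fractions and are vastly outnumbered by sequencing and PCR
artifacts: on the order of one high-confidence somatic variant (HCSV)
per thousand called variants. `cfsomatic` treats variant filtering as
supervised classification. The positive class is defined
operationally from a matched tumour-tissue sample: a cfDNA variant is
an HCSV when the same SNV, in the merged tissue call set, passes a
stringent filter — read depth strictly greater than 70 (low-depth
mode) or 500 (high-depth mode), site QUAL ≥ 50, membership in COSMIC
coding mutations, absence from dbSNP common variants, and an allele
fraction outside the germline-like windows ([0.4, 0.6] or > 0.9).
Every other called cfDNA variant is an artefact variant (AV). No
matched-normal sample is used; germline variants are suppressed by the
allele-fraction filter and the dbSNP exclusion.

The classifier is a Random Forest over fifteen per-variant features:

| group | features |
|---|---|
| alignment | standardized read depth (ref+alt reads), allele frequency alt/(ref+alt), Fisher strand bias (Phred-scaled two-sided p), medians over alt-supporting reads of fragment length, mapping quality, base quality and distance from the nearer read end |
| reference context | GC% and weighted homopolymer rate (WHR) of the 41-base window centred on the variant |
| call set | four caller-provenance flags (bcftools, FreeBayes, LoFreq, Mutect2), dbSNP flag, COSMIC flag |

WHR = Σ lᵢ² / k over the k maximal single-base runs of length lᵢ ≥ 4
inside the window; runs clipped by the window edge count with their
visible length, runs do not span N, and a window with no qualifying
run scores 0. Read depth counts only ref- plus alt-supporting reads;
reads showing a third base are excluded from depth and AF. Depth is
z-scored with mean and *population* (divide-by-n) SD fitted on the
training split only and reused unchanged for validation and test, so
no scaling statistics leak across splits.

## Ensemble merging

Each caller's VCF is decomposed (one record per ALT, sharing the site
QUAL), indels are removed, and duplicate keys within a caller keep the
maximum QUAL. Merging is an exact-key union on (contig, pos, ref,
alt); no left-alignment is needed because only SNVs survive
normalization. The representative site QUAL of a merged variant — used
by the truth filter and the rule-based baseline — is the maximum over
the callers that detected it (monotone in evidence; callers' merged-VCF
conventions differ, so a single deterministic rule is used). The
germline AF filter discards AF in [0.4, 0.6] inclusive and AF > 0.9
strict ("between" read as inclusive, "above" as strict), with AF always
computed from site evidence rather than caller INFO fields, whose
encodings are caller-specific. Database matching is allele-exact by
default; position-only matching is a switch.

## Training loop

The HCSV:AV imbalance makes a plainly fitted forest collapse to the
majority class, so the undersampling ratio is itself optimised:

1. pooled labelled vectors are split 70:30 (stratified by label) into
   Training and Validation Data;
2. outer loop — Training Data is randomly undersampled to each of
   1:10, 1:5, 2:5, 3:5, 4:5 and 1:1 HCSV:AV. All positives are kept;
   negatives retained = min(N, ⌊P·neg/pos⌋), drawn uniformly without
   replacement (floor rather than round, fixed for determinism);
3. inner loop — a randomized search (100 candidate draws by default)
   over forest hyperparameters (trees 100–800; max depth None/5–40;
   min leaf 1–10; min split 2–20; feature subset sqrt/log2/0.3),
   scored by mean recall over 3-fold cross-validation that keeps
   variants of one sample together (GroupKFold). With fewer than three
   sample groups the search falls back to stratified 3-fold with a
   logged warning. A fold without positives contributes recall 0
   (pessimistic rather than skipped);
4. each ratio's refitted best model predicts on the full,
   never-undersampled Validation Data; candidates are ranked by
   validation recall, then precision, then PR-AUC, then the more
   imbalanced ratio. Selection metrics use a 0.5 probability cut; the
   production HCSV threshold defaults to 0.75 (call = probability ≥
   threshold), trading some of the recall selected for during
   optimisation against false positives.

Low- and high-depth models share one code path; "mode" only changes
the truth depth threshold and the rule-based depth cuts. One global
seed drives every stochastic step (splitting, undersampling, search,
forest fitting) through `numpy.random.SeedSequence` spawning, so a run
is reproducible bit-for-bit.

## Evaluation

Average precision is the step-wise weighted mean AP = Σₙ (Rₙ−Rₙ₋₁)·Pₙ
over decreasing distinct-score thresholds with R₀ = 0 — no
trapezoidal interpolation. ROC curves are deliberately not offered:
with ~10³:1 imbalance the false-positive rate is uninformatively small.
PR curves store a recall-0 anchor carrying the first threshold's
precision (plot convenience only; AP is unaffected). Precision is
reported as missing when nothing is called positive. Permutation
importance shuffles one feature column at a time (default 30
repetitions, AP scoring, seeded) and reports mean ± SD of the AP drop;
partial dependence sets a feature to each grid value in every
background vector and averages predicted probabilities.

The rule-based baseline retains a variant when depth exceeds the
level's cut (low mode: >20/>10/>5 for hard/medium/soft; high mode:
>1000/>750/>500), QUAL ≥ 50/40/20, dbSNP flag is 0, COSMIC flag is 1,
and the germline AF filter passes. Depth cuts are strict and QUAL
inclusive, following the printed operators; by construction hard ⊆
medium ⊆ soft.

## Synthetic cohorts

The generator emulates the *statistical* structure of ensemble-called
WES data so the whole pipeline is testable without sequence data. From
one seed it produces: a reference contig with planted homopolymer
runs; per-sample planted SNVs at a configurable prevalence of true
somatics (default 0.001 ≈ 1:1000, matching the imbalance the pipeline
is designed for); per-read evidence tables (strand, fragment length,
base/mapping quality, distance from read end) consistent with the
drawn depths and allele fractions; four partially concordant caller
call sets per tissue type; and cohort-level dbSNP/COSMIC key sets.

Class-conditional distributions are simple parametric families with
artifact baselines and signed effect sizes (`SignalConfig`): true
somatics get COSMIC enrichment (0.90 vs 0.02), higher caller
concordance and QUAL (+45 Phred), a shorter alt fragment length
(−35 bp, the ctDNA fragmentation signal), low cfDNA AF
(Beta(2, 25) clipped to [0.01, 0.35]) with higher tissue AF; artifacts
get dbSNP enrichment (0.15), strand-skewed alt support (rate 0.35),
and base/mapping-quality deficits (10/15). The artifact AF mixture
(70 % low Beta(1.5, 20), 20 % uniform in [0.4, 0.6], 10 % above 0.9)
deliberately exercises every branch of the germline filter.
cfDNA depth is ~N(30, 8) in low mode and ~N(750, 120) in high mode;
matched tissue ~N(110, 25) and ~N(700, 120), placing most — not all —
true somatics above the truth depth cut. `SignalConfig.null()` zeroes
every effect, giving identically distributed classes: the negative
control under which learned validation AP must match prevalence.

Positions are partitioned across samples so that cohort-level
membership databases can never contradict per-sample flags. The
generator also injects indel and multiallelic lines into the raw
caller VCFs to exercise normalization. Oracle truth-eligibility is
bookkept per planted variant by applying the exact truth predicates to
the realized (not drawn) tissue counts and emitted QUALs, so pipeline
truth recovery can be checked for set equality, not approximately.
What the generator does *not* model: read-level sequence errors,
alignment artifacts, mappability structure, correlated errors between
callers, contamination, and real mutational signatures — passing tests
demonstrate the machinery is correct and learnable signal is learned,
not that real-data performance is reproduced.

## Numerical choices and degenerate inputs

- Fisher strand bias: two-sided exact test on the {ref,alt}×{fwd,rev}
  table; degenerate tables (an empty row or column) carry no strand
  information and score 0; p-values are Phred-capped at 10000.
- Medians over an even number of alt reads average the two central
  values; reads with zero/undefined template length are excluded from
  the fragment-length median only.
- Variants with no alt-supporting read in the evidence are dropped
  from the feature table with a logged count rather than imputing five
  undefined features.
- "Distance from end of read" is the distance to the *nearer* end of
  the aligned portion of the read — the conventional artifact signal;
  one fixed end would be an equally defensible reading.
- Zero-SD depth scaler maps every depth to 0.
- Depth-histogram mode ties resolve to the smallest depth.
- The probability threshold is inclusive (call at exactly 0.75).

## Problem sizes used in the checks

The test-suite and acceptance-script cohorts are deliberately
desk-scale: up to 4 samples × 12,500 variants (50,000 total, ~30×
cfDNA depth, prevalence 0.005) for the end-to-end learning check, a
20-draw randomized search over a reduced grid (trees ≤ 400), 10
single-sample null-signal cohorts of 4,000 variants, and exhaustive
Fisher verification over all 2×2 tables with total ≤ 40. These sizes
make the full nested loop run in minutes on one core while keeping
every check property-based rather than anecdotal.

## Known limitations

- The truth set is operational, not biological: a tissue biopsy
  samples one site of a heterogeneous tumour, so real truth sets are
  incomplete and model false-positive rates are correspondingly
  overestimated. The synthetic oracle sidesteps this by construction.
- Rows whose alt reads all lack a template length would carry a
  missing fragment-length median; the forest does not accept missing
  values, so such rows should be imputed or dropped upstream (the
  generator never produces them).
- Only SNVs are modelled; indels and MNVs are removed at
  normalization.
- Class-weighted forests (an alternative to undersampling) are not
  implemented.
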