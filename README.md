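# cfsomatic

Ensemble machine-learning prediction of high-confidence somatic
variants (HCSVs) in cell-free DNA (cfDNA) whole-exome sequencing data.

Circulating tumour DNA is a small fraction of plasma cfDNA, so real
somatic variants sit at low allele fractions among a ~1000-fold excess
of sequencing and PCR artifacts. `cfsomatic` is for analysts running
liquid-biopsy WES who need to shrink an ensemble call set to a
reviewable list without discarding true positives. It:

- merges the call sets of **bcftools, FreeBayes, LoFreq and Mutect2**
  into one set of biallelic SNVs with caller-provenance flags
  (multiallelic decomposition, indel removal, germline
  allele-frequency filter, dbSNP-common / COSMIC-coding annotation);
- extracts **15 features** per variant from alignments (depth, allele
  frequency, Fisher strand bias, medians over alt-supporting reads of
  fragment length, base/mapping quality and distance from read end),
  the reference (GC%, weighted homopolymer rate of the 41-bp window),
  and the call sets (caller and database membership flags);
- builds a truth set from a **matched tumour-tissue sample** after
  stringent filtering (depth > 70 or > 500 by sequencing depth,
  QUAL ≥ 50, in COSMIC, not in dbSNP, non-germline AF), labelling
  cfDNA variants HCSV (positive) or artefact (negative);
- trains a **class-balanced Random Forest**: training data is randomly
  undersampled to each of six HCSV:AV ratios (1:10 … 1:1), each ratio
  is tuned by a 100-candidate randomized search under sample-grouped
  3-fold CV scored by recall, and the model with the best validation
  recall/precision/PR-AUC is kept with an HCSV probability threshold
  of 0.75;
- evaluates with precision, recall, confusion counts, PR curves with
  step-wise average precision AP = Σₙ(Rₙ−Rₙ₋₁)Pₙ, permutation feature
  importance, partial dependence, and a hard/medium/soft **rule-based
  filtering baseline**.

A fully seeded synthetic-cohort generator (reference contig, planted
variants, caller call sets, per-read evidence, membership databases)
makes every stage testable end-to-end without sequence downloads.

## Worked example

Train on a simulated low-depth cohort (three train/validation samples,
one held out) and evaluate the selected model:

```bash
$ cfsomatic train --out run --samples 3 --variants 800 --prevalence 0.02 \
      --candidates 2 --seed 3
ratio  precision   recall   pr_auc
 1:10   1.000000 0.909091 0.947552
  1:5   1.000000 0.909091 0.956710
  2:5   0.523810 1.000000 0.961722
  3:5   0.666667 0.909091 0.961722
  4:5   0.500000 1.000000 0.961722
  1:1   0.588235 0.909091 0.964646
selected ratio 2:5
test (S3): recall=0.941 precision=1.000 PR-AUC=0.987
```

The table is the outer loop: one tuned forest per undersampling ratio,
scored on the full (never undersampled) validation data at a 0.5 cut.
Recall is prioritised — here 2:5 and 4:5 tie at recall 1.00 and 2:5
wins on the later tie-breaks — because a missed somatic variant cannot
be recovered downstream, while false positives can be removed by
orthogonal validation. The final line applies the selected model to
the held-out sample at the production 0.75 threshold: 16 of the 17
held-out true HCSVs are recovered with no false positives. Artifacts
written to `run/`: `model.joblib` (forest + depth scaler + ratio +
threshold + seed), `ratio_sweep.tsv`, `test_report.json`.

The same flow in Python:

```python
from cfsomatic import CohortConfig, simulate_cohort, predict_hcsv
from cfsomatic.pipeline import run_cohort_pipeline

cohort = simulate_cohort(CohortConfig(n_samples=3, n_variants_per_sample=800,
                                      prevalence=0.02, seed=3))
result = run_cohort_pipeline(cohort, test_samples=("S3",), seed=3)
calls = predict_hcsv(result.model, result.test_vectors)
```

Other commands: `cfsomatic simulate` (write a cohort to disk as
FASTA + per-caller VCFs + evidence/label TSVs), `cfsomatic predict`
(score a feature TSV with a saved model), `cfsomatic depth-hist`
(per-position depth histogram and modal depth, used to choose depth
thresholds).

On real data the same library functions apply: read each caller's VCF
with `read_caller_vcf`, collect per-read evidence from the BAM with
`collect_site_evidence` (or supply the tabular evidence format), and
feed `build_feature_table` / `build_truth_set` / `train_final_model`.

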