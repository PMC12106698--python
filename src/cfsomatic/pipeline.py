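"""End-to-end orchestration: caller VCFs + evidence -> labelled features -> model.

Ties the stage modules together in the order the workflow prescribes:

1. per caller: normalize (decompose multiallelics, drop indels);
2. merge the four call sets with provenance flags;
3. compute per-site depth/AF from evidence and discard germline-like
   variants (AF in [0.4, 0.6] or > 0.9);
4. annotate dbSNP-common and COSMIC-coding membership;
5. extract the fifteen features per variant;
6. build the matched-tissue truth set and label cfDNA variants;
7. train the class-balanced Random Forest and evaluate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import ensemble_merge as em
from . import feature_extraction as fx
from .model_training import (
    CANONICAL_RATIOS,
    BalancingRatio,
    FinalModel,
    SearchSpace,
    train_final_model,
)
from .synthetic_fixtures import Cohort, SimulatedSample
from .truth_labeling import TruthConfig, TruthSet, build_truth_set, label_cfdna_variants
from .variant_io import EvidenceTable, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "merge_and_annotate",
    "extract_sample_features",
    "tissue_summary",
    "label_sample",
    "PipelineResult",
    "run_cohort_pipeline",
]


def merge_and_annotate(
    caller_records: Mapping[str, Sequence[VariantRecord]],
    evidence: EvidenceTable,
    dbsnp: em.MembershipDB,
    cosmic: em.MembershipDB,
    apply_af_filter: bool = True,
) -> list[em.MergedVariant]:
    """Normalize, merge, AF-filter and annotate one sample's call sets."""
    normalized = {c: em.normalize_records(list(r)) for c, r in caller_records.items()}
    merged = em.merge_caller_sets(normalized)
    if apply_af_filter:
        site = evidence.depth_af_table()
        af_by_key = dict(
            zip(
                zip(site["contig"], site["pos"], site["ref"], site["alt"]),
                site["af"].to_numpy(float),
            )
        )
        afs = [
            float(af_by_key.get((m.key.contig, m.key.pos, m.key.ref, m.key.alt), 0.0))
            for m in merged
        ]
        merged = em.germline_af_filter(merged, afs)
    merged = em.annotate_membership(merged, dbsnp)
    merged = em.annotate_membership(merged, cosmic)
    return merged


def extract_sample_features(
    sample_id: str,
    caller_records: Mapping[str, Sequence[VariantRecord]],
    evidence: EvidenceTable,
    reference: Mapping[str, str],
    dbsnp: em.MembershipDB,
    cosmic: em.MembershipDB,
) -> pd.DataFrame:
    """Feature table for one cfDNA sample (unlabelled)."""
    merged = merge_and_annotate(caller_records, evidence, dbsnp, cosmic)
    table, dropped = fx.build_feature_table(merged, evidence, reference)
    table.insert(0, "sample", sample_id)
    logger.info(
        "%s: %d merged variants, %d feature rows, %d dropped",
        sample_id,
        len(merged),
        len(table),
        dropped,
    )
    return table


def tissue_summary(
    caller_records: Mapping[str, Sequence[VariantRecord]],
    evidence: EvidenceTable,
    dbsnp: em.MembershipDB,
    cosmic: em.MembershipDB,
) -> pd.DataFrame:
    """Merged, annotated tissue variants with evidence depth/AF and QUAL.

    The germline AF filter is *not* applied here; it is one of the truth
    predicates and is handled inside ``build_truth_set``.
    """
    merged = merge_and_annotate(
        caller_records, evidence, dbsnp, cosmic, apply_af_filter=False
    )
    base = em.merged_to_dataframe(merged)
    if base.empty:
        return pd.DataFrame(
            columns=["contig", "pos", "ref", "alt", "depth", "af", "qual", "in_cosmic", "in_dbsnp"]
        )
    site = evidence.depth_af_table()[["contig", "pos", "ref", "alt", "depth", "af"]]
    out = base.merge(site, on=["contig", "pos", "ref", "alt"], how="left")
    out["depth"] = out["depth"].fillna(0).astype(int)
    out["af"] = out["af"].fillna(0.0)
    out["in_cosmic"] = out["in_cosmic"].astype(bool)
    out["in_dbsnp"] = out["in_dbsnp"].astype(bool)
    return out[["contig", "pos", "ref", "alt", "depth", "af", "qual", "in_cosmic", "in_dbsnp"]]


def label_sample(
    sample: SimulatedSample,
    reference: Mapping[str, str],
    dbsnp: em.MembershipDB,
    cosmic: em.MembershipDB,
    truth_config: TruthConfig,
) -> tuple[pd.DataFrame, TruthSet]:
    """Run the full per-sample path on a simulated pair: features + labels."""
    features = extract_sample_features(
        sample.sample_id,
        sample.cf_caller_records,
        sample.cf_evidence,
        reference,
        dbsnp,
        cosmic,
    )
    tissue = tissue_summary(sample.tissue_caller_records, sample.tissue_evidence, dbsnp, cosmic)
    truth = build_truth_set(tissue, truth_config, source_sample=sample.sample_id)
    return label_cfdna_variants(features, truth), truth


@dataclass(slots=True)
class PipelineResult:
    model: FinalModel
    candidates_report: pd.DataFrame
    train_vectors: pd.DataFrame
    validation_vectors: pd.DataFrame
    test_vectors: pd.DataFrame | None
    truth_sets: dict[str, TruthSet] = field(default_factory=dict)


def run_cohort_pipeline(
    cohort: Cohort,
    test_samples: Sequence[str] = (),
    ratios: Sequence[BalancingRatio] = CANONICAL_RATIOS,
    space: SearchSpace | None = None,
    probability_threshold: float = 0.75,
    seed: int = 0,
) -> PipelineResult:
    """Full training run on a simulated cohort.

    Samples named in ``test_samples`` are held out entirely; the rest
    are pooled, split 70:30 into training and validation, and swept over
    the undersampling ratios.  The held-out feature rows (with the
    training scaler applied) are returned for evaluation.
    """
    from .model_training import candidates_report
    from .feature_extraction import apply_depth_scaler

    tc = cohort.config.truth_config
    trainval_frames = []
    test_frames = []
    truth_sets = {}
    for s in cohort.samples:
        labelled, truth = label_sample(s, cohort.reference, cohort.dbsnp, cohort.cosmic, tc)
        truth_sets[s.sample_id] = truth
        (test_frames if s.sample_id in test_samples else trainval_frames).append(labelled)
    if not trainval_frames:
        raise ValueError("no samples left for training")
    vectors = pd.concat(trainval_frames, ignore_index=True)
    model, candidates, train, val = train_final_model(
        vectors,
        ratios=ratios,
        space=space,
        probability_threshold=probability_threshold,
        seed=seed,
    )
    test = None
    if test_frames:
        test = pd.concat(test_frames, ignore_index=True)
        test["read_depth_std"] = apply_depth_scaler(model.scaler, test["read_depth"])
    return PipelineResult(
        model=model,
        candidates_report=candidates_report(candidates),
        train_vectors=train,
        validation_vectors=val,
        test_vectors=test,
        truth_sets=truth_sets,
    )
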