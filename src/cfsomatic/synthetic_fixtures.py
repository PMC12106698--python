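"""Self-contained synthetic cohorts for exercising the whole pipeline.

Generates, from one seed: a reference contig with controllable GC and
homopolymer content; planted variants per sample at a configurable
prevalence of true somatics (default 1:1000, the order of imbalance
seen in real low-depth cfDNA exomes); four partially concordant caller
call sets for cfDNA and matched tissue, with concordance and QUAL
higher for true somatics; per-read site evidence consistent with the
drawn allele fractions and depths; and dbSNP-common / COSMIC-coding
membership key sets.

Class-conditional signal is parametric and fully dialable through
:class:`SignalConfig`: true somatics are enriched for COSMIC
membership, shorter alt fragments (the ctDNA fragmentation signal) and
higher caller concordance/QUAL; artifacts are enriched for dbSNP
membership, strand-skewed alt support, and lower alt base/mapping
quality.  ``SignalConfig.null()`` zeroes every effect so both classes
are drawn from identical distributions — the negative control for the
learning pipeline.

This generator emulates the *statistical* structure of ensemble-called
WES data, not reads: there is no sequence-error model, no alignment,
and artifacts are planted rather than emergent.
"""

from __future__ import annotations

import os
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .truth_labeling import TruthConfig
from .variant_io import CALLERS, EvidenceTable, VariantKey, VariantRecord
from .ensemble_merge import MembershipDB

__all__ = [
    "SignalConfig",
    "CohortConfig",
    "SimulatedSample",
    "Cohort",
    "generate_reference",
    "simulate_sample",
    "simulate_cohort",
    "oracle_labels",
    "write_records_vcf",
]


@dataclass(frozen=True, slots=True)
class SignalConfig:
    """Class-conditional effect sizes separating true somatics from artifacts.

    The artifact distributions are the baseline; each field moves the
    true-somatic (or artifact) class away from it.  Zeroing everything
    makes the two classes statistically identical.
    """

    p_cosmic_true: float = 0.90
    p_cosmic_artifact: float = 0.02
    p_dbsnp_true: float = 0.01
    p_dbsnp_artifact: float = 0.15
    depth_shift_sd: float = 0.5  # true-somatic depth shift, in depth SDs
    strand_bias_rate: float = 0.35  # fraction of artifacts with skewed alt strand
    fragment_shift: float = -35.0  # bp added to true-somatic alt fragment length
    baseq_deficit: float = 10.0  # Phred subtracted from artifact alt base quality
    mapq_deficit: float = 15.0  # subtracted from artifact alt mapping quality
    qual_shift: float = 45.0  # added to true-somatic caller QUAL
    af_separation: float = 1.0  # 0 = true AFs drawn from the artifact mixture
    caller_sens_true: tuple[float, float, float, float] = (0.90, 0.85, 0.90, 0.95)
    caller_sens_artifact: tuple[float, float, float, float] = (0.35, 0.30, 0.35, 0.40)
    tissue_sens_true: float = 0.97
    tissue_sens_artifact: float = 0.25

    @classmethod
    def null(cls) -> "SignalConfig":
        """No class separation at all: every feature is pure noise."""
        return cls(
            p_cosmic_true=0.02,
            p_cosmic_artifact=0.02,
            p_dbsnp_true=0.15,
            p_dbsnp_artifact=0.15,
            depth_shift_sd=0.0,
            strand_bias_rate=0.0,
            fragment_shift=0.0,
            baseq_deficit=0.0,
            mapq_deficit=0.0,
            qual_shift=0.0,
            af_separation=0.0,
            caller_sens_true=(0.5, 0.5, 0.5, 0.5),
            caller_sens_artifact=(0.5, 0.5, 0.5, 0.5),
            tissue_sens_true=0.5,
            tissue_sens_artifact=0.5,
        )


@dataclass(frozen=True, slots=True)
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_samples: int = 4
    contig_length: int = 200_000
    contig_name: str = "sim1"
    n_variants_per_sample: int = 5_000
    prevalence: float = 0.001  # true somatics per called variant (~1:1000)
    depth_mode: str = "low"  # low ~10-50x cfDNA; high ~500-1000x
    signal: SignalConfig = field(default_factory=SignalConfig)
    indel_noise_rate: float = 0.02  # raw caller-VCF indel lines (removed on normalize)
    multiallelic_rate: float = 0.01  # raw caller-VCF multiallelic lines
    n_membership_decoys: int = 500  # database keys at positions with no call
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.depth_mode not in ("low", "high"):
            raise ValueError("depth_mode must be 'low' or 'high'")
        total = self.n_samples * self.n_variants_per_sample + self.n_membership_decoys
        if total > self.contig_length // 2:
            raise ValueError("contig too short for the requested variant count")

    @property
    def truth_config(self) -> TruthConfig:
        return TruthConfig.low_depth() if self.depth_mode == "low" else TruthConfig.high_depth()

    def depth_params(self) -> tuple[float, float, float, float]:
        """(cfDNA mean, cfDNA sd, tissue mean, tissue sd) read depths."""
        if self.depth_mode == "low":
            return 30.0, 8.0, 110.0, 25.0
        return 750.0, 120.0, 700.0, 120.0

    def to_json(self, path: str | os.PathLike) -> None:
        payload = asdict(self)
        payload["signal"] = asdict(self.signal)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(slots=True)
class SimulatedSample:
    """One cfDNA/tissue pair with full generator bookkeeping.

    ``planted`` has one row per planted SNV: identity, class, drawn and
    realized allele fractions/depths, memberships, per-caller detection
    outcomes, tissue QUAL, and the oracle truth-eligibility flag.
    """

    sample_id: str
    cf_caller_records: dict[str, list[VariantRecord]]
    tissue_caller_records: dict[str, list[VariantRecord]]
    cf_evidence: EvidenceTable
    tissue_evidence: EvidenceTable
    planted: pd.DataFrame


@dataclass(slots=True)
class Cohort:
    config: CohortConfig
    reference: dict[str, str]
    samples: list[SimulatedSample]
    dbsnp: MembershipDB
    cosmic: MembershipDB


# ---------------------------------------------------------------------------
# reference


def generate_reference(
    length: int,
    gc_fraction: float = 0.41,
    homopolymer_density: float = 1.0,
    seed: int = 0,
) -> str:
    """Seeded random contig with planted homopolymer runs.

    ``homopolymer_density`` is the number of planted runs (length 4-8)
    per kilobase; infeasible densities (planted bases exceeding half the
    contig) raise.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=p)
    n_runs = int(round(homopolymer_density * length / 1000))
    if n_runs * 8 > length // 2:
        raise ValueError("homopolymer density infeasible for this length")
    if n_runs:
        run_lens = rng.integers(4, 9, size=n_runs)
        # place runs on a coarse grid so they never overlap
        slots = rng.choice(length // 10 - 1, size=min(n_runs, length // 10 - 1), replace=False)
        for slot, rl in zip(slots, run_lens):
            start = slot * 10
            seq[start : start + rl] = rng.choice(bases, p=p)
    return "".join(seq)


# ---------------------------------------------------------------------------
# per-sample simulation


def _artifact_af(rng: np.random.Generator, n: int) -> np.ndarray:
    """Artifact AF mixture: mostly low, with germline-mimic components."""
    comp = rng.choice(3, size=n, p=[0.7, 0.2, 0.1])
    af = rng.beta(1.5, 20.0, size=n)
    af = np.where(comp == 1, rng.uniform(0.4, 0.6, size=n), af)
    af = np.where(comp == 2, rng.uniform(0.905, 0.999, size=n), af)
    return np.clip(af, 1e-3, 0.999)


def _true_af(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.clip(rng.beta(2.0, 25.0, size=n), 0.01, 0.35)


def _expand_reads(
    rng: np.random.Generator,
    rep: np.ndarray,
    *,
    base: np.ndarray,
    supports_alt: bool,
    p_fwd: np.ndarray,
    frag_mean: np.ndarray,
    mapq_mean: np.ndarray,
    baseq_mean: np.ndarray,
) -> pd.DataFrame:
    m = rep.size
    strand = np.where(rng.random(m) < p_fwd, "forward", "reverse")
    frag = np.clip(rng.normal(frag_mean, 25.0), 60.0, None).round(1)
    mapq = np.clip(rng.normal(mapq_mean, 4.0), 0.0, 60.0).round(1)
    baseq = np.clip(rng.normal(baseq_mean, 3.0), 2.0, 41.0).round(1)
    dist = rng.integers(0, 75, size=m)
    return pd.DataFrame(
        {
            "_rep": rep,
            "base": base,
            "strand": strand,
            "fragment_length": frag,
            "mapq": mapq,
            "baseq": baseq,
            "dist_from_end": dist,
            "supports_alt": supports_alt,
        }
    )


def _evidence_frame(parts: list[pd.DataFrame], keys: pd.DataFrame) -> EvidenceTable:
    df = pd.concat(parts, ignore_index=True)
    order = np.argsort(df["_rep"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    rep = df.pop("_rep").to_numpy()
    for col in ("contig", "pos", "ref", "alt"):
        df.insert(
            ["contig", "pos", "ref", "alt"].index(col),
            col,
            keys[col].to_numpy()[rep],
        )
    return EvidenceTable(df)


def _other_base(rng: np.random.Generator, ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """A base differing from both ref and alt, per row."""
    all_bases = np.array(list("ACGT"))
    out = np.empty(ref.size, dtype="<U1")
    for i in range(ref.size):
        choices = [b for b in all_bases if b != ref[i] and b != alt[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def simulate_sample(
    config: CohortConfig,
    reference: Mapping[str, str] | str,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    positions: np.ndarray | None = None,
) -> SimulatedSample:
    """Simulate one cfDNA/tissue pair of call sets with evidence.

    ``positions`` (1-based, distinct) may be supplied by the cohort
    driver so keys never collide between samples; otherwise they are
    drawn here.  ``reference`` is a contig-name→sequence mapping or a
    bare sequence string for ``config.contig_name``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = config.signal
    contig = config.contig_name
    refseq = reference if isinstance(reference, str) else reference[contig]
    n = config.n_variants_per_sample

    if positions is None:
        positions = rng.choice(len(refseq) - 1, size=n, replace=False) + 1
    positions = np.sort(np.asarray(positions))
    ref_bases = np.array([refseq[p - 1] for p in positions])
    alt_bases = _other_base(rng, ref_bases, ref_bases)  # any base != ref

    is_true = rng.random(n) < config.prevalence
    if not is_true.any():
        warnings.warn("prevalence x n_variants < 1; forcing one true somatic", stacklevel=2)
        is_true[rng.integers(n)] = True

    # allele fractions -------------------------------------------------
    art_af = _artifact_af(rng, n)
    cf_af = np.where(is_true & (sig.af_separation > 0), _true_af(rng, n), art_af)
    tissue_draw = rng.uniform(0.15, 0.38, size=n)
    if sig.af_separation > 0:
        # tumour fraction is higher in tissue; keep it below the germline AF window
        tissue_af = np.where(is_true, np.clip(np.maximum(cf_af + 0.05, tissue_draw), None, 0.39), _artifact_af(rng, n))
    else:
        tissue_af = np.maximum(cf_af, _artifact_af(rng, n))

    # memberships ------------------------------------------------------
    in_cosmic = rng.random(n) < np.where(is_true, sig.p_cosmic_true, sig.p_cosmic_artifact)
    in_dbsnp = rng.random(n) < np.where(is_true, sig.p_dbsnp_true, sig.p_dbsnp_artifact)

    # caller detection and QUAL ---------------------------------------
    sens_true = np.array(sig.caller_sens_true)
    sens_art = np.array(sig.caller_sens_artifact)
    p_call = np.where(is_true[:, None], sens_true[None, :], sens_art[None, :])
    called = rng.random((n, 4)) < p_call
    none_called = ~called.any(axis=1)
    if none_called.any():
        forced = rng.integers(0, 4, size=int(none_called.sum()))
        called[np.flatnonzero(none_called), forced] = True
    site_qual = np.clip(rng.normal(40.0 + sig.qual_shift * is_true, 10.0), 1.0, 160.0)
    caller_quals = np.clip(site_qual[:, None] + rng.normal(0.0, 5.0, size=(n, 4)), 1.0, None)
    caller_quals = np.where(called, caller_quals, np.nan).round(2)

    t_p = np.where(is_true, sig.tissue_sens_true, sig.tissue_sens_artifact)
    t_called = rng.random((n, 4)) < t_p[:, None]
    t_site_qual = np.clip(rng.normal(40.0 + sig.qual_shift * is_true, 10.0), 1.0, 160.0)
    t_quals = np.clip(t_site_qual[:, None] + rng.normal(0.0, 5.0, size=(n, 4)), 1.0, None)
    t_quals = np.where(t_called, t_quals, np.nan).round(2)
    t_any = t_called.any(axis=1)

    # depths and realized counts --------------------------------------
    cf_mean, cf_sd, t_mean, t_sd = config.depth_params()
    cf_depth = np.clip(
        rng.normal(cf_mean + sig.depth_shift_sd * cf_sd * is_true, cf_sd), 4, None
    ).astype(int)
    cf_alt = np.clip(rng.binomial(cf_depth, cf_af), 1, cf_depth)
    cf_ref = cf_depth - cf_alt
    cf_other = rng.binomial(2, 0.04, size=n)

    t_depth = np.clip(rng.normal(t_mean, t_sd, size=n), 4, None).astype(int)
    t_alt = np.clip(rng.binomial(t_depth, tissue_af), 1, t_depth)
    t_ref = t_depth - t_alt
    # variants uncalled in tissue leave no tissue evidence
    t_alt = np.where(t_any, t_alt, 0)
    t_ref = np.where(t_any, t_ref, 0)

    keys = pd.DataFrame(
        {"contig": contig, "pos": positions, "ref": ref_bases, "alt": alt_bases}
    )

    # cfDNA evidence ---------------------------------------------------
    biased = (~is_true) & (rng.random(n) < sig.strand_bias_rate)
    alt_p_fwd = np.where(biased, np.where(rng.random(n) < 0.5, 0.92, 0.08), 0.5)
    frag_alt_mean = 168.0 + sig.fragment_shift * is_true
    mapq_alt_mean = 55.0 - sig.mapq_deficit * (~is_true)
    baseq_alt_mean = 34.0 - sig.baseq_deficit * (~is_true)

    rep_ref = np.repeat(np.arange(n), cf_ref)
    rep_alt = np.repeat(np.arange(n), cf_alt)
    rep_oth = np.repeat(np.arange(n), cf_other)
    parts = [
        _expand_reads(
            rng,
            rep_ref,
            base=ref_bases[rep_ref],
            supports_alt=False,
            p_fwd=np.full(rep_ref.size, 0.5),
            frag_mean=np.full(rep_ref.size, 168.0),
            mapq_mean=np.full(rep_ref.size, 55.0),
            baseq_mean=np.full(rep_ref.size, 34.0),
        ),
        _expand_reads(
            rng,
            rep_alt,
            base=alt_bases[rep_alt],
            supports_alt=True,
            p_fwd=alt_p_fwd[rep_alt],
            frag_mean=frag_alt_mean[rep_alt],
            mapq_mean=mapq_alt_mean[rep_alt],
            baseq_mean=baseq_alt_mean[rep_alt],
        ),
        _expand_reads(
            rng,
            rep_oth,
            base=_other_base(rng, ref_bases[rep_oth], alt_bases[rep_oth]),
            supports_alt=False,
            p_fwd=np.full(rep_oth.size, 0.5),
            frag_mean=np.full(rep_oth.size, 168.0),
            mapq_mean=np.full(rep_oth.size, 55.0),
            baseq_mean=np.full(rep_oth.size, 34.0),
        ),
    ]
    cf_evidence = _evidence_frame(parts, keys)

    # tissue evidence --------------------------------------------------
    rep_tref = np.repeat(np.arange(n), t_ref)
    rep_talt = np.repeat(np.arange(n), t_alt)
    t_parts = [
        _expand_reads(
            rng,
            rep_tref,
            base=ref_bases[rep_tref],
            supports_alt=False,
            p_fwd=np.full(rep_tref.size, 0.5),
            frag_mean=np.full(rep_tref.size, 168.0),
            mapq_mean=np.full(rep_tref.size, 55.0),
            baseq_mean=np.full(rep_tref.size, 34.0),
        ),
        _expand_reads(
            rng,
            rep_talt,
            base=alt_bases[rep_talt],
            supports_alt=True,
            p_fwd=np.full(rep_talt.size, 0.5),
            frag_mean=np.full(rep_talt.size, 168.0),
            mapq_mean=np.full(rep_talt.size, 55.0),
            baseq_mean=np.full(rep_talt.size, 34.0),
        ),
    ]
    tissue_evidence = _evidence_frame(t_parts, keys)

    # caller VCF records ----------------------------------------------
    cf_records: dict[str, list[VariantRecord]] = {c: [] for c in CALLERS}
    t_records: dict[str, list[VariantRecord]] = {c: [] for c in CALLERS}
    for j, caller in enumerate(CALLERS):
        for i in np.flatnonzero(called[:, j]):
            cf_records[caller].append(
                VariantRecord(
                    contig=contig,
                    pos=int(positions[i]),
                    ref=str(ref_bases[i]),
                    alts=(str(alt_bases[i]),),
                    qual=float(caller_quals[i, j]),
                    caller=caller,
                )
            )
        for i in np.flatnonzero(t_called[:, j]):
            t_records[caller].append(
                VariantRecord(
                    contig=contig,
                    pos=int(positions[i]),
                    ref=str(ref_bases[i]),
                    alts=(str(alt_bases[i]),),
                    qual=float(t_quals[i, j]),
                    caller=caller,
                )
            )

    _inject_vcf_noise(rng, config, cf_records, refseq)

    # oracle bookkeeping ----------------------------------------------
    t_depth_real = t_ref + t_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        t_af_real = np.where(t_depth_real > 0, t_alt / np.maximum(t_depth_real, 1), 0.0)
    t_qual_max = np.nanmax(np.where(t_called, t_quals, -np.inf), axis=1)
    t_qual_max = np.where(t_any, t_qual_max, np.nan)
    tc = config.truth_config
    eligible = (
        t_any
        & (t_depth_real > tc.depth_threshold)
        & ~np.isnan(t_qual_max)
        & (np.nan_to_num(t_qual_max, nan=-1.0) >= tc.qual_threshold)
        & in_cosmic
        & ~in_dbsnp
        & ~((t_af_real >= 0.4) & (t_af_real <= 0.6))
        & ~(t_af_real > 0.9)
    )

    planted = keys.copy()
    planted["is_true_somatic"] = is_true
    planted["cf_af_drawn"] = cf_af.round(5)
    planted["tissue_af_drawn"] = tissue_af.round(5)
    planted["in_cosmic"] = in_cosmic
    planted["in_dbsnp"] = in_dbsnp
    for j, caller in enumerate(CALLERS):
        planted[f"cf_called_{caller}"] = called[:, j]
        planted[f"tissue_called_{caller}"] = t_called[:, j]
    planted["tissue_called_any"] = t_any
    planted["tissue_depth_realized"] = t_depth_real
    planted["tissue_af_realized"] = t_af_real.round(6)
    planted["tissue_qual"] = t_qual_max
    planted["truth_eligible"] = eligible
    planted["sample"] = sample_id

    return SimulatedSample(
        sample_id=sample_id,
        cf_caller_records=cf_records,
        tissue_caller_records=t_records,
        cf_evidence=cf_evidence,
        tissue_evidence=tissue_evidence,
        planted=planted,
    )


def _inject_vcf_noise(
    rng: np.random.Generator,
    config: CohortConfig,
    records: dict[str, list[VariantRecord]],
    refseq: str,
) -> None:
    """Add indel and multiallelic lines that normalization must handle."""
    for caller in CALLERS:
        recs = records[caller]
        n_indel = rng.binomial(len(recs), config.indel_noise_rate)
        for _ in range(n_indel):
            pos = int(rng.integers(1, len(refseq)))
            base = refseq[pos - 1]
            recs.append(
                VariantRecord(
                    contig=config.contig_name,
                    pos=pos,
                    ref=base,
                    alts=(base + "T",),
                    qual=float(np.round(rng.uniform(5, 60), 2)),
                    caller=caller,
                )
            )
        n_multi = rng.binomial(len(recs), config.multiallelic_rate)
        for idx in rng.choice(len(recs), size=n_multi, replace=False):
            rec = recs[idx]
            if len(rec.alts) != 1 or len(rec.alts[0]) != 1 or len(rec.ref) != 1:
                continue
            extra = [b for b in "ACGT" if b != rec.ref and b != rec.alts[0]]
            rec.alts = (rec.alts[0], extra[int(rng.integers(len(extra)))])
        recs.sort(key=lambda r: (r.pos, r.alts))


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate the full cohort: reference, samples, shared membership DBs.

    Positions are partitioned across samples so a key is planted in at
    most one sample — membership databases are cohort-level key sets and
    must not contradict per-sample flags.
    """
    root = np.random.SeedSequence(config.seed)
    ref_seed, pos_seed, decoy_seed, *sample_seeds = [
        int(s) % (2**31) for s in root.generate_state(3 + config.n_samples)
    ]
    refseq = generate_reference(config.contig_length, seed=ref_seed)
    reference = {config.contig_name: refseq}

    total = config.n_samples * config.n_variants_per_sample
    pos_rng = np.random.default_rng(pos_seed)
    all_pos = pos_rng.choice(config.contig_length - 1, size=total + config.n_membership_decoys, replace=False) + 1
    decoy_pos = all_pos[total:]
    all_pos = all_pos[:total]

    samples = []
    for i in range(config.n_samples):
        chunk = all_pos[i * config.n_variants_per_sample : (i + 1) * config.n_variants_per_sample]
        samples.append(
            simulate_sample(
                config,
                reference,
                seed=np.random.default_rng(sample_seeds[i]),
                sample_id=f"S{i + 1}",
                positions=chunk,
            )
        )

    dbsnp_keys: set[VariantKey] = set()
    cosmic_keys: set[VariantKey] = set()
    for s in samples:
        for row in s.planted.itertuples(index=False):
            if row.in_dbsnp:
                dbsnp_keys.add(VariantKey(row.contig, int(row.pos), row.ref, row.alt))
            if row.in_cosmic:
                cosmic_keys.add(VariantKey(row.contig, int(row.pos), row.ref, row.alt))
    decoy_rng = np.random.default_rng(decoy_seed)
    for p in decoy_pos:
        ref = refseq[p - 1]
        alt = "ACGT".replace(ref, "")[decoy_rng.integers(3)]
        (dbsnp_keys if decoy_rng.random() < 0.5 else cosmic_keys).add(
            VariantKey(config.contig_name, int(p), ref, alt)
        )
    return Cohort(
        config=config,
        reference=reference,
        samples=samples,
        dbsnp=MembershipDB("dbsnp_common", dbsnp_keys),
        cosmic=MembershipDB("cosmic_coding", cosmic_keys),
    )


def oracle_labels(sample: SimulatedSample) -> dict[VariantKey, int]:
    """Truth eligibility per planted key.

    A key is HCSV-eligible when its planted tissue evidence passes every
    truth predicate (called in tissue, depth strictly above threshold,
    QUAL >= 50, COSMIC member, not dbSNP, AF outside the germline
    windows); with non-null signal, eligible keys are almost surely true
    somatics.
    """
    out = {}
    for row in sample.planted.itertuples(index=False):
        out[VariantKey(row.contig, int(row.pos), row.ref, row.alt)] = int(row.truth_eligible)
    return out


# ---------------------------------------------------------------------------
# emission


def write_records_vcf(
    records: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write raw caller records (possibly multiallelic / indel) to VCF."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.contig, r.pos, r.alts)):
            v = out.new_record(
                contig=rec.contig,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref,) + rec.alts,
            )
            if rec.qual is not None:
                v.qual = rec.qual
            out.write(v)


def write_cohort(cohort: Cohort, outdir: str | os.PathLike) -> None:
    """Emit the cohort as plain files: FASTA, VCFs, evidence/label TSVs."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    contig = cohort.config.contig_name
    seq = cohort.reference[contig]
    fasta = os.path.join(outdir, "reference.fa")
    with open(fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(fasta)
    lengths = {contig: len(seq)}
    cohort.dbsnp.to_tsv(os.path.join(outdir, "dbsnp_common.tsv"))
    cohort.cosmic.to_tsv(os.path.join(outdir, "cosmic_coding.tsv"))
    cohort.config.to_json(os.path.join(outdir, "config.json"))
    for s in cohort.samples:
        sdir = os.path.join(outdir, s.sample_id)
        os.makedirs(sdir, exist_ok=True)
        for caller in CALLERS:
            write_records_vcf(
                s.cf_caller_records[caller], lengths, os.path.join(sdir, f"cfdna.{caller}.vcf")
            )
            write_records_vcf(
                s.tissue_caller_records[caller],
                lengths,
                os.path.join(sdir, f"tissue.{caller}.vcf"),
            )
        s.cf_evidence.to_tsv(os.path.join(sdir, "cfdna.evidence.tsv"))
        s.tissue_evidence.to_tsv(os.path.join(sdir, "tissue.evidence.tsv"))
        s.planted.to_csv(os.path.join(sdir, "planted.tsv"), sep="\t", index=False)
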