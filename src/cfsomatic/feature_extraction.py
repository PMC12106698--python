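"""Per-variant feature extraction.

Computes the fifteen features used by the classifier from three kinds of
evidence:

* alignment-level — read depth (ref- plus alt-supporting reads), allele
  frequency, Fisher strand bias (Phred-scaled p-value), and medians over
  alt-supporting reads of fragment length, mapping quality, base quality
  and distance from the nearer read end;
* reference-context — GC percentage and the weighted homopolymer rate
  (WHR) of the 41-base window centred on the variant (20 bp each side);
* call-set-level — caller provenance flags and dbSNP/COSMIC membership.

WHR is the sum of squared homopolymer run lengths divided by the number
of runs, where a homopolymer is a maximal single-base run of length >= 4
within the window; windows without a qualifying run score 0.

Read depth is additionally standardised (z-scored) with mean/SD fitted
on training data only and reused unchanged for validation and test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_merge import MergedVariant
from .variant_io import EvidenceTable, ReferenceWindow, SiteEvidence, VariantKey, fetch_reference_window

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "KEY_COLUMNS",
    "ScalerStats",
    "whr_score",
    "gc_percent",
    "strand_bias_phred",
    "depth_and_af",
    "alt_read_medians",
    "fit_depth_scaler",
    "apply_depth_scaler",
    "build_feature_table",
]

#: Model feature columns, in fixed order (standardised depth stands in for
#: the raw read depth).
FEATURE_COLUMNS = [
    "read_depth_std",
    "in_dbsnp",
    "in_cosmic",
    "strand_bias_phred",
    "median_alt_fragment_length",
    "whr",
    "gc_percent",
    "median_alt_mapq",
    "allele_frequency",
    "called_bcftools",
    "called_freebayes",
    "called_lofreq",
    "called_mutect2",
    "median_dist_from_end",
    "median_alt_baseq",
]

KEY_COLUMNS = ["contig", "pos", "ref", "alt"]

PHRED_CAP = 10000.0
MIN_HOMOPOLYMER = 4


def whr_score(window: ReferenceWindow | str) -> float:
    """Weighted homopolymer rate of a reference window.

    Maximal single-base runs of in-window length >= 4 count as
    homopolymers (runs clipped by the window edge count with their
    visible length; runs do not span N).  Returns
    ``sum(len_i**2) / n_runs``, or 0 with no qualifying run.
    """
    seq = window.sequence if isinstance(window, ReferenceWindow) else window
    if not seq:
        raise ValueError("empty window")
    total = 0
    n_runs = 0
    run_base = seq[0]
    run_len = 1
    for ch in seq[1:] + "\0":  # sentinel flushes the last run
        if ch == run_base:
            run_len += 1
            continue
        if run_base != "N" and run_len >= MIN_HOMOPOLYMER:
            total += run_len * run_len
            n_runs += 1
        run_base = ch
        run_len = 1
    return total / n_runs if n_runs else 0.0


def gc_percent(window: ReferenceWindow | str) -> float:
    """GC percentage of the window over called bases (N excluded entirely)."""
    seq = window.sequence if isinstance(window, ReferenceWindow) else window
    if not seq:
        raise ValueError("empty window")
    gc = sum(seq.count(b) for b in "GC")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * gc / acgt


@lru_cache(maxsize=1 << 18)
def _fisher_phred(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    # degenerate tables (an empty row or column) carry no strand information
    if min(ref_fwd + ref_rev, alt_fwd + alt_rev) == 0 or min(
        ref_fwd + alt_fwd, ref_rev + alt_rev
    ) == 0:
        return 0.0
    _, p = stats.fisher_exact([[ref_fwd, ref_rev], [alt_fwd, alt_rev]], alternative="two-sided")
    if p <= 0:
        return PHRED_CAP
    return min(PHRED_CAP, -10.0 * math.log10(p))


def strand_bias_phred(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """Phred-scaled two-sided Fisher exact p-value for strand asymmetry.

    Rows are {ref, alt} support, columns {forward, reverse} strand.
    Degenerate tables score 0; underflowing p-values cap at 10000.
    """
    counts = (ref_fwd, ref_rev, alt_fwd, alt_rev)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative strand count in {counts}")
    return _fisher_phred(*(int(c) for c in counts))


def depth_and_af(evidence: SiteEvidence, key: VariantKey | None = None) -> tuple[int, float]:
    """Read depth (ref + alt supporting reads) and allele frequency.

    Reads showing a third base are excluded from both counts; zero-depth
    sites report AF 0.
    """
    key = key or evidence.key
    ref_count = sum(
        1 for o in evidence.observations if not o.supports_alt and o.base == key.ref
    )
    alt_count = sum(1 for o in evidence.observations if o.supports_alt)
    depth = ref_count + alt_count
    return depth, (alt_count / depth if depth else 0.0)


def _median(values: Sequence[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def alt_read_medians(
    evidence: SiteEvidence,
) -> tuple[float, float, float, float] | None:
    """Medians over alt-supporting reads.

    Returns (fragment length, mapq, baseq, distance from nearer read
    end); even counts average the two central values.  ``None`` when the
    site has no alt-supporting observation (the variant is then dropped
    from the feature table).  Reads with unknown fragment length are
    excluded from the fragment-length median only.
    """
    alt = [o for o in evidence.observations if o.supports_alt]
    if not alt:
        return None
    frags = [o.fragment_length for o in alt if o.fragment_length is not None]
    med_frag = _median(frags) if frags else float("nan")
    return (
        med_frag,
        _median([o.mapq for o in alt]),
        _median([o.baseq for o in alt]),
        _median([o.dist_from_end for o in alt]),
    )


@dataclass(slots=True)
class ScalerStats:
    """Training-set mean and (population) SD of read depth."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def fit_depth_scaler(read_depths: Sequence[float] | pd.Series) -> ScalerStats:
    """Fit the depth standardiser on training data (divide-by-n SD)."""
    arr = np.asarray(read_depths, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    return ScalerStats(mean=float(arr.mean()), sd=float(arr.std(ddof=0)))


def apply_depth_scaler(stats_: ScalerStats, read_depth: "float | np.ndarray | pd.Series"):
    """z-score read depth; a zero-SD scaler maps everything to 0."""
    if stats_.sd == 0:
        return np.zeros_like(np.asarray(read_depth, dtype=float)) if np.ndim(read_depth) else 0.0
    return (np.asarray(read_depth, dtype=float) - stats_.mean) / stats_.sd


def build_feature_table(
    merged: Sequence[MergedVariant],
    evidence: EvidenceTable,
    reference: Mapping[str, str],
    flank: int = 20,
) -> tuple[pd.DataFrame, int]:
    """One feature row per merged variant with alt-supporting evidence.

    Returns ``(table, n_dropped)``; variants with zero alt-supporting
    observations are dropped (their five alt-read features would all be
    undefined) and counted.  ``read_depth_std`` is left NaN here — it is
    filled by :func:`apply_depth_scaler` after the train/validation split
    so scaling statistics never leak out of the training data.
    """
    df = evidence.df
    base_arr = df["base"].to_numpy(str)
    ref_arr = df["ref"].to_numpy(str)
    alt_mask_arr = df["supports_alt"].to_numpy(bool)
    fwd_arr = df["strand"].to_numpy(str) == "forward"
    frag_arr = df["fragment_length"].to_numpy(float)
    mapq_arr = df["mapq"].to_numpy(float)
    baseq_arr = df["baseq"].to_numpy(float)
    dist_arr = df["dist_from_end"].to_numpy(float)
    groups = evidence.groups

    rows: list[dict] = []
    dropped = 0
    window_cache: dict[tuple[str, int], tuple[float, float]] = {}
    for mv in merged:
        k = mv.key
        idx = groups.get((k.contig, k.pos, k.ref, k.alt))
        if idx is None:
            dropped += 1
            continue
        is_alt = alt_mask_arr[idx]
        if not is_alt.any():
            dropped += 1
            continue
        is_ref = (base_arr[idx] == k.ref) & ~is_alt
        counted = is_ref | is_alt
        depth = int(counted.sum())
        af = float(is_alt.sum() / depth)
        fwd = fwd_arr[idx]
        sb = strand_bias_phred(
            int((is_ref & fwd).sum()),
            int((is_ref & ~fwd).sum()),
            int((is_alt & fwd).sum()),
            int((is_alt & ~fwd).sum()),
        )
        alt_idx = idx[is_alt]
        frags = frag_arr[alt_idx]
        frags = frags[~np.isnan(frags)]
        med_frag = float(np.median(frags)) if frags.size else float("nan")

        ck = (k.contig, k.pos)
        ctx = window_cache.get(ck)
        if ctx is None:
            win = fetch_reference_window(reference, k, flank=flank)
            ctx = (whr_score(win), gc_percent(win))
            window_cache[ck] = ctx

        rows.append(
            {
                "contig": k.contig,
                "pos": k.pos,
                "ref": k.ref,
                "alt": k.alt,
                "read_depth": depth,
                "read_depth_std": float("nan"),
                "in_dbsnp": int(mv.in_dbsnp),
                "in_cosmic": int(mv.in_cosmic),
                "strand_bias_phred": sb,
                "median_alt_fragment_length": med_frag,
                "whr": ctx[0],
                "gc_percent": ctx[1],
                "median_alt_mapq": float(np.median(mapq_arr[alt_idx])),
                "allele_frequency": af,
                "called_bcftools": int(mv.called_by["bcftools"]),
                "called_freebayes": int(mv.called_by["freebayes"]),
                "called_lofreq": int(mv.called_by["lofreq"]),
                "called_mutect2": int(mv.called_by["mutect2"]),
                "median_dist_from_end": float(np.median(dist_arr[alt_idx])),
                "median_alt_baseq": float(np.median(baseq_arr[alt_idx])),
                "qual": mv.representative_qual,
            }
        )
    if dropped:
        logger.info("dropped %d merged variants with no alt-supporting evidence", dropped)
    table = pd.DataFrame(rows, columns=KEY_COLUMNS + ["read_depth", "qual"] + FEATURE_COLUMNS)
    return table, dropped
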