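"""Matched-tissue truth sets and cfDNA labelling.

High-confidence somatic variants (HCSVs, the positive class) are defined
operationally: a cfDNA variant is an HCSV when it is also present in the
matched tumour-tissue sample after stringent filtering.  Tissue variants
qualify when they are deep (depth strictly greater than 70 for low-depth
data, 500 for high-depth data), confidently called (QUAL >= 50), present
in COSMIC coding mutations, absent from dbSNP common variants, and not
germline-like by allele frequency.  Every cfDNA variant absent from the
truth set is an artefact variant (AV, negative class).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Set

import numpy as np
import pandas as pd

from .variant_io import VariantKey

__all__ = ["TruthConfig", "TruthSet", "build_truth_set", "label_cfdna_variants"]


@dataclass(frozen=True, slots=True)
class TruthConfig:
    """Stringent filters defining tissue high-confidence variants."""

    depth_threshold: int = 70  # strict: depth must exceed this
    qual_threshold: float = 50.0  # inclusive
    require_cosmic: bool = True
    exclude_dbsnp: bool = True
    apply_af_filter: bool = True

    def __post_init__(self) -> None:
        if self.depth_threshold <= 0:
            raise ValueError("depth_threshold must be > 0")
        if self.qual_threshold < 0:
            raise ValueError("qual_threshold must be >= 0")

    @classmethod
    def low_depth(cls) -> "TruthConfig":
        return cls(depth_threshold=70)

    @classmethod
    def high_depth(cls) -> "TruthConfig":
        return cls(depth_threshold=500)


@dataclass(slots=True)
class TruthSet:
    """Keys of matched-tissue high-confidence variants."""

    keys: Set[VariantKey]
    config: TruthConfig
    source_sample: str = ""

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# source_sample={self.source_sample} config={self.config}\n")
            fh.write("contig\tpos\tref\talt\n")
            for k in sorted(self.keys, key=lambda k: (k.contig, k.pos, k.ref, k.alt)):
                fh.write(f"{k.contig}\t{k.pos}\t{k.ref}\t{k.alt}\n")


def build_truth_set(
    tissue: pd.DataFrame,
    config: TruthConfig,
    source_sample: str = "",
) -> TruthSet:
    """Apply the truth predicates to merged, annotated tissue variants.

    ``tissue`` needs columns contig/pos/ref/alt, depth (ref+alt reads
    from tissue evidence), af, qual (representative site QUAL; NaN fails
    the QUAL criterion), in_cosmic, in_dbsnp.  All enabled predicates
    are conjunctive; their order is immaterial.
    """
    required = {"contig", "pos", "ref", "alt", "depth", "af", "qual", "in_cosmic", "in_dbsnp"}
    missing = required - set(tissue.columns)
    if missing:
        raise ValueError(f"tissue table missing columns: {sorted(missing)}")
    depth = tissue["depth"].to_numpy(float)
    qual = tissue["qual"].to_numpy(float)
    af = tissue["af"].to_numpy(float)
    if np.any((af < 0) | (af > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    mask = depth > config.depth_threshold
    mask &= ~np.isnan(qual) & (qual >= config.qual_threshold)
    if config.require_cosmic:
        mask &= tissue["in_cosmic"].to_numpy(bool)
    if config.exclude_dbsnp:
        mask &= ~tissue["in_dbsnp"].to_numpy(bool)
    if config.apply_af_filter:
        mask &= ~((af >= 0.4) & (af <= 0.6)) & ~(af > 0.9)
    keys = {
        VariantKey(str(r.contig), int(r.pos), str(r.ref), str(r.alt))
        for r in tissue.loc[mask, ["contig", "pos", "ref", "alt"]].itertuples(index=False)
    }
    return TruthSet(keys=keys, config=config, source_sample=source_sample)


def label_cfdna_variants(vectors: pd.DataFrame, truth: TruthSet) -> pd.DataFrame:
    """Attach the binary label: 1 (HCSV) iff the key is in the truth set.

    Input row order is preserved; returns a copy with a ``label`` column.
    """
    out = vectors.copy()
    truth_tuples = {(k.contig, k.pos, k.ref, k.alt) for k in truth.keys}
    labels = [
        int((str(c), int(p), str(r), str(a)) in truth_tuples)
        for c, p, r, a in zip(out["contig"], out["pos"], out["ref"], out["alt"])
    ]
    out["label"] = labels
    return out
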