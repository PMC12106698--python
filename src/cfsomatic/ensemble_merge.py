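"""Ensemble merging of per-caller call sets.

Normalizes each caller's records to biallelic SNVs (multiallelic
decomposition, indel removal), removes likely germline variants by
allele frequency, merges the call sets into one set of keys with
caller-provenance flags, and attaches dbSNP-common / COSMIC-coding
membership flags.

The allele-frequency germline filter discards variants with AF in
[0.4, 0.6] (heterozygous-like) or above 0.9 (homozygous-like); the AF
used in the pipeline is computed uniformly from site evidence rather
than caller INFO fields, whose encodings differ between callers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TypeVar

import pandas as pd
import pysam

from .variant_io import CALLERS, BASES, VariantKey, VariantRecord

__all__ = [
    "MergedVariant",
    "MembershipDB",
    "normalize_records",
    "passes_af_filter",
    "germline_af_filter",
    "merge_caller_sets",
    "annotate_membership",
    "merged_to_dataframe",
    "write_merged_vcf",
]


@dataclass(slots=True)
class MergedVariant:
    """One SNV key with caller provenance, per-caller QUALs and memberships."""

    key: VariantKey
    called_by: dict[str, bool]
    quals: dict[str, float | None]
    in_dbsnp: bool = False
    in_cosmic: bool = False

    @property
    def n_callers(self) -> int:
        return sum(self.called_by.values())

    @property
    def representative_qual(self) -> float | None:
        """Site QUAL used by truth and rule-based filters: max over callers."""
        vals = [q for c, q in self.quals.items() if self.called_by.get(c) and q is not None]
        return max(vals) if vals else None


@dataclass(slots=True)
class MembershipDB:
    """A set of normalized SNV keys from an annotation database."""

    name: str
    keys: set[VariantKey] = field(default_factory=set)

    @classmethod
    def from_vcf(cls, path: str | os.PathLike, name: str) -> "MembershipDB":
        keys: set[VariantKey] = set()
        with pysam.VariantFile(os.fspath(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and len(alt) == 1 and rec.ref in BASES and alt in BASES:
                        keys.add(VariantKey(rec.contig, rec.pos, rec.ref, alt))
        return cls(name=name, keys=keys)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, name: str) -> "MembershipDB":
        """Key list: columns contig, pos, ref, alt (tab-separated, with header)."""
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        keys = {
            VariantKey(str(r.contig), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples(index=False)
        }
        return cls(name=name, keys=keys)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\tref\talt\n")
            for k in sorted(self.keys, key=lambda k: (k.contig, k.pos, k.ref, k.alt)):
                fh.write(f"{k.contig}\t{k.pos}\t{k.ref}\t{k.alt}\n")


def normalize_records(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Decompose multiallelic sites, drop indels, collapse duplicate keys.

    Each ALT of a multiallelic line becomes its own record sharing the
    site QUAL.  Records whose REF or ALT is not a single A/C/G/T base
    are removed.  Duplicate keys within the caller keep the maximum QUAL
    (a missing QUAL sorts below any number).
    """
    best: dict[VariantKey, VariantRecord] = {}
    order: list[VariantKey] = []
    for rec in records:
        for alt in rec.alts:
            if len(rec.ref) != 1 or len(alt) != 1:
                continue
            if rec.ref not in BASES or alt not in BASES or rec.ref == alt:
                continue
            split = VariantRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alts=(alt,),
                qual=rec.qual,
                caller=rec.caller,
                raw_filters=rec.raw_filters,
            )
            k = split.key
            if k not in best:
                best[k] = split
                order.append(k)
            else:
                old = best[k].qual
                if old is None or (split.qual is not None and split.qual > old):
                    best[k] = split
    return [best[k] for k in order]


def passes_af_filter(af: float) -> bool:
    """True when an allele frequency is not germline-like.

    Discards af in [0.4, 0.6] (inclusive) and af > 0.9 (strict).
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return not (0.4 <= af <= 0.6 or af > 0.9)


_T = TypeVar("_T")


def germline_af_filter(variants: Sequence[_T], afs: Sequence[float]) -> list[_T]:
    """Retain variants whose AF passes the germline filter; order preserved."""
    if len(variants) != len(afs):
        raise ValueError("variants and afs differ in length")
    return [v for v, af in zip(variants, afs) if passes_af_filter(af)]


def merge_caller_sets(
    per_caller: Mapping[str, Sequence[VariantRecord]]
) -> list[MergedVariant]:
    """Union of normalized per-caller key sets with provenance flags.

    Output is sorted by (contig, pos, ref, alt); ``called_by`` and
    ``quals`` have one entry per known caller.
    """
    unknown = set(per_caller) - set(CALLERS)
    if unknown:
        raise ValueError(f"unknown callers in merge input: {sorted(unknown)}")
    merged: dict[VariantKey, MergedVariant] = {}
    for caller in CALLERS:
        for rec in per_caller.get(caller, ()):
            k = rec.key
            mv = merged.get(k)
            if mv is None:
                mv = MergedVariant(
                    key=k,
                    called_by={c: False for c in CALLERS},
                    quals={c: None for c in CALLERS},
                )
                merged[k] = mv
            mv.called_by[caller] = True
            mv.quals[caller] = rec.qual
    return sorted(merged.values(), key=lambda m: (m.key.contig, m.key.pos, m.key.ref, m.key.alt))


def annotate_membership(
    variants: Iterable[MergedVariant],
    db: MembershipDB,
    position_only: bool = False,
) -> list[MergedVariant]:
    """Set the dbSNP/COSMIC flag for variants present in ``db``.

    Matching is allele-exact on (contig, pos, ref, alt) by default;
    ``position_only`` relaxes it to (contig, pos).
    """
    if db.name not in ("dbsnp_common", "cosmic_coding"):
        raise ValueError(f"unknown membership database {db.name!r}")
    if position_only:
        positions = {(k.contig, k.pos) for k in db.keys}
    out = []
    for mv in variants:
        hit = (
            (mv.key.contig, mv.key.pos) in positions
            if position_only
            else mv.key in db.keys
        )
        if db.name == "dbsnp_common":
            mv.in_dbsnp = hit
        else:
            mv.in_cosmic = hit
        out.append(mv)
    return out


def merged_to_dataframe(variants: Sequence[MergedVariant]) -> pd.DataFrame:
    """TSV mirror of the merged set (one row per key)."""
    rows = []
    for mv in variants:
        row = {
            "contig": mv.key.contig,
            "pos": mv.key.pos,
            "ref": mv.key.ref,
            "alt": mv.key.alt,
            "qual": mv.representative_qual,
            "in_dbsnp": int(mv.in_dbsnp),
            "in_cosmic": int(mv.in_cosmic),
        }
        for c in CALLERS:
            row[f"called_{c}"] = int(mv.called_by[c])
        rows.append(row)
    return pd.DataFrame(rows)


def write_merged_vcf(
    variants: Sequence[MergedVariant],
    contig_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write the merged set as VCF with CALLED_BY_*, DBSNP and COSMIC INFO flags."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    for c in CALLERS:
        header.info.add(f"CALLED_BY_{c.upper()}", 0, "Flag", f"Called by {c}")
    header.info.add("DBSNP", 0, "Flag", "Present in dbSNP common variants")
    header.info.add("COSMIC", 0, "Flag", "Present in COSMIC coding variants")
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for mv in variants:
            rec = out.new_record(
                contig=mv.key.contig,
                start=mv.key.pos - 1,
                stop=mv.key.pos,
                alleles=(mv.key.ref, mv.key.alt),
            )
            q = mv.representative_qual
            if q is not None:
                rec.qual = q
            for c in CALLERS:
                if mv.called_by[c]:
                    rec.info[f"CALLED_BY_{c.upper()}"] = True
            if mv.in_dbsnp:
                rec.info["DBSNP"] = True
            if mv.in_cosmic:
                rec.info["COSMIC"] = True
            out.write(rec)
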