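"""Reading and writing the standard formats the pipeline touches.

VCF call sets (one per variant caller), coordinate-sorted alignments (BAM)
or an equivalent tabular site-evidence format, and an indexed reference
FASTA.  Everything downstream works with the small value types defined
here: a :class:`VariantKey` identifying a single-nucleotide variant, the
per-read :class:`ReadObservation` records powering alignment-level
features, and the :class:`ReferenceWindow` powering sequence-context
features.

Coordinates are 1-based inclusive (VCF convention) on every public
surface; 0-based arithmetic is confined to the helpers in this module.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "BASES",
    "CALLERS",
    "VariantKey",
    "VariantRecord",
    "ReadObservation",
    "SiteEvidence",
    "ReferenceWindow",
    "EvidenceTable",
    "read_caller_vcf",
    "collect_site_evidence",
    "fetch_reference_window",
    "exome_depth_histogram",
    "write_depth_histogram_tsv",
    "plot_depth_histogram",
]

BASES = frozenset("ACGT")

#: Caller identifiers, in the fixed order used for provenance flags.
CALLERS = ("bcftools", "freebayes", "lofreq", "mutect2")

_VALID_CALLERS = CALLERS + ("other",)


class VcfParseError(ValueError):
    """A VCF record could not be interpreted (reports the line number)."""


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Identity of a biallelic SNV: (contig, 1-based pos, ref base, alt base)."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.contig}:{self.pos}")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(slots=True)
class VariantRecord:
    """One VCF data line from a single caller.

    As read from the file a record may still carry several ALT alleles;
    decomposition into per-allele records happens in ``ensemble_merge``.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    caller: str
    raw_filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"negative QUAL {self.qual} at {self.contig}:{self.pos}")

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def is_snv(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref in BASES
            and self.alts[0] in BASES
        )

    @property
    def key(self) -> VariantKey:
        if not self.is_snv:
            raise ValueError(
                f"record at {self.contig}:{self.pos} is not a normalized biallelic SNV"
            )
        return VariantKey(self.contig, self.pos, self.ref, self.alts[0])


@dataclass(slots=True)
class ReadObservation:
    """One primary, non-duplicate read overlapping a variant position.

    ``fragment_length`` is the absolute template length of the read's
    pair; reads with zero/undefined template length carry ``None`` and
    are excluded from the fragment-length median only.
    ``dist_from_end`` is the distance (bases, 0-based) from the variant
    to the nearer end of the aligned portion of the read.
    """

    base: str
    supports_alt: bool
    strand: str  # "forward" | "reverse"
    fragment_length: float | None
    mapq: float
    baseq: float
    dist_from_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward/reverse, got {self.strand!r}")
        if self.fragment_length is not None and self.fragment_length < 0:
            raise ValueError("fragment_length must be >= 0")
        if not 0 <= self.mapq <= 255:
            raise ValueError("mapq out of [0, 255]")
        if self.baseq < 0 or self.dist_from_end < 0:
            raise ValueError("baseq and dist_from_end must be >= 0")


@dataclass(slots=True)
class SiteEvidence:
    """All read observations at one variant site."""

    key: VariantKey
    observations: list[ReadObservation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(slots=True)
class ReferenceWindow:
    """Reference sequence around a variant (up to 20 bp each side, 41 total)."""

    sequence: str
    effective_length: int

    def __post_init__(self) -> None:
        if not 1 <= self.effective_length <= 41:
            raise ValueError("effective_length out of [1, 41]")
        if self.effective_length != len(self.sequence):
            raise ValueError("effective_length does not match sequence length")
        if set(self.sequence) - (BASES | {"N"}):
            raise ValueError("window may contain only A/C/G/T/N")


def read_caller_vcf(path: str | os.PathLike, caller: str) -> list[VariantRecord]:
    """Read one caller's VCF into raw :class:`VariantRecord` objects.

    Multiallelic lines are kept as single records (decomposition is the
    job of ``ensemble_merge.normalize_records``); missing QUAL (``.``)
    is preserved as ``None``.
    """
    if caller not in _VALID_CALLERS:
        raise ValueError(f"unknown caller {caller!r}; expected one of {_VALID_CALLERS}")
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf):
            try:
                alts = tuple(rec.alts or ())
                filters = tuple(rec.filter.keys())
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=alts,
                        qual=None if rec.qual is None else float(rec.qual),
                        caller=caller,
                        raw_filters=filters,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - re-raise with locus context
                raise VcfParseError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# site evidence


_EVIDENCE_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "base",
    "strand",
    "fragment_length",
    "mapq",
    "baseq",
    "dist_from_end",
    "supports_alt",
]


class EvidenceTable:
    """Tabular site evidence: one row per (variant, overlapping read).

    Accepted interchangeably with a BAM file so the whole pipeline can be
    exercised on plain-text fixtures.  Columns: contig, pos (1-based),
    ref, alt, base (read base at the site), strand (forward/reverse),
    fragment_length (bp; empty = unknown), mapq, baseq, dist_from_end,
    supports_alt (0/1).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _EVIDENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"evidence table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self._groups: dict | None = None

    # -- construction -------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
        df["supports_alt"] = df["supports_alt"].astype(bool)
        return cls(df)

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.df.copy()
        out["supports_alt"] = out["supports_alt"].astype(int)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    # -- lookup --------------------------------------------------------
    @property
    def groups(self) -> Mapping[tuple, np.ndarray]:
        """Row indices grouped by variant key tuple (cached)."""
        if self._groups is None:
            self._groups = self.df.groupby(
                ["contig", "pos", "ref", "alt"], sort=False
            ).indices
        return self._groups

    def site(self, key: VariantKey) -> SiteEvidence:
        idx = self.groups.get((key.contig, key.pos, key.ref, key.alt))
        ev = SiteEvidence(key=key)
        if idx is None:
            return ev
        sub = self.df.iloc[idx]
        for row in sub.itertuples(index=False):
            frag = None if pd.isna(row.fragment_length) else float(row.fragment_length)
            ev.observations.append(
                ReadObservation(
                    base=str(row.base),
                    supports_alt=bool(row.supports_alt),
                    strand=str(row.strand),
                    fragment_length=frag,
                    mapq=float(row.mapq),
                    baseq=float(row.baseq),
                    dist_from_end=int(row.dist_from_end),
                )
            )
        return ev

    def depth_af_table(self) -> pd.DataFrame:
        """Vectorized per-site (ref_count, alt_count, depth, af).

        Depth counts ref- plus alt-supporting reads only; other-base
        reads are excluded, matching the per-site feature definitions.
        """
        df = self.df
        is_alt = df["supports_alt"].to_numpy(bool)
        is_ref = (df["base"].to_numpy(str) == df["ref"].to_numpy(str)) & ~is_alt
        agg = (
            pd.DataFrame(
                {
                    "contig": df["contig"],
                    "pos": df["pos"],
                    "ref": df["ref"],
                    "alt": df["alt"],
                    "ref_count": is_ref.astype(np.int64),
                    "alt_count": is_alt.astype(np.int64),
                }
            )
            .groupby(["contig", "pos", "ref", "alt"], sort=False, as_index=False)
            .sum()
        )
        agg["depth"] = agg["ref_count"] + agg["alt_count"]
        depth = agg["depth"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(depth > 0, agg["alt_count"].to_numpy(float) / np.maximum(depth, 1), 0.0)
        agg["af"] = af
        return agg


def _bam_site_evidence(bam_path: str | os.PathLike, key: VariantKey) -> SiteEvidence:
    ev = SiteEvidence(key=key)
    with pysam.AlignmentFile(os.fspath(bam_path), "rb") as bam:
        if key.contig not in bam.references:
            raise KeyError(f"contig {key.contig!r} absent from {bam_path}")
        pos0 = key.pos - 1
        for read in bam.fetch(key.contig, pos0, pos0 + 1):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            qpos = None
            for q, r in read.get_aligned_pairs(matches_only=True):
                if r == pos0:
                    qpos = q
                    break
            if qpos is None:  # deleted / skipped at the variant position
                continue
            base = read.query_sequence[qpos].upper()
            tlen = abs(read.template_length)
            dist = min(
                qpos - read.query_alignment_start,
                read.query_alignment_end - 1 - qpos,
            )
            ev.observations.append(
                ReadObservation(
                    base=base,
                    supports_alt=base == key.alt,
                    strand="reverse" if read.is_reverse else "forward",
                    fragment_length=float(tlen) if tlen > 0 else None,
                    mapq=float(read.mapping_quality),
                    baseq=float(read.query_qualities[qpos]),
                    dist_from_end=max(int(dist), 0),
                )
            )
    return ev


def collect_site_evidence(
    source: "str | os.PathLike | EvidenceTable", key: VariantKey
) -> SiteEvidence:
    """Collect per-read evidence at ``key`` from a BAM file or evidence table.

    Only primary, mapped, non-duplicate reads contribute; a read deleted
    at the variant position has no base to observe and is excluded.
    """
    if isinstance(source, EvidenceTable):
        return source.site(key)
    path = os.fspath(source)
    if path.endswith((".bam", ".cram")):
        return _bam_site_evidence(path, key)
    table = EvidenceTable.read_tsv(path)
    if key.contig not in set(table.df["contig"].astype(str)):
        raise KeyError(f"contig {key.contig!r} absent from {path}")
    return table.site(key)


# ---------------------------------------------------------------------------
# reference windows


def fetch_reference_window(
    reference: "Mapping[str, str] | pysam.FastaFile | str | os.PathLike",
    key: VariantKey,
    flank: int = 20,
) -> ReferenceWindow:
    """Reference sequence in ``[pos - flank, pos + flank]``, clipped to the contig.

    ``reference`` may be a pysam ``FastaFile``, a FASTA path, or a plain
    mapping of contig name to sequence.
    """
    if isinstance(reference, (str, os.PathLike)):
        reference = pysam.FastaFile(os.fspath(reference))
    if isinstance(reference, pysam.FastaFile):
        if key.contig not in reference.references:
            raise KeyError(f"contig {key.contig!r} absent from reference")
        clen = reference.get_reference_length(key.contig)
        if key.pos > clen:
            raise IndexError(f"pos {key.pos} beyond end of {key.contig} ({clen} bp)")
        start0 = max(0, key.pos - 1 - flank)
        end0 = min(clen, key.pos + flank)
        seq = reference.fetch(key.contig, start0, end0)
    else:
        try:
            contig_seq = reference[key.contig]
        except KeyError:
            raise KeyError(f"contig {key.contig!r} absent from reference") from None
        clen = len(contig_seq)
        if key.pos > clen:
            raise IndexError(f"pos {key.pos} beyond end of {key.contig} ({clen} bp)")
        start0 = max(0, key.pos - 1 - flank)
        end0 = min(clen, key.pos + flank)
        seq = contig_seq[start0:end0]
    seq = seq.upper()
    return ReferenceWindow(sequence=seq, effective_length=len(seq))


# ---------------------------------------------------------------------------
# depth histogram (sequencing-depth profile)


def exome_depth_histogram(
    per_position_depths: Iterable[tuple[int, int]] | Iterator[tuple[int, int]],
) -> tuple[dict[int, int], int]:
    """Histogram of read depth over positions, plus the modal depth.

    Returns ``(counts, mode)`` where ``counts[d]`` is the number of
    positions at depth ``d``.  Ties in the mode resolve to the smallest
    depth.  An empty stream is an error.
    """
    counts: Counter[int] = Counter()
    n = 0
    for _pos, depth in per_position_depths:
        depth = int(depth)
        if depth < 0:
            raise ValueError(f"negative depth {depth}")
        counts[depth] += 1
        n += 1
    if n == 0:
        raise ValueError("empty depth stream")
    mode = min(d for d, c in counts.items() if c == max(counts.values()))
    return dict(counts), mode


def write_depth_histogram_tsv(
    counts: Mapping[int, int], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tpositions\n")
        for d in sorted(counts):
            fh.write(f"{d}\t{counts[d]}\n")


def plot_depth_histogram(
    counts: Mapping[int, int], path: str | os.PathLike, title: str = "Read depth profile"
) -> None:
    """Bar plot of the per-position depth histogram (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depths = sorted(counts)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(depths, [counts[d] for d in depths], width=1.0, color="#4878b0")
    ax.set_xlabel("Read depth")
    ax.set_ylabel("Exome positions")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
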