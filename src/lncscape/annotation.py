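"""Transcript models and GTF/GFF3 input/output.

Internal coordinates are 0-based half-open (BED-like) on every interval;
GTF/GFF3 files are 1-based inclusive and are converted at the file boundary
only.  Strand is one of ``+``, ``-`` or ``.`` (unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils

__all__ = [
    "AnnotationError",
    "GenomicInterval",
    "TranscriptModel",
    "TranscriptomeAnnotation",
    "read_annotation",
    "write_annotation",
    "write_bed6",
    "transcript_coord_to_genomic",
    "genomic_coord_to_transcript",
]

STRANDS = ("+", "-", ".")

#: biotype attribute values mapped onto the internal three-way biotype
_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "mrna": "protein_coding",
    "lncrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "antisense_rna": "lncRNA",
    "antisense": "lncRNA",
    "lincrna": "lncRNA",
}

_TRANSCRIPT_FEATURES = {
    "transcript",
    "mRNA",
    "lnc_RNA",
    "lncRNA",
    "ncRNA",
    "antisense_RNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "miRNA",
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript, optionally with a CDS span.

    ``exons`` are non-overlapping, ascending by start, all on ``chrom`` /
    ``strand``; ``cds`` (protein-coding only) spans first to last coding
    base in genomic coordinates.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "other"
    cds: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise AnnotationError(
                    f"{self.transcript_id}: exon on {ex.chrom}, transcript on {self.chrom}"
                )
            if prev_end is not None and ex.start <= prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons unsorted or separated by <1 nt"
                )
            prev_end = ex.end
        if self.cds is not None:
            span = self.span
            if not (span.start <= self.cds.start and self.cds.end <= span.end):
                raise AnnotationError(f"{self.transcript_id}: CDS outside transcript span")
            if not any(
                ex.start < self.cds.end and self.cds.start < ex.end for ex in self.exons
            ):
                raise AnnotationError(f"{self.transcript_id}: CDS overlaps no exon")

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths)."""
        return sum(ex.length for ex in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Ordered (intron start, intron end) pairs; empty iff single-exon."""
        return tuple(
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.junctions
        )

    def utr_cds_utr_lengths(self) -> tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths in transcript coordinates.

        Requires a CDS; UTRs are derived as exonic-minus-CDS, never read
        from UTR features.
        """
        if self.cds is None:
            raise AnnotationError(f"{self.transcript_id}: no CDS")
        cds_len = sum(
            max(0, min(ex.end, self.cds.end) - max(ex.start, self.cds.start))
            for ex in self.exons
        )
        # exonic bases genomically left of the CDS
        left = sum(
            max(0, min(ex.end, self.cds.start) - ex.start) for ex in self.exons
        )
        right = self.length - cds_len - left
        if self.strand == "-":
            left, right = right, left
        return left, cds_len, right


def transcript_coord_to_genomic(t: TranscriptModel, pos: int) -> int:
    """Map a 0-based transcript position to its genomic position.

    Walks the exon chain 5'→3'; on the minus strand transcript position 0
    is the genomically last exon base.
    """
    if not (0 <= pos < t.length):
        raise ValueError(f"position {pos} out of range for {t.transcript_id}")
    if t.strand == "-":
        remaining = pos
        for ex in reversed(t.exons):
            if remaining < ex.length:
                return ex.end - 1 - remaining
            remaining -= ex.length
    else:
        remaining = pos
        for ex in t.exons:
            if remaining < ex.length:
                return ex.start + remaining
            remaining -= ex.length
    raise AssertionError("unreachable")


def genomic_coord_to_transcript(t: TranscriptModel, gpos: int) -> int:
    """Inverse of :func:`transcript_coord_to_genomic` (exonic bases only)."""
    offset = 0
    if t.strand == "-":
        for ex in reversed(t.exons):
            if ex.start <= gpos < ex.end:
                return offset + (ex.end - 1 - gpos)
            offset += ex.length
    else:
        for ex in t.exons:
            if ex.start <= gpos < ex.end:
                return offset + (gpos - ex.start)
            offset += ex.length
    raise ValueError(f"genomic position {gpos} is not exonic in {t.transcript_id}")


@dataclass
class TranscriptomeAnnotation:
    """A collection of transcripts keyed by id, with a gene index."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    source: str = "assembly"  # "reference" | "assembly"

    def __post_init__(self) -> None:
        self.genes: dict[str, list[str]] = {}
        for tid, t in self.transcripts.items():
            if tid != t.transcript_id:
                raise AnnotationError(f"key {tid} != transcript_id {t.transcript_id}")
            self.genes.setdefault(t.gene_id, []).append(tid)

    @classmethod
    def from_transcripts(
        cls, transcripts: Iterable[TranscriptModel], source: str = "assembly"
    ) -> "TranscriptomeAnnotation":
        d: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in d:
                raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
            d[t.transcript_id] = t
        return cls(d, source=source)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def subset(self, tids: Iterable[str], source: Optional[str] = None) -> "TranscriptomeAnnotation":
        return TranscriptomeAnnotation(
            {tid: self.transcripts[tid] for tid in tids},
            source=source or self.source,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: str | Path) -> str:
    s = str(path).lower()
    if s.endswith((".gff", ".gff3")):
        return "GFF3"
    return "GTF"


def _norm_biotype(value: str) -> str:
    return _BIOTYPE_MAP.get(value.lower(), "other")


def read_annotation(
    path: str | Path, dialect: Optional[str] = None, source: str = "assembly"
) -> TranscriptomeAnnotation:
    """Read a GTF or GFF3 file into a :class:`TranscriptomeAnnotation`.

    Exon and CDS features are grouped by transcript; 1-based inclusive file
    coordinates become 0-based half-open.  Biotype comes from an explicit
    ``transcript_biotype`` / ``gene_biotype`` / ``biotype`` attribute when
    present, else from the presence of CDS features, else ``other``.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect not in ("GTF", "GFF3"):
        raise ValueError(f"unknown dialect {dialect!r}")

    exons: dict[str, list[GenomicInterval]] = {}
    cds_bounds: dict[str, list[int]] = {}
    meta: dict[str, dict] = {}  # tid -> chrom/strand/gene_id/biotype_attr

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 fields, got {len(fields)}")
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # pragma: no cover - gffutils message varies
                raise AnnotationError(f"{path}:{lineno}: parse error: {exc}") from exc
            ftype = feat.featuretype
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise AnnotationError(f"{path}:{lineno}: end < start")
            strand = feat.strand if feat.strand in ("+", "-") else "."

            attrs = feat.attributes

            def attr(*names: str) -> Optional[str]:
                for n in names:
                    if n in attrs and attrs[n]:
                        v = attrs[n][0]
                        # Ensembl GFF3 id prefixes (transcript:..., gene:...)
                        for pre in ("transcript:", "gene:"):
                            if v.startswith(pre):
                                v = v[len(pre):]
                        return v
                return None

            if ftype in _TRANSCRIPT_FEATURES:
                tid = attr("transcript_id", "ID")
                if tid is None:
                    continue
                m = meta.setdefault(tid, {})
                m.setdefault("chrom", feat.seqid)
                m.setdefault("strand", strand)
                gid = attr("gene_id", "Parent")
                if gid is not None:
                    m.setdefault("gene_id", gid)
                bt = attr("transcript_biotype", "gene_biotype", "biotype")
                if bt is not None:
                    m.setdefault("biotype_attr", bt)
                if ftype in ("mRNA",):
                    m.setdefault("biotype_attr", "protein_coding")
                elif ftype in ("lnc_RNA", "lncRNA", "antisense_RNA"):
                    m.setdefault("biotype_attr", "lncRNA")
                continue
            if ftype not in ("exon", "CDS"):
                continue

            tid = attr("transcript_id", "Parent")
            if tid is None:
                raise AnnotationError(
                    f"{path}:{lineno}: {ftype} feature without transcript attribute"
                )
            m = meta.setdefault(tid, {})
            if "chrom" in m and m["chrom"] != feat.seqid:
                raise AnnotationError(f"{path}:{lineno}: {tid} spans multiple chromosomes")
            if "strand" in m and m["strand"] != strand and strand != "." and m["strand"] != ".":
                raise AnnotationError(f"{path}:{lineno}: {tid} spans multiple strands")
            m.setdefault("chrom", feat.seqid)
            if m.get("strand", ".") == ".":
                m["strand"] = strand
            gid = attr("gene_id")
            if gid is not None:
                m.setdefault("gene_id", gid)
            bt = attr("transcript_biotype", "gene_biotype", "biotype")
            if bt is not None:
                m.setdefault("biotype_attr", bt)

            if ftype == "exon":
                exons.setdefault(tid, []).append(
                    GenomicInterval(feat.seqid, start1 - 1, end1, strand if strand in "+-" else ".")
                )
            else:
                cds_bounds.setdefault(tid, []).extend((start1 - 1, end1))

    transcripts: dict[str, TranscriptModel] = {}
    for tid, exon_list in exons.items():
        m = meta[tid]
        chrom = m["chrom"]
        strand = m.get("strand", ".")
        exon_list.sort(key=lambda iv: iv.start)
        cds = None
        if tid in cds_bounds:
            b = cds_bounds[tid]
            cds = GenomicInterval(chrom, min(b), max(b), strand)
        if "biotype_attr" in m:
            biotype = _norm_biotype(m["biotype_attr"])
        elif cds is not None:
            biotype = "protein_coding"
        else:
            biotype = "other"
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=m.get("gene_id", tid),
            chrom=chrom,
            strand=strand,
            exons=tuple(
                GenomicInterval(chrom, iv.start, iv.end, strand) for iv in exon_list
            ),
            biotype=biotype,
            cds=cds,
        )
    return TranscriptomeAnnotation(transcripts, source=source)


_GTF_BIOTYPE = {"protein_coding": "protein_coding", "lncRNA": "lncRNA", "other": "other"}


def write_annotation(
    annotation: TranscriptomeAnnotation, path: str | Path, dialect: Optional[str] = None
) -> None:
    """Write an annotation as GTF or GFF3, deterministically sorted.

    Transcripts are ordered by (chrom, span start, transcript_id) so that
    output is byte-stable for a given annotation.
    """
    dialect = dialect or _infer_dialect(path)
    order = sorted(
        annotation, key=lambda t: (t.chrom, t.span.start, t.transcript_id)
    )
    lines: list[str] = ["##gff-version 3"] if dialect == "GFF3" else ["#!lncscape annotation"]
    for t in order:
        strand = t.strand if t.strand in "+-" else "."
        span = t.span
        if dialect == "GTF":
            attr_t = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            lines.append(
                "\t".join(
                    [t.chrom, "lncscape", "transcript", str(span.start + 1), str(span.end),
                     ".", strand, ".", attr_t]
                )
            )
            for ex in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, "lncscape", "exon", str(ex.start + 1), str(ex.end),
                         ".", strand, ".", attr_t]
                    )
                )
            if t.cds is not None:
                for ex in t.exons:
                    s = max(ex.start, t.cds.start)
                    e = min(ex.end, t.cds.end)
                    if s < e:
                        lines.append(
                            "\t".join(
                                [t.chrom, "lncscape", "CDS", str(s + 1), str(e),
                                 ".", strand, ".", attr_t]
                            )
                        )
        else:
            lines.append(
                "\t".join(
                    [t.chrom, "lncscape", "transcript", str(span.start + 1), str(span.end),
                     ".", strand, ".",
                     f"ID={t.transcript_id};Parent={t.gene_id};biotype={t.biotype}"]
                )
            )
            for ex in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, "lncscape", "exon", str(ex.start + 1), str(ex.end),
                         ".", strand, ".", f"Parent={t.transcript_id}"]
                    )
                )
            if t.cds is not None:
                for ex in t.exons:
                    s = max(ex.start, t.cds.start)
                    e = min(ex.end, t.cds.end)
                    if s < e:
                        lines.append(
                            "\t".join(
                                [t.chrom, "lncscape", "CDS", str(s + 1), str(e),
                                 ".", strand, ".", f"Parent={t.transcript_id}"]
                            )
                        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed6(annotation: TranscriptomeAnnotation, path: str | Path) -> None:
    """Export transcript spans as BED6 for quick inspection."""
    order = sorted(annotation, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in order:
            span = t.span
            strand = t.strand if t.strand in "+-" else "."
            fh.write(
                f"{t.chrom}\t{span.start}\t{span.end}\t{t.transcript_id}\t0\t{strand}\n"
            )
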