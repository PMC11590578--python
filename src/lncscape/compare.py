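"""Strand-aware classification of assembled transcripts against a reference.

Each query transcript receives one class code describing its structural
relationship to the reference annotation, in the gffcompare tradition:

=====  =========================================================
``=``  identical junction chain on the same strand (single-exon:
       mutual exonic overlap, both unspliced)
``i``  query contained within a single intron, same strand
``y``  a reference contained within an intron of the query
``o``  same-strand exonic overlap (``j_like`` when a junction is
       shared) without being ``=``
``x``  opposite-strand exonic overlap
``s``  query contained within an intron of an opposite-strand
       reference
``p``  no overlap but within a run-on distance, same strand
``u``  intergenic
=====  =========================================================

Codes are resolved by the fixed precedence
``= > i > y > o > x > s > p > u``; ``.`` marks queries whose strand is
unknown and which therefore cannot be classified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .annotation import TranscriptModel, TranscriptomeAnnotation

__all__ = [
    "UNCLASSIFIABLE",
    "ClassCodeAssignment",
    "JunctionIndex",
    "build_junction_index",
    "shares_junction_with",
    "assign_class_code",
    "identify_novel",
    "summarize_codes",
    "write_assignments",
]

#: code returned for queries with unknown strand
UNCLASSIFIABLE = "."

#: resolution order when several reference transcripts match different rules
_PRECEDENCE = {"=": 0, "i": 1, "y": 2, "o": 3, "x": 4, "s": 5, "p": 6, "u": 7}

DEFAULT_RUN_ON_DISTANCE = 2000


@dataclass(frozen=True)
class ClassCodeAssignment:
    """One query's relationship to the reference annotation."""

    query_id: str
    code: str
    best_reference_id: Optional[str] = None
    j_like: bool = False
    evidence: str = ""


@dataclass(frozen=True)
class JunctionIndex:
    """Exact-membership set of (chrom, intron start, intron end, strand)."""

    junctions: frozenset[tuple[str, int, int, str]]

    def __len__(self) -> int:
        return len(self.junctions)

    def __contains__(self, junction: tuple[str, int, int, str]) -> bool:
        return junction in self.junctions


def build_junction_index(
    transcripts: Iterable[TranscriptModel], biotype_filter: Optional[str] = None
) -> JunctionIndex:
    """Collect the splice junctions of all transcripts passing the filter."""
    out: set[tuple[str, int, int, str]] = set()
    for t in transcripts:
        if biotype_filter is not None and t.biotype != biotype_filter:
            continue
        for s, e in t.junctions:
            out.add((t.chrom, s, e, t.strand))
    return JunctionIndex(frozenset(out))


def shares_junction_with(query: TranscriptModel, index: JunctionIndex) -> bool:
    """True iff at least one query junction is in the index (exact match)."""
    return any((query.chrom, s, e, query.strand) in index for s, e in query.junctions)


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def _contained_in_intron(inner: TranscriptModel, outer: TranscriptModel) -> bool:
    """Whole span of ``inner`` inside a single intron of ``outer``."""
    span = inner.span
    return any(s <= span.start and span.end <= e for s, e in outer.junctions)


def _code_against(
    query: TranscriptModel, ref: TranscriptModel, run_on_distance: int
) -> Optional[tuple[str, bool, int, str]]:
    """(code, j_like, score, evidence) of query vs one reference, or None."""
    if query.chrom != ref.chrom:
        return None
    qspan, rspan = query.span, ref.span
    span_overlap = qspan.start < rspan.end and rspan.start < qspan.end
    gap = max(rspan.start - qspan.end, qspan.start - rspan.end, 0)
    if not span_overlap and gap > run_on_distance:
        return None

    same_strand = query.strand == ref.strand
    exonic = _exonic_overlap(query, ref)

    if same_strand:
        qj, rj = query.junctions, ref.junctions
        if qj and qj == rj:
            return ("=", False, exonic, "identical junction chain")
        if not qj and not rj and exonic >= 1:
            return ("=", False, exonic, f"single-exon mutual overlap {exonic} nt")
        if _contained_in_intron(query, ref):
            return ("i", False, 0, "contained in same-strand intron")
        if _contained_in_intron(ref, query):
            return ("y", False, 0, "reference contained in query intron")
        if exonic >= 1:
            shared = bool(set(qj) & set(rj))
            return ("o", shared, exonic, f"same-strand exonic overlap {exonic} nt")
        if not span_overlap and gap <= run_on_distance:
            # score favours the nearest reference
            return ("p", False, -gap, f"run-on at {gap} nt")
    else:
        if exonic >= 1:
            return ("x", False, exonic, f"opposite-strand exonic overlap {exonic} nt")
        if _contained_in_intron(query, ref):
            return ("s", False, 0, "contained in opposite-strand intron")
    return None


class _ReferenceIndex:
    """chrom → interval tree of reference spans, padded by run_on_distance."""

    def __init__(self, reference: TranscriptomeAnnotation, pad: int) -> None:
        self.trees: dict[str, IntervalTree] = {}
        self.pad = pad
        for t in reference:
            span = t.span
            self.trees.setdefault(t.chrom, IntervalTree()).addi(
                max(0, span.start - pad), span.end + pad, t
            )

    def candidates(self, query: TranscriptModel) -> list[TranscriptModel]:
        tree = self.trees.get(query.chrom)
        if tree is None:
            return []
        span = query.span
        return [iv.data for iv in tree.overlap(span.start, span.end)]


def assign_class_code(
    query: TranscriptModel,
    reference: TranscriptomeAnnotation,
    run_on_distance: int = DEFAULT_RUN_ON_DISTANCE,
    _index: Optional[_ReferenceIndex] = None,
) -> ClassCodeAssignment:
    """Assign the single class code of ``query`` against the reference.

    Candidate codes are computed against every reference transcript whose
    padded span overlaps the query, then resolved by precedence; ties
    within a code prefer larger exonic overlap, then the lexicographically
    smallest reference id, making the result independent of reference
    order.
    """
    if query.strand not in ("+", "-"):
        return ClassCodeAssignment(
            query.transcript_id, UNCLASSIFIABLE, None, False, "unknown strand"
        )
    candidates = (
        _index.candidates(query)
        if _index is not None
        else [
            r
            for r in reference
            if r.chrom == query.chrom
        ]
    )
    best: Optional[tuple[int, int, str, str, bool, str]] = None
    for ref in candidates:
        if ref.strand not in ("+", "-"):
            continue  # strand-unknown references are excluded from strand logic
        res = _code_against(query, ref, run_on_distance)
        if res is None:
            continue
        code, j_like, score, evidence = res
        key = (_PRECEDENCE[code], -score, ref.transcript_id)
        if best is None or key < (best[0], best[1], best[2]):
            best = (key[0], key[1], key[2], code, j_like, evidence)
    if best is None:
        return ClassCodeAssignment(query.transcript_id, "u", None, False, "intergenic")
    _, _, ref_id, code, j_like, evidence = best
    return ClassCodeAssignment(query.transcript_id, code, ref_id, j_like, evidence)


def identify_novel(
    assembly: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    run_on_distance: int = DEFAULT_RUN_ON_DISTANCE,
) -> list[ClassCodeAssignment]:
    """Assignments for every assembly transcript whose code is not ``=``.

    Transcripts with code ``=`` are annotated transcripts and are dropped;
    everything else (including unclassifiable queries) is returned.
    """
    return [
        a
        for a in classify_all(assembly, reference, run_on_distance)
        if a.code != "="
    ]


def classify_all(
    assembly: TranscriptomeAnnotation,
    reference: TranscriptomeAnnotation,
    run_on_distance: int = DEFAULT_RUN_ON_DISTANCE,
) -> list[ClassCodeAssignment]:
    """Class codes for every assembly transcript, in id order."""
    index = _ReferenceIndex(reference, run_on_distance)
    return [
        assign_class_code(q, reference, run_on_distance, _index=index)
        for q in sorted(assembly, key=lambda t: t.transcript_id)
    ]


def summarize_codes(assignments: Iterable[ClassCodeAssignment]) -> Counter:
    """Counts per class code (tracking-style summary)."""
    return Counter(a.code for a in assignments)


def write_assignments(
    assignments: Iterable[ClassCodeAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tclass_code\tbest_reference_id\tj_like\tevidence\n")
        for a in assignments:
            fh.write(
                f"{a.query_id}\t{a.code}\t{a.best_reference_id or ''}\t"
                f"{int(a.j_like)}\t{a.evidence}\n"
            )
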