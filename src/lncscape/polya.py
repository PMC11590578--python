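"""Poly(A) tail aggregation and poly(A)/non-poly(A) classification.

Per-read tail estimates (Nanopolish polya style) are averaged to
transcripts over QC-passing reads.  A transcript with NGS expression
support (TPM > 0.1 in at least two samples) is non-poly(A) when zero
QC-passing DRS reads aligned to it — detectable in rRNA-depleted NGS but
invisible to poly(A)-selected DRS — and poly(A) when at least one did.
Transcripts without NGS support are undetermined.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolyARead",
    "PolyAStatus",
    "read_polya_table",
    "transcript_tail_length",
    "tail_length_table",
    "classify_polyadenylation",
    "classify_all",
    "polya_summary",
]

DEFAULT_TPM_THRESHOLD = 0.1
DEFAULT_MIN_SAMPLES = 2


@dataclass(frozen=True)
class PolyARead:
    """One read's estimated poly(A) tail length with QC status."""

    read_id: str
    transcript_id: str
    tail_length: float
    qc_pass: bool
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.tail_length < 0:
            raise ValueError(f"{self.read_id}: negative tail length")


@dataclass(frozen=True)
class PolyAStatus:
    transcript_id: str
    status: str  # "polyA" | "non_polyA" | "undetermined"
    mean_tail_length: Optional[float]
    n_reads: int


def read_polya_table(path: str | Path, library_id: str = "") -> list[PolyARead]:
    """Read a Nanopolish-polya-style TSV.

    Columns: readname, contig (transcript), polya_length, qc_tag; the read
    passes QC iff qc_tag == "PASS".
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PolyARead(
            read_id=str(row.readname),
            transcript_id=str(row.contig),
            tail_length=float(row.polya_length),
            qc_pass=str(row.qc_tag) == "PASS",
            library_id=library_id,
        )
        for row in df.itertuples(index=False)
    ]


def transcript_tail_length(reads: Sequence[PolyARead]) -> Optional[float]:
    """Mean tail length over QC-passing reads, pooled across libraries.

    Returns None when no read passes QC (no record, never 0).
    """
    tails = [r.tail_length for r in reads if r.qc_pass]
    if not tails:
        return None
    return float(np.mean(tails))


def tail_length_table(reads: Iterable[PolyARead]) -> pd.DataFrame:
    """Per-transcript mean tail length and QC-passing read count."""
    by_tid: dict[str, list[PolyARead]] = defaultdict(list)
    for r in reads:
        by_tid[r.transcript_id].append(r)
    rows = []
    for tid, group in sorted(by_tid.items()):
        mean = transcript_tail_length(group)
        n_pass = sum(r.qc_pass for r in group)
        if mean is not None:
            rows.append((tid, round(mean, 2), n_pass))
    return pd.DataFrame(rows, columns=["transcript_id", "mean_tail_length", "n_reads"])


def classify_polyadenylation(
    transcript_id: str,
    ngs_tpm: Sequence[float],
    drs_read_count: int,
    mean_tail_length: Optional[float] = None,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> PolyAStatus:
    """Classify one transcript as polyA / non_polyA / undetermined.

    NGS support means TPM strictly above ``tpm_threshold`` in at least
    ``min_samples`` samples.  With support: zero QC-passing DRS reads →
    non_polyA, otherwise polyA.  Without support the transcript is
    undetermined regardless of DRS evidence.
    """
    supported = sum(v > tpm_threshold for v in ngs_tpm) >= min_samples
    if supported and drs_read_count == 0:
        status = "non_polyA"
    elif supported and drs_read_count >= 1:
        status = "polyA"
    else:
        status = "undetermined"
    return PolyAStatus(
        transcript_id,
        status,
        mean_tail_length if status == "polyA" else None,
        drs_read_count,
    )


def classify_all(
    tpm_matrix: pd.DataFrame,
    drs_reads: Iterable[PolyARead],
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> list[PolyAStatus]:
    """Classify every transcript in the TPM matrix (transcripts x samples)."""
    by_tid: dict[str, list[PolyARead]] = defaultdict(list)
    for r in drs_reads:
        by_tid[r.transcript_id].append(r)
    out = []
    for tid in tpm_matrix.index:
        group = by_tid.get(tid, [])
        n_pass = sum(r.qc_pass for r in group)
        out.append(
            classify_polyadenylation(
                tid,
                tpm_matrix.loc[tid].to_numpy(float),
                n_pass,
                transcript_tail_length(group),
                tpm_threshold,
                min_samples,
            )
        )
    return out


def polya_summary(
    statuses: Iterable[PolyAStatus],
    categories: Optional[Mapping[str, str]] = None,
) -> dict:
    """Counts and proportions per status, plus per-category median tails.

    Proportions are percentages over the classified transcripts
    (polyA + non_polyA); when everything is undetermined no proportions
    are emitted.  ``categories`` optionally maps transcript ids to lncRNA
    categories for per-category tail medians.
    """
    statuses = list(statuses)
    counts = {
        "polyA": sum(s.status == "polyA" for s in statuses),
        "non_polyA": sum(s.status == "non_polyA" for s in statuses),
        "undetermined": sum(s.status == "undetermined" for s in statuses),
    }
    classified = counts["polyA"] + counts["non_polyA"]
    out: dict = {"counts": counts}
    if classified:
        out["proportions"] = {
            "polyA": 100.0 * counts["polyA"] / classified,
            "non_polyA": 100.0 * counts["non_polyA"] / classified,
        }
    tails = [
        s.mean_tail_length for s in statuses if s.mean_tail_length is not None
    ]
    if tails:
        out["median_tail_length"] = round(float(np.median(tails)), 2)
    if categories is not None:
        by_cat: dict[str, list[float]] = defaultdict(list)
        for s in statuses:
            if s.mean_tail_length is not None and s.transcript_id in categories:
                by_cat[categories[s.transcript_id]].append(s.mean_tail_length)
        out["median_tail_by_category"] = {
            c: round(float(np.median(v)), 2) for c, v in sorted(by_cat.items())
        }
    return out


def write_status_table(statuses: Iterable[PolyAStatus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstatus\tmean_tail_length\tn_reads\n")
        for s in statuses:
            tail = "" if s.mean_tail_length is None else f"{s.mean_tail_length:.2f}"
            fh.write(f"{s.transcript_id}\t{s.status}\t{tail}\t{s.n_reads}\n")
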