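"""Curating novel lncRNAs and categorizing lncRNAs by class code.

A novel transcript is accepted as a lncRNA when it exceeds a minimum
length (default 200 nt), has a coding probability below a cutoff
(default 0.325, or one trained from labelled scores via a two-graph ROC),
carries a non-coding label from a second predictor, and shares no splice
junction with any protein-coding transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .compare import ClassCodeAssignment, JunctionIndex, shares_junction_with

__all__ = [
    "CATEGORY_BY_CODE",
    "DEFAULT_CPAT_CUTOFF",
    "DEFAULT_MIN_LENGTH",
    "CodingEvidence",
    "TgrocResult",
    "tgroc_cutoff",
    "is_novel_lncrna",
    "filter_novel_lncrnas",
    "categorize_lncrnas",
    "CategoryReport",
    "read_coding_evidence",
]

DEFAULT_CPAT_CUTOFF = 0.325
DEFAULT_MIN_LENGTH = 200

#: class code → lncRNA category; anything else is "unclassified"
CATEGORY_BY_CODE = {
    "s": "antisense",
    "x": "antisense",
    "p": "intergenic",
    "u": "intergenic",
    "i": "intronic",
    "y": "overlapping",
    "o": "overlapping",
}

CATEGORIES = ("antisense", "intergenic", "intronic", "overlapping")


@dataclass(frozen=True)
class CodingEvidence:
    """Coding-potential evidence for one transcript from two predictors."""

    transcript_id: str
    cpat_probability: float
    cpc2_label: str  # "coding" | "noncoding"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cpat_probability <= 1.0):
            raise ValueError(
                f"{self.transcript_id}: coding probability outside [0, 1]"
            )
        if self.cpc2_label not in ("coding", "noncoding"):
            raise ValueError(f"{self.transcript_id}: bad label {self.cpc2_label!r}")


@dataclass(frozen=True)
class TgrocResult:
    cutoff: float
    sensitivity: float
    specificity: float


def tgroc_cutoff(
    scores: Sequence[float],
    truths: Sequence[str],
    mode: str = "intersection",
) -> TgrocResult:
    """Train a coding-probability cutoff from labelled scores (TG-ROC).

    Sensitivity(t) is the fraction of coding examples with score >= t and
    specificity(t) the fraction of non-coding examples with score < t,
    swept over the observed score values plus 0 and 1.  The default
    ``intersection`` mode returns the smallest threshold minimizing
    |sensitivity - specificity|; ``max_mean`` maximizes their mean.

    Scores must follow the higher-is-more-coding orientation; inputs where
    the coding class does not score higher on average are rejected.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths)
    if scores.ndim != 1 or scores.shape != truths.shape:
        raise ValueError("scores and truths must be 1-D and aligned")
    coding = scores[truths == "coding"]
    noncoding = scores[truths == "noncoding"]
    if len(coding) == 0 or len(noncoding) == 0:
        raise ValueError("both classes must be present to train a cutoff")
    if len(np.unique(scores)) < 2:
        raise ValueError("need at least 2 distinct scores")
    if coding.mean() < noncoding.mean():
        raise ValueError(
            "coding scores do not exceed non-coding scores on average; "
            "scores appear to be flipped"
        )
    if mode not in ("intersection", "max_mean"):
        raise ValueError(f"unknown mode {mode!r}")

    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    sens = np.array([(coding >= t).mean() for t in candidates])
    spec = np.array([(noncoding < t).mean() for t in candidates])
    if mode == "intersection":
        objective = np.abs(sens - spec)
        best = int(np.flatnonzero(objective == objective.min())[0])
    else:
        objective = (sens + spec) / 2.0
        best = int(np.flatnonzero(objective == objective.max())[0])
    return TgrocResult(float(candidates[best]), float(sens[best]), float(spec[best]))


def is_novel_lncrna(
    t: TranscriptModel,
    ev: CodingEvidence,
    coding_junctions: JunctionIndex,
    cutoff: float = DEFAULT_CPAT_CUTOFF,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[bool, str]:
    """Apply the length / coding-probability / label / junction filter.

    Returns (accepted, reason); on rejection the reason names the first
    failed criterion, in the order length, cpat, cpc2, junction.
    """
    if ev.transcript_id != t.transcript_id:
        raise ValueError(
            f"evidence for {ev.transcript_id} applied to {t.transcript_id}"
        )
    if not t.length > min_length:
        return False, "length"
    if not ev.cpat_probability < cutoff:
        return False, "cpat"
    if ev.cpc2_label != "noncoding":
        return False, "cpc2"
    if shares_junction_with(t, coding_junctions):
        return False, "junction"
    return True, "pass"


def filter_novel_lncrnas(
    transcripts: Iterable[TranscriptModel],
    evidence: Mapping[str, CodingEvidence],
    coding_junctions: JunctionIndex,
    cutoff: float = DEFAULT_CPAT_CUTOFF,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Run the lncRNA filter over many transcripts.

    Returns a DataFrame (transcript_id, accepted, reason); missing
    evidence raises, naming the transcript.
    """
    rows = []
    for t in transcripts:
        if t.transcript_id not in evidence:
            raise KeyError(f"no coding evidence for transcript {t.transcript_id}")
        ok, reason = is_novel_lncrna(
            t, evidence[t.transcript_id], coding_junctions, cutoff, min_length
        )
        rows.append((t.transcript_id, ok, reason))
    return pd.DataFrame(rows, columns=["transcript_id", "accepted", "reason"])


@dataclass
class CategoryReport:
    """Per-transcript categories with counts and proportions.

    Proportions are percentages over the classified subset only;
    unclassified transcripts are counted separately.
    """

    category_by_id: dict[str, str]
    counts: Counter
    n_unclassified: int

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        total = self.n_classified
        if total == 0:
            return {}
        return {c: 100.0 * self.counts[c] / total for c in CATEGORIES if self.counts[c]}


def categorize_lncrnas(
    assignments: Iterable[ClassCodeAssignment | tuple[str, str]],
) -> CategoryReport:
    """Map class codes to lncRNA categories and tally proportions.

    Accepts assignments or bare (transcript_id, code) pairs.  Codes with
    no category mapping (``=``, unknown-strand ``.``) become
    "unclassified" and are excluded from the proportion denominator.
    """
    category_by_id: dict[str, str] = {}
    counts: Counter = Counter()
    n_unclassified = 0
    for a in assignments:
        if isinstance(a, tuple):
            tid, code = a
        else:
            tid, code = a.query_id, a.code
        category = CATEGORY_BY_CODE.get(code)
        if category is None:
            category_by_id[tid] = "unclassified"
            n_unclassified += 1
        else:
            category_by_id[tid] = category
            counts[category] += 1
    return CategoryReport(category_by_id, counts, n_unclassified)


def read_coding_evidence(path: str | Path) -> dict[str, CodingEvidence]:
    """Read a TSV of (transcript_id, cpat_prob, cpc2_label)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        ev = CodingEvidence(
            str(row.transcript_id), float(row.cpat_prob), str(row.cpc2_label)
        )
        out[ev.transcript_id] = ev
    return out


def read_labeled_scores(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV of (score, truth) used for cutoff training."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df["score"].to_numpy(float), df["truth"].to_numpy(str)
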