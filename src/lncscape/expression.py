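"""Expression normalization, stage dynamics and supporting statistics.

Counts are normalized to counts per million (CPM) over the full
quantified transcript universe of each sample.  The stage
differential-expression statistic for a transcript is

    d = log2( (mean CPM, floral bud + 0.1) / (mean CPM, seedling + 0.1) )

with 0.1 a pseudo-CPM; d > 0.7 calls the transcript up-regulated in the
floral bud and d < -0.7 down-regulated.  A transcript is moderately
expressed in a sample when its CPM strictly exceeds 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_PSEUDO_CPM",
    "DEFAULT_CPM_THRESHOLD",
    "DEFAULT_UP_CUT",
    "DEFAULT_DOWN_CUT",
    "cpm_normalize",
    "moderately_expressed",
    "differential_expression",
    "stage_sets",
    "StageSets",
    "mann_whitney",
    "spearman",
    "linear_fit",
    "correlate_expression_methylation",
]

DEFAULT_PSEUDO_CPM = 0.1
DEFAULT_CPM_THRESHOLD = 0.1
DEFAULT_UP_CUT = 0.7
DEFAULT_DOWN_CUT = -0.7


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization, per sample (column).

    The denominator is the column sum over all quantified transcripts;
    zero-library-size columns are an error naming the sample.
    """
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    return counts * 1e6 / sums


def moderately_expressed(
    cpm: pd.DataFrame,
    sample_meta: Mapping[str, str],
    threshold: float = DEFAULT_CPM_THRESHOLD,
) -> dict[str, set[str]]:
    """Expressed-transcript sets per stage, plus the all-samples set.

    ``sample_meta`` maps sample id → stage.  A transcript is in a stage's
    set when its CPM strictly exceeds the threshold in at least one sample
    of that stage; key "all_samples" holds transcripts above threshold in
    every sample of the matrix.
    """
    missing = [c for c in cpm.columns if c not in sample_meta]
    if missing:
        raise KeyError(f"samples missing stage metadata: {missing}")
    expressed = cpm > threshold
    out: dict[str, set[str]] = {}
    for stage in sorted(set(sample_meta[c] for c in cpm.columns)):
        cols = [c for c in cpm.columns if sample_meta[c] == stage]
        out[stage] = set(cpm.index[expressed[cols].any(axis=1)])
    out["all_samples"] = set(cpm.index[expressed.all(axis=1)])
    return out


def differential_expression(
    cpm: pd.DataFrame,
    sample_meta: Mapping[str, str],
    universe: Optional[Iterable[str]] = None,
    pseudo: float = DEFAULT_PSEUDO_CPM,
    up_cut: float = DEFAULT_UP_CUT,
    down_cut: float = DEFAULT_DOWN_CUT,
) -> pd.DataFrame:
    """Stage fold-change statistic d with up/down/unchanged calls.

    ``universe`` restricts the computation (default: transcripts above
    the expression threshold in all samples of the matrix, mirroring the
    expressed-in-all-four-samples analysis set).
    """
    seedling = [c for c in cpm.columns if sample_meta.get(c) == "seedling"]
    floral = [c for c in cpm.columns if sample_meta.get(c) == "floral_bud"]
    if not seedling or not floral:
        raise ValueError("need at least one sample in each stage")
    if universe is None:
        universe = moderately_expressed(cpm, sample_meta)["all_samples"]
    idx = [t for t in cpm.index if t in set(universe)]
    sub = cpm.loc[idx]
    d = np.log2(
        (sub[floral].mean(axis=1) + pseudo) / (sub[seedling].mean(axis=1) + pseudo)
    )
    call = np.where(d > up_cut, "up", np.where(d < down_cut, "down", "unchanged"))
    return pd.DataFrame({"transcript_id": idx, "d": d.to_numpy(), "call": call})


@dataclass
class StageSets:
    """Two-stage set algebra with optional annotated/novel split."""

    both: set[str]
    stage1_only: set[str]
    stage2_only: set[str]

    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "stage1_only": len(self.stage1_only),
            "stage2_only": len(self.stage2_only),
            "union": len(self.both) + len(self.stage1_only) + len(self.stage2_only),
        }


def stage_sets(
    stage1: set[str],
    stage2: set[str],
    annotated: Optional[set[str]] = None,
) -> StageSets | tuple[StageSets, dict[str, dict[str, int]]]:
    """Shared and stage-specific transcript sets.

    With ``annotated`` given, also returns per-stage counts split into
    annotated vs novel transcripts.
    """
    sets = StageSets(
        both=stage1 & stage2,
        stage1_only=stage1 - stage2,
        stage2_only=stage2 - stage1,
    )
    if annotated is None:
        return sets
    split = {
        name: {
            "annotated": len(s & annotated),
            "novel": len(s - annotated),
        }
        for name, s in [
            ("stage1", stage1),
            ("stage2", stage2),
            ("both", sets.both),
        ]
    }
    return sets, split


# ---------------------------------------------------------------------------
# Supporting statistics (library-grade implementations)
# ---------------------------------------------------------------------------

def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction; returns (U, p)."""
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie-aware ranks; returns (rho, p).

    Constant vectors leave rho undefined: (nan, nan) is returned.
    """
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if len(set(x)) < 2 or len(set(y)) < 2:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least squares trend line; returns (slope, intercept)."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def correlate_expression_methylation(
    d_values: Mapping[str, float] | pd.Series,
    delta_m_values: Mapping[str, float] | pd.Series,
) -> tuple[float, float, int]:
    """Spearman correlation between expression change d and methylation
    change, joined on transcripts carrying both statistics.

    Returns (rho, p, n); fewer than 3 joined transcripts is an error.
    """
    d = pd.Series(d_values, dtype=float)
    dm = pd.Series(delta_m_values, dtype=float)
    joined = pd.concat([d.rename("d"), dm.rename("dm")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} transcripts with both statistics")
    rho, p = spearman(joined["d"].to_numpy(), joined["dm"].to_numpy())
    return rho, p, len(joined)
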