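"""m6A methylome construction from per-site modification tables.

Sites arrive as m6Anet-style rows (transcript, transcript position of the
central A, 5-mer, modification ratio m_i in [0, 1], supporting reads r_i)
per sequencing library.  The module filters by read support, partitions
sites into methylated (m_i > 0) and unmethylated, aggregates ratios to
transcript level with the read-weighted mean

    M = sum(m_i * r_i) / sum(r_i),

builds metagene profiles (full-length normalization for lncRNAs; fixed
5'UTR:CDS:3'UTR = 2:5:3 bands for mRNAs), summarizes DRACH motif usage,
computes site densities, and compares site sets across genotypes and
developmental stages.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, TranscriptomeAnnotation

__all__ = [
    "DRACH_RE",
    "DEFAULT_MIN_READS",
    "M6ASite",
    "TranscriptMethylation",
    "read_m6a_table",
    "write_m6a_table",
    "filter_sites",
    "call_methylated",
    "pool_sites",
    "transcript_modification_ratio",
    "methylation_table",
    "metagene_position",
    "metagene_profile",
    "motif_usage",
    "site_density",
    "compare_genotypes",
    "differential_modification",
]

DEFAULT_MIN_READS = 5

#: DRACH: D in {A,G,T}, R in {A,G}, central A, C, H in {A,C,T}
DRACH_RE = re.compile(r"^[AGT][AG]AC[ACT]$")

#: mRNA metagene bands: 5'UTR [0, 0.2), CDS [0.2, 0.7), 3'UTR [0.7, 1.0)
MRNA_BANDS = {"utr5": (0.0, 0.2), "cds": (0.2, 0.7), "utr3": (0.7, 1.0)}


class NonDrachKmerError(ValueError):
    pass


@dataclass(frozen=True)
class M6ASite:
    """One candidate m6A locus on one transcript in one library."""

    transcript_id: str
    position: int  # 0-based transcript coordinate of the central A
    kmer: str
    mod_ratio: float
    n_reads: int
    library_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.mod_ratio <= 1.0):
            raise ValueError(
                f"{self.transcript_id}:{self.position}: modification ratio "
                f"{self.mod_ratio} outside [0, 1]"
            )
        if self.n_reads < 1:
            raise ValueError(
                f"{self.transcript_id}:{self.position}: n_reads must be >= 1"
            )

    @property
    def is_drach(self) -> bool:
        return bool(DRACH_RE.match(self.kmer))

    @property
    def methylated(self) -> bool:
        return self.mod_ratio > 0.0


@dataclass(frozen=True)
class TranscriptMethylation:
    """Transcript-level read-weighted modification ratio."""

    transcript_id: str
    M: float
    n_sites: int
    total_reads: int
    group_id: str = ""


def read_m6a_table(path: str | Path, library_id: str = "", drach: str = "warn") -> list[M6ASite]:
    """Read an m6Anet-style TSV into sites.

    Accepts ``mod_ratio`` or ``probability_modified`` as the ratio column.
    ``drach`` controls non-DRACH kmers: "warn" keeps them (they are later
    excluded from motif usage), "error" raises, "drop" silently removes.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    ratio_col = "mod_ratio" if "mod_ratio" in df.columns else "probability_modified"
    sites = []
    for row in df.itertuples(index=False):
        site = M6ASite(
            transcript_id=str(row.transcript_id),
            position=int(row.transcript_position),
            kmer=str(row.kmer),
            mod_ratio=float(getattr(row, ratio_col)),
            n_reads=int(row.n_reads),
            library_id=library_id or str(getattr(row, "library_id", "")),
        )
        if not site.is_drach:
            if drach == "error":
                raise NonDrachKmerError(
                    f"{path}: non-DRACH kmer {site.kmer!r} at "
                    f"{site.transcript_id}:{site.position}"
                )
            if drach == "drop":
                continue
        sites.append(site)
    return sites


def write_m6a_table(sites: Iterable[M6ASite], path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("transcript_id\ttranscript_position\tn_reads\tmod_ratio\tkmer\tlibrary_id\n")
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.n_reads}\t"
                f"{s.mod_ratio:.6g}\t{s.kmer}\t{s.library_id}\n"
            )


def filter_sites(raw: Iterable[M6ASite], min_reads: int = DEFAULT_MIN_READS) -> list[M6ASite]:
    """Drop sites with fewer than ``min_reads`` supporting reads."""
    return [s for s in raw if s.n_reads >= min_reads]


def call_methylated(sites: Iterable[M6ASite]) -> tuple[list[M6ASite], list[M6ASite]]:
    """Partition sites into (methylated: m_i > 0, unmethylated: m_i = 0)."""
    methylated, unmethylated = [], []
    for s in sites:
        (methylated if s.methylated else unmethylated).append(s)
    return methylated, unmethylated


def methylated_transcripts(sites: Iterable[M6ASite]) -> set[str]:
    """Transcripts carrying at least one methylated site."""
    return {s.transcript_id for s in sites if s.methylated}


def pool_sites(sites: Iterable[M6ASite]) -> list[M6ASite]:
    """Pool per-library sites by (transcript, position).

    Reads are summed and the pooled ratio is the read-weighted mean of the
    per-library ratios.  Kmer disagreements between libraries at the same
    position raise, since site identity is positional.
    """
    acc: dict[tuple[str, int], list[M6ASite]] = defaultdict(list)
    for s in sites:
        acc[(s.transcript_id, s.position)].append(s)
    pooled = []
    for (tid, pos), group in sorted(acc.items()):
        kmers = {s.kmer for s in group}
        if len(kmers) > 1:
            raise ValueError(f"inconsistent kmers at {tid}:{pos}: {sorted(kmers)}")
        reads = sum(s.n_reads for s in group)
        ratio = sum(s.mod_ratio * s.n_reads for s in group) / reads
        pooled.append(M6ASite(tid, pos, group[0].kmer, ratio, reads, "pooled"))
    return pooled


def transcript_modification_ratio(
    sites: Sequence[M6ASite], include_zero_sites: bool = True
) -> Optional[TranscriptMethylation]:
    """Read-weighted mean modification ratio of one transcript's sites.

    With ``include_zero_sites`` (the default) every candidate site enters
    the weighted mean regardless of modification status; otherwise only
    methylated sites (m_i > 0) contribute.  Returns None when no site
    remains — an absent record, never a ratio of 0.
    """
    if not sites:
        return None
    tids = {s.transcript_id for s in sites}
    if len(tids) > 1:
        raise ValueError(f"sites from multiple transcripts: {sorted(tids)}")
    use = list(sites) if include_zero_sites else [s for s in sites if s.methylated]
    if not use:
        return None
    total_reads = sum(s.n_reads for s in use)
    M = sum(s.mod_ratio * s.n_reads for s in use) / total_reads
    return TranscriptMethylation(use[0].transcript_id, M, len(use), total_reads)


def methylation_table(
    sites: Iterable[M6ASite],
    include_zero_sites: bool = True,
    by_library: bool = False,
) -> pd.DataFrame:
    """Per-transcript (or per transcript x library) M values.

    Columns: transcript_id, [library_id,] M, n_sites, total_reads.
    """
    keyed: dict[tuple, list[M6ASite]] = defaultdict(list)
    for s in sites:
        key = (s.transcript_id, s.library_id) if by_library else (s.transcript_id,)
        keyed[key].append(s)
    rows = []
    for key, group in sorted(keyed.items()):
        tm = transcript_modification_ratio(group, include_zero_sites)
        if tm is None:
            continue
        rows.append(key + (tm.M, tm.n_sites, tm.total_reads))
    cols = ["transcript_id"] + (["library_id"] if by_library else [])
    return pd.DataFrame(rows, columns=cols + ["M", "n_sites", "total_reads"])


def metagene_position(
    position: int, t: TranscriptModel, mode: Optional[str] = None
) -> tuple[float, str]:
    """Relative metagene coordinate of a transcript position.

    lncRNA (full-length) mode: position / (length - 1), so 0 is the TSS
    base and 1 the TTS base (length-1 transcript → 0.5).  mRNA mode maps
    the position's region (derived from the CDS span projected onto
    transcript coordinates) into fixed bands 5'UTR [0, 0.2), CDS
    [0.2, 0.7), 3'UTR [0.7, 1.0) with within-region fraction
    (pos - region_start) / region_length.

    Returns (relative position, region name); region is "full" in
    full-length mode.
    """
    if not (0 <= position < t.length):
        raise ValueError(
            f"position {position} out of range for {t.transcript_id} "
            f"(length {t.length})"
        )
    if mode is None:
        mode = "mrna" if t.cds is not None else "full"
    if mode == "full":
        if t.length == 1:
            return 0.5, "full"
        return position / (t.length - 1), "full"
    if mode != "mrna":
        raise ValueError(f"unknown metagene mode {mode!r}")
    if t.cds is None:
        raise ValueError(f"{t.transcript_id}: mRNA metagene mode requires a CDS")
    utr5, cds, utr3 = t.utr_cds_utr_lengths()
    if position < utr5:
        region, region_start, region_len = "utr5", 0, utr5
    elif position < utr5 + cds:
        region, region_start, region_len = "cds", utr5, cds
    else:
        region, region_start, region_len = "utr3", utr5 + cds, utr3
    lo, hi = MRNA_BANDS[region]
    frac = (position - region_start) / max(region_len, 1)
    return lo + (hi - lo) * frac, region


def metagene_profile(
    sites: Iterable[M6ASite],
    annotation: TranscriptomeAnnotation,
    mode: Optional[str] = None,
    n_bins: int = 100,
    min_ratio: float = 0.0,
) -> pd.DataFrame:
    """Histogram of relative site positions over [0, 1].

    ``min_ratio`` > 0 restricts to highly methylated sites (e.g. 0.4).
    Sites on transcripts missing from the annotation, or lacking a CDS in
    mRNA mode, are skipped and reported in the ``n_skipped`` attribute of
    the returned frame.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rel = []
    skipped = 0
    for s in sites:
        if s.mod_ratio <= min_ratio and min_ratio > 0:
            continue
        t = annotation.transcripts.get(s.transcript_id)
        if t is None:
            skipped += 1
            continue
        site_mode = mode
        if site_mode == "mrna" and t.cds is None:
            skipped += 1
            continue
        rel.append(metagene_position(s.position, t, site_mode)[0])
    counts, _ = np.histogram(rel, bins=edges)
    df = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "n_sites": counts}
    )
    df.attrs["n_skipped"] = skipped
    df.attrs["n_used"] = len(rel)
    return df


def motif_usage(sites: Iterable[M6ASite]) -> tuple[pd.DataFrame, int]:
    """Per-5-mer counts and fractions among DRACH sites.

    Returns (frame with kmer / count / fraction / is_aaach, rejected
    non-DRACH count).  AAACH is the subfamily AAAC[ACT].
    """
    counts: Counter = Counter()
    rejects = 0
    for s in sites:
        if not s.is_drach:
            rejects += 1
            continue
        counts[s.kmer] += 1
    total = sum(counts.values())
    rows = [
        (k, n, n / total if total else 0.0, bool(re.match(r"^AAAC[ACT]$", k)))
        for k, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return (
        pd.DataFrame(rows, columns=["kmer", "count", "fraction", "is_aaach"]),
        rejects,
    )


def aaach_fraction(sites: Iterable[M6ASite]) -> float:
    """Fraction of DRACH sites in the AAACH subfamily."""
    usage, _ = motif_usage(sites)
    if usage.empty:
        return 0.0
    return float(usage.loc[usage.is_aaach, "fraction"].sum())


def site_density(n_methylated_sites: int, t: TranscriptModel) -> float:
    """Methylated sites per 100 nt of transcript."""
    if t.length < 1:
        raise ValueError(f"{t.transcript_id}: zero-length transcript")
    return 100.0 * n_methylated_sites / t.length


def density_table(
    sites: Iterable[M6ASite], annotation: TranscriptomeAnnotation
) -> pd.DataFrame:
    """Per-transcript methylated-site counts and densities."""
    counts: Counter = Counter(
        s.transcript_id for s in sites if s.methylated and s.transcript_id in annotation
    )
    rows = [
        (tid, n, site_density(n, annotation[tid]))
        for tid, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "n_methylated", "per_100nt"])


@dataclass
class GenotypePartition:
    """Set-algebra summary of methylated-site sets across genotypes."""

    wildtype_only: set
    shared_all: set
    novel_by_mutant: dict[str, set]
    pattern_counts: dict[frozenset, int]

    def counts(self) -> dict[str, int]:
        out = {
            "wildtype_only": len(self.wildtype_only),
            "shared_all": len(self.shared_all),
        }
        for g, s in sorted(self.novel_by_mutant.items()):
            out[f"novel_in_{g}"] = len(s)
        return out


def compare_genotypes(site_sets: Mapping[str, set]) -> GenotypePartition:
    """Partition site identities (transcript, position) across genotypes.

    wildtype_only = WT minus the union of all mutants; shared_all = the
    intersection of WT and every mutant; novel_in(g) = g minus WT.  The
    full membership-pattern tally is also returned so the categories'
    union over patterns reconstructs the universe exactly.
    """
    if "wildtype" not in site_sets:
        raise KeyError("site_sets must contain a 'wildtype' key")
    wt = set(site_sets["wildtype"])
    mutants = {g: set(s) for g, s in site_sets.items() if g != "wildtype"}
    union_mut: set = set().union(*mutants.values()) if mutants else set()
    shared = wt.copy()
    for s in mutants.values():
        shared &= s
    universe = wt | union_mut
    patterns: dict[frozenset, int] = defaultdict(int)
    for site in universe:
        members = frozenset(
            g for g, s in {**{"wildtype": wt}, **mutants}.items() if site in s
        )
        patterns[members] += 1
    return GenotypePartition(
        wildtype_only=wt - union_mut,
        shared_all=shared,
        novel_by_mutant={g: s - wt for g, s in mutants.items()},
        pattern_counts=dict(patterns),
    )


def shared_site_partition(set_a: set, set_b: set) -> dict[str, int]:
    """Two-way Venn counts (a_only / b_only / shared), e.g. stage-specific
    versus shared methylated sites between seedling and floral bud."""
    return {
        "a_only": len(set_a - set_b),
        "b_only": len(set_b - set_a),
        "shared": len(set_a & set_b),
    }


def differential_modification(
    M_by_library: pd.DataFrame, group_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-transcript methylation change between developmental stages.

    ``M_by_library`` is the per transcript x library table from
    :func:`methylation_table`; ``group_map`` maps library_id to
    "seedling" or "floral_bud".  The statistic is mean(M, floral bud
    libraries) - mean(M, seedling libraries); positive values mean the
    transcript gains methylation during development.  Transcripts missing
    a group are excluded; the count of exclusions is in
    ``df.attrs["n_excluded"]``.
    """
    df = M_by_library.copy()
    df["group"] = df["library_id"].map(group_map)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "library_id"].unique())
        raise KeyError(f"libraries missing from group_map: {missing}")
    means = (
        df.groupby(["transcript_id", "group"])["M"].mean().unstack("group")
    )
    complete = means.dropna(subset=["seedling", "floral_bud"])
    out = pd.DataFrame(
        {
            "transcript_id": complete.index,
            "delta_M": (complete["floral_bud"] - complete["seedling"]).to_numpy(),
            "M_seedling": complete["seedling"].to_numpy(),
            "M_floral_bud": complete["floral_bud"].to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["n_excluded"] = int(len(means) - len(complete))
    return out
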