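"""Synthetic input bundles with known ground truth.

The generator lays out a small Arabidopsis-like transcriptome on one
chromosome divided into fixed-width slots, one planted unit per slot:
a protein-coding gene (optionally hosting one novel transcript built
geometrically to realize a chosen class code), a reference lncRNA, or an
intergenic novel transcript.  Around that geometry it emits every input
table the pipeline consumes — reference and assembly GTFs, per-library
m6A site tables (wild type per stage plus methyltransferase-mutant
genotypes), per-read poly(A) tables, DRS count and NGS TPM matrices,
coding-potential evidence, and labelled scores for cutoff training —
together with per-transcript ground truth.

The default parameters emulate the study conditions at desk scale:
two seedling and two floral-bud wild-type DRS libraries (the stage
comparison), four mutant genotypes, four NGS samples per stage,
beta-distributed site-level modification ratios with lncRNAs less
methylated than mRNAs, gamma-distributed poly(A) tails with lncRNA tails
slightly shorter, and about one third of lncRNAs escaping
polyadenylation.  Identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation import (
    GenomicInterval,
    TranscriptModel,
    TranscriptomeAnnotation,
    write_annotation,
)
from .m6a import M6ASite, write_m6a_table

__all__ = [
    "M6AConfig",
    "PolyAConfig",
    "ExpressionConfig",
    "CodingScoreConfig",
    "SimulationConfig",
    "TruthRecord",
    "GroundTruth",
    "SimulatedBundle",
    "generate",
]

_DRACH_KMERS = [
    d + r + "AC" + h
    for d in "AGT"
    for r in "AG"
    for h in "ACT"
]
_AAACH = [k for k in _DRACH_KMERS if k.startswith("AAAC")]
_OTHER_DRACH = [k for k in _DRACH_KMERS if not k.startswith("AAAC")]

WT_LIBRARIES = {
    "seedling_1": "seedling",
    "seedling_2": "seedling",
    "floral_1": "floral_bud",
    "floral_2": "floral_bud",
}

MUTANT_GENOTYPES = ("vir", "fip37", "mtb", "fio1")

#: site "writer" classes and which genotypes retain them; the MTA-complex
#: mutants (vir/fip37/mtb) lose mta_complex sites, fio1 loses fio1 sites,
#: independent sites survive every mutant, fragile sites survive none
_WRITER_RETAINED = {
    "independent": set(MUTANT_GENOTYPES),
    "mta_complex": {"fio1"},
    "fio1": {"vir", "fip37", "mtb"},
    "fragile": set(),
}


@dataclass
class M6AConfig:
    site_rate_lnc: float = 1.0  # candidate sites per 100 nt, lncRNA
    site_rate_mrna: float = 1.6  # candidate sites per 100 nt, mRNA
    mu_beta_lnc: tuple[float, float] = (2.0, 10.0)  # pooled median M ~0.16
    mu_beta_mrna: tuple[float, float] = (2.5, 9.4)  # pooled median M ~0.18
    site_mu_jitter: float = 0.04
    frac_zero_sites: float = 0.1  # candidate sites that are never modified
    read_depth: float = 30.0  # mean supporting reads per site per library
    frac_low_support: float = 0.1  # sites drawn with < 5 reads (filtered)
    aaach_weight: float = 0.38  # kmer mass on the AAACH subfamily
    coupling_slope: float = 0.08  # d(mu)/d(log2FC) stage coupling
    coupling_noise: float = 0.02
    writer_probs: tuple[float, float, float, float] = (0.2, 0.35, 0.2, 0.25)
    n_novel_sites_per_mutant: int = 10


@dataclass
class PolyAConfig:
    frac_non_polya: float = 0.33
    tail_shape_lnc: float = 4.5
    tail_scale_lnc: float = 20.0  # median ~ 83.5 nt
    tail_shape_mrna: float = 4.5
    tail_scale_mrna: float = 21.7  # median ~ 90.6 nt
    reads_per_library: float = 4.0  # Poisson mean of DRS reads per library
    qc_fail_rate: float = 0.1


@dataclass
class ExpressionConfig:
    n_ngs_per_stage: int = 4
    depth_drs: int = 300_000
    log_abundance_sigma: float = 1.0
    lfc_sigma: float = 1.0  # planted log2 fold-changes for both-stage lncRNAs
    frac_stage_specific: float = 0.15  # per stage
    tpm_noise_sigma: float = 0.15


@dataclass
class CodingScoreConfig:
    beta_coding: tuple[float, float] = (6.0, 3.0)
    beta_noncoding: tuple[float, float] = (2.0, 10.0)
    n_train_per_class: int = 200


def _default_novel_counts() -> dict[str, int]:
    return {"x": 12, "s": 8, "i": 5, "y": 5, "o": 12, "p": 8, "u": 15}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_coding_genes: int = 60
    n_reference_lncrnas: int = 30
    n_novel_per_category: dict[str, int] = field(default_factory=_default_novel_counts)
    n_annotated_in_assembly: int = 30
    n_novel_coding_isoforms: int = 6
    n_short_novel: int = 4
    chrom: str = "Chr1"
    slot_width: int = 20_000
    run_on_distance: int = 2000
    m6a: M6AConfig = field(default_factory=M6AConfig)
    polya: PolyAConfig = field(default_factory=PolyAConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    coding_scores: CodingScoreConfig = field(default_factory=CodingScoreConfig)


@dataclass
class TruthRecord:
    """Planted ground truth for one transcript."""

    transcript_id: str
    role: str  # reference_coding | reference_lncrna | annotated_copy |
    #            novel_lncrna | novel_coding_isoform | novel_short
    class_code: Optional[str] = None  # planted code for assembly transcripts
    category: Optional[str] = None
    coding_label: str = "noncoding"
    is_lncrna: bool = False
    stage_presence: str = "both"  # both | seedling | floral_bud
    log2fc: float = 0.0
    mu_seedling: Optional[float] = None  # planted transcript methylation level
    mu_floral: Optional[float] = None
    true_M_seedling: Optional[float] = None  # read-weighted planted site means
    true_M_floral: Optional[float] = None
    polya_status: Optional[str] = None
    tail_mean: Optional[float] = None
    base_abundance: float = 0.0


@dataclass
class GroundTruth:
    records: dict[str, TruthRecord]
    wt_sites: set[tuple[str, int]]  # methylated WT site identities
    site_writers: dict[tuple[str, int], str]
    mutant_sites: dict[str, set[tuple[str, int]]]
    expected_partition: dict[str, int]

    def by_role(self, role: str) -> list[TruthRecord]:
        return [r for r in self.records.values() if r.role == role]


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    out_dir: Path
    reference: TranscriptomeAnnotation
    assembly: TranscriptomeAnnotation
    truth: GroundTruth
    paths: dict[str, Path]
    wt_libraries: dict[str, str] = field(default_factory=lambda: dict(WT_LIBRARIES))


_CAT_BY_CODE = {
    "s": "antisense", "x": "antisense", "p": "intergenic", "u": "intergenic",
    "i": "intronic", "y": "overlapping", "o": "overlapping",
}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _make_coding_gene(rng, chrom: str, slot_start: int, idx: int) -> TranscriptModel:
    n_exons = int(rng.integers(3, 6))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = slot_start + 6000
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(150, 401))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(400, 901))
    cds = GenomicInterval(chrom, exons[0].start + 30, exons[-1].end - 30, strand)
    return TranscriptModel(
        transcript_id=f"AT1G{10000 + idx:05d}.1",
        gene_id=f"AT1G{10000 + idx:05d}",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        biotype="protein_coding",
        cds=cds,
    )


def _make_reference_lncrna(rng, chrom: str, slot_start: int, idx: int) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    start = slot_start + 7000
    if rng.random() < 0.3:  # spliced reference lncRNA
        l1, l2 = int(rng.integers(200, 301)), int(rng.integers(200, 301))
        gap = int(rng.integers(300, 601))
        exons = (
            GenomicInterval(chrom, start, start + l1, strand),
            GenomicInterval(chrom, start + l1 + gap, start + l1 + gap + l2, strand),
        )
    else:
        length = int(rng.integers(300, 601))
        exons = (GenomicInterval(chrom, start, start + length, strand),)
    return TranscriptModel(
        transcript_id=f"AT1G{60000 + idx:05d}.1",
        gene_id=f"AT1G{60000 + idx:05d}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        biotype="lncRNA",
    )


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _novel_for_code(
    rng, code: str, host: Optional[TranscriptModel], chrom: str,
    slot_start: int, tid: str,
) -> TranscriptModel:
    """Construct a novel transcript realizing ``code`` against its host."""
    if code in ("x", "o"):
        ex = host.exons[1]
        strand = host.strand if code == "o" else _flip(host.strand)
        exons = (GenomicInterval(chrom, ex.start - 50, ex.end + 50, strand),)
    elif code in ("s", "i"):
        istart, iend = host.junctions[0]
        strand = host.strand if code == "i" else _flip(host.strand)
        exons = (GenomicInterval(chrom, istart + 60, iend - 60, strand),)
    elif code == "p":
        start = host.span.end + 400
        exons = (GenomicInterval(chrom, start, start + 300, host.strand),)
        strand = host.strand
    elif code == "y":
        # host is a small single-exon reference placed inside our intron
        span = host.span
        strand = host.strand
        exons = (
            GenomicInterval(chrom, span.start - 450, span.start - 200, strand),
            GenomicInterval(chrom, span.end + 200, span.end + 450, strand),
        )
    elif code == "u":
        start = slot_start + 8000
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(250, 601))
        exons = (GenomicInterval(chrom, start, start + length, strand),)
    else:
        raise ValueError(f"no geometric construction for code {code!r}")
    return TranscriptModel(
        transcript_id=tid, gene_id=tid.rsplit(".", 1)[0], chrom=chrom,
        strand=strand, exons=exons, biotype="other",
    )


def _novel_isoform(host: TranscriptModel, tid: str) -> TranscriptModel:
    """Same-strand novel sharing the host's first splice junction."""
    e0, e1 = host.exons[0], host.exons[1]
    exons = (
        GenomicInterval(host.chrom, e0.start, e0.end, host.strand),
        GenomicInterval(host.chrom, e1.start, e1.end + 150, host.strand),
    )
    return TranscriptModel(
        transcript_id=tid, gene_id=tid.rsplit(".", 1)[0], chrom=host.chrom,
        strand=host.strand, exons=exons, biotype="other",
    )


def _short_novel(rng, chrom: str, slot_start: int, tid: str) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    start = slot_start + 8000
    return TranscriptModel(
        transcript_id=tid, gene_id=tid.rsplit(".", 1)[0], chrom=chrom,
        strand=strand,
        exons=(GenomicInterval(chrom, start, start + 150, strand),),
        biotype="other",
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_kmer(rng, cfg: M6AConfig) -> str:
    if rng.random() < cfg.aaach_weight:
        return _AAACH[int(rng.integers(len(_AAACH)))]
    return _OTHER_DRACH[int(rng.integers(len(_OTHER_DRACH)))]


def _draw_reads(rng, cfg: M6AConfig) -> int:
    if rng.random() < cfg.frac_low_support:
        return int(rng.integers(1, 5))
    return 5 + int(rng.poisson(max(cfg.read_depth - 5, 1)))


def generate(config: SimulationConfig, out_dir: str | Path) -> SimulatedBundle:
    """Generate the full synthetic input bundle under ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom = config.chrom
    mcfg, pcfg, ecfg, ccfg = config.m6a, config.polya, config.expression, config.coding_scores

    host_codes = [c for c in ("x", "s", "i", "o", "p") for _ in range(config.n_novel_per_category.get(c, 0))]
    n_hosted = len(host_codes) + config.n_novel_coding_isoforms
    if config.n_coding_genes < n_hosted:
        raise ValueError(
            f"{n_hosted} novel transcripts need coding-gene hosts but only "
            f"{config.n_coding_genes} coding genes configured"
        )
    n_y = config.n_novel_per_category.get("y", 0)
    n_u = config.n_novel_per_category.get("u", 0)

    reference: list[TranscriptModel] = []
    novels: list[tuple[TranscriptModel, str, str]] = []  # (model, code, role)
    truth: dict[str, TruthRecord] = {}
    slot = 0
    novel_idx = 0

    def next_novel_id() -> str:
        nonlocal novel_idx
        novel_idx += 1
        return f"MLAFT.{novel_idx}.1"

    # coding genes, some hosting a planted novel
    for gi in range(config.n_coding_genes):
        gene = _make_coding_gene(rng, chrom, slot * config.slot_width, gi)
        slot += 1
        reference.append(gene)
        if gi < len(host_codes):
            code = host_codes[gi]
            t = _novel_for_code(rng, code, gene, chrom, 0, next_novel_id())
            novels.append((t, code, "novel_lncrna"))
        elif gi < n_hosted:
            t = _novel_isoform(gene, next_novel_id())
            novels.append((t, "o", "novel_coding_isoform"))

    # y units: a small single-exon reference lncRNA inside the query intron
    for yi in range(n_y):
        start = slot * config.slot_width + 7000
        y_strand = "+" if rng.random() < 0.5 else "-"
        host = TranscriptModel(
            transcript_id=f"AT1G{80000 + yi:05d}.1",
            gene_id=f"AT1G{80000 + yi:05d}",
            chrom=chrom,
            strand=y_strand,
            exons=(GenomicInterval(chrom, start, start + 300, y_strand),),
            biotype="lncRNA",
        )
        slot += 1
        reference.append(host)
        t = _novel_for_code(rng, "y", host, chrom, 0, next_novel_id())
        novels.append((t, "y", "novel_lncrna"))

    # intergenic novels and short rejects, each in an empty slot
    for _ in range(n_u):
        t = _novel_for_code(rng, "u", None, chrom, slot * config.slot_width, next_novel_id())
        slot += 1
        novels.append((t, "u", "novel_lncrna"))
    for _ in range(config.n_short_novel):
        t = _short_novel(rng, chrom, slot * config.slot_width, next_novel_id())
        slot += 1
        novels.append((t, "u", "novel_short"))

    # reference lncRNAs in their own slots
    for li in range(config.n_reference_lncrnas):
        t = _make_reference_lncrna(rng, chrom, slot * config.slot_width, li)
        slot += 1
        reference.append(t)

    reference_ann = TranscriptomeAnnotation.from_transcripts(reference, source="reference")

    # assembly: copies of annotated transcripts (class code "=") + novels
    assembly: list[TranscriptModel] = []
    ref_sorted = sorted(reference, key=lambda t: t.transcript_id)
    for src in ref_sorted[: config.n_annotated_in_assembly]:
        tid = next_novel_id()
        copy = TranscriptModel(
            tid, tid.rsplit(".", 1)[0], src.chrom, src.strand, src.exons,
            biotype="other", cds=None,
        )
        assembly.append(copy)
        truth[tid] = TruthRecord(
            tid, "annotated_copy", class_code="=",
            coding_label="coding" if src.biotype == "protein_coding" else "noncoding",
        )
    for t, code, role in novels:
        assembly.append(t)
        truth[t.transcript_id] = TruthRecord(
            t.transcript_id, role, class_code=code,
            category=_CAT_BY_CODE[code],
            coding_label="noncoding",
            is_lncrna=(role == "novel_lncrna"),
        )
    assembly_ann = TranscriptomeAnnotation.from_transcripts(assembly, source="assembly")

    for t in reference:
        role = "reference_coding" if t.biotype == "protein_coding" else "reference_lncrna"
        truth[t.transcript_id] = TruthRecord(
            t.transcript_id, role,
            coding_label="coding" if t.biotype == "protein_coding" else "noncoding",
            is_lncrna=(t.biotype == "lncRNA"),
        )

    # ------------------------------------------------------------------
    # expression: stage presence, fold changes, abundance
    # ------------------------------------------------------------------
    universe = [t for t in reference] + [t for t, _, role in novels]
    lnc_like = {
        r.transcript_id
        for r in truth.values()
        if r.is_lncrna
    }
    for t in universe:
        rec = truth[t.transcript_id]
        rec.base_abundance = float(rng.lognormal(mean=2.0, sigma=ecfg.log_abundance_sigma))
        if rec.transcript_id in lnc_like:
            u = rng.random()
            if u < ecfg.frac_stage_specific:
                rec.stage_presence = "seedling"
            elif u < 2 * ecfg.frac_stage_specific:
                rec.stage_presence = "floral_bud"
            else:
                rec.stage_presence = "both"
                rec.log2fc = float(rng.normal(0.0, ecfg.lfc_sigma))
        else:
            rec.stage_presence = "both"

    # poly(A) status (lncRNAs may escape polyadenylation; mRNAs do not)
    for t in universe:
        rec = truth[t.transcript_id]
        if rec.transcript_id in lnc_like and rng.random() < pcfg.frac_non_polya:
            rec.polya_status = "non_polyA"
        else:
            rec.polya_status = "polyA"

    def _stage_mult(rec: TruthRecord, stage: str) -> float:
        if rec.stage_presence != "both" and rec.stage_presence != stage:
            return 0.0
        if stage == "floral_bud":
            return 2.0 ** (rec.log2fc / 2.0)
        return 2.0 ** (-rec.log2fc / 2.0)

    def _drs_visible(rec: TruthRecord) -> bool:
        return rec.polya_status == "polyA"

    # DRS counts (poly(A)-selected: non-poly(A) transcripts are invisible)
    drs_samples = list(WT_LIBRARIES)
    counts = np.zeros((len(universe), len(drs_samples)))
    for j, lib in enumerate(drs_samples):
        stage = WT_LIBRARIES[lib]
        w = np.array(
            [
                truth[t.transcript_id].base_abundance
                * _stage_mult(truth[t.transcript_id], stage)
                * (1.0 if _drs_visible(truth[t.transcript_id]) else 0.0)
                for t in universe
            ]
        )
        p = w / w.sum()
        counts[:, j] = rng.poisson(ecfg.depth_drs * p)

    # NGS TPM (rRNA-depleted: everything expressed is present)
    ngs_samples = [f"ngs_seedling_{i+1}" for i in range(ecfg.n_ngs_per_stage)] + [
        f"ngs_floral_{i+1}" for i in range(ecfg.n_ngs_per_stage)
    ]
    tpm = np.zeros((len(universe), len(ngs_samples)))
    for j, lib in enumerate(ngs_samples):
        stage = "seedling" if "seedling" in lib else "floral_bud"
        w = np.array(
            [
                truth[t.transcript_id].base_abundance
                * _stage_mult(truth[t.transcript_id], stage)
                * float(rng.lognormal(0.0, ecfg.tpm_noise_sigma))
                for t in universe
            ]
        )
        tpm[:, j] = 1e6 * w / w.sum()

    # ------------------------------------------------------------------
    # m6A sites
    # ------------------------------------------------------------------
    mu_by_stage: dict[str, dict[str, float]] = {}
    site_defs: dict[str, list[tuple[int, str, float, bool]]] = {}
    for t in universe:
        rec = truth[t.transcript_id]
        if not _drs_visible(rec):
            continue
        is_lnc = rec.transcript_id in lnc_like
        a, b = mcfg.mu_beta_lnc if is_lnc else mcfg.mu_beta_mrna
        mu = float(rng.beta(a, b))
        delta = mcfg.coupling_slope * rec.log2fc + float(
            rng.normal(0.0, mcfg.coupling_noise)
        )
        mu_s = float(np.clip(mu - delta / 2.0, 0.02, 0.95))
        mu_f = float(np.clip(mu + delta / 2.0, 0.02, 0.95))
        rec.mu_seedling, rec.mu_floral = mu_s, mu_f
        rate = mcfg.site_rate_lnc if is_lnc else mcfg.site_rate_mrna
        n_sites = int(rng.poisson(rate * t.length / 100.0))
        if n_sites == 0 or t.length < 10:
            continue
        n_sites = min(n_sites, t.length - 4)
        positions = np.sort(
            rng.choice(np.arange(2, t.length - 2), size=n_sites, replace=False)
        )
        defs = []
        for pos in positions:
            kmer = _draw_kmer(rng, mcfg)
            zero = rng.random() < mcfg.frac_zero_sites
            jitter = float(rng.normal(0.0, mcfg.site_mu_jitter))
            defs.append((int(pos), kmer, jitter, zero))
        site_defs[t.transcript_id] = defs
        mu_by_stage[t.transcript_id] = {"seedling": mu_s, "floral_bud": mu_f}

    paths: dict[str, Path] = {}
    wt_methylated: set[tuple[str, int]] = set()
    true_reads: dict[str, dict[str, tuple[float, float]]] = {}
    for lib, stage in WT_LIBRARIES.items():
        rows: list[M6ASite] = []
        for t in universe:
            rec = truth[t.transcript_id]
            tid = t.transcript_id
            if tid not in site_defs:
                continue
            if rec.stage_presence != "both" and rec.stage_presence != stage:
                continue
            mu_t = mu_by_stage[tid][stage]
            for pos, kmer, jitter, zero in site_defs[tid]:
                reads = _draw_reads(rng, mcfg)
                if zero:
                    m = 0.0
                    mu_site = 0.0
                else:
                    mu_site = float(np.clip(mu_t + jitter, 0.01, 0.99))
                    m = float(rng.binomial(reads, mu_site)) / reads
                rows.append(M6ASite(tid, pos, kmer, m, reads, lib))
                if m > 0 and reads >= 5:
                    wt_methylated.add((tid, pos))
                if reads >= 5:
                    acc = true_reads.setdefault(tid, {}).setdefault(stage, (0.0, 0.0))
                    true_reads[tid][stage] = (acc[0] + mu_site * reads, acc[1] + reads)
        path = out / f"m6a_{lib}.tsv"
        write_m6a_table(rows, path, header=f"library={lib} stage={stage}")
        paths[f"m6a_{lib}"] = path

    for tid, stages in true_reads.items():
        rec = truth[tid]
        if "seedling" in stages and stages["seedling"][1] > 0:
            rec.true_M_seedling = stages["seedling"][0] / stages["seedling"][1]
        if "floral_bud" in stages and stages["floral_bud"][1] > 0:
            rec.true_M_floral = stages["floral_bud"][0] / stages["floral_bud"][1]

    # mutant genotypes: delete planted writer-dependent subsets, add novels
    writers = ("independent", "mta_complex", "fio1", "fragile")
    site_writers: dict[tuple[str, int], str] = {}
    for site in sorted(wt_methylated):
        site_writers[site] = writers[
            int(rng.choice(len(writers), p=np.asarray(mcfg.writer_probs)))
        ]
    kmer_by_site = {
        (tid, pos): kmer
        for tid, defs in site_defs.items()
        for pos, kmer, _, _ in defs
    }
    mutant_sites: dict[str, set[tuple[str, int]]] = {}
    for g in MUTANT_GENOTYPES:
        retained = {
            s for s, w in site_writers.items() if g in _WRITER_RETAINED[w]
        }
        # mutant-specific novel sites on transcripts with site capacity
        novel: set[tuple[str, int]] = set()
        candidates = sorted(site_defs)
        for k in range(mcfg.n_novel_sites_per_mutant):
            tid = candidates[int(rng.integers(len(candidates)))]
            t = assembly_ann.transcripts.get(tid) or reference_ann.transcripts.get(tid)
            existing = {p for p, *_ in site_defs[tid]} | {
                p for tt, p in novel if tt == tid
            }
            for _ in range(50):
                pos = int(rng.integers(2, t.length - 2))
                if pos not in existing and (tid, pos) not in wt_methylated:
                    novel.add((tid, pos))
                    break
        mutant_sites[g] = retained | novel
        rows = []
        for tid, pos in sorted(retained | novel):
            kmer = kmer_by_site.get((tid, pos)) or _draw_kmer(rng, mcfg)
            reads = 5 + int(rng.poisson(max(mcfg.read_depth - 5, 1)))
            m = float(np.clip(rng.beta(2.0, 9.0), 0.01, 0.99))
            rows.append(M6ASite(tid, pos, kmer, m, reads, f"mutant_{g}"))
        path = out / f"m6a_mutant_{g}.tsv"
        write_m6a_table(rows, path, header=f"genotype={g}")
        paths[f"m6a_mutant_{g}"] = path

    n_fragile = sum(w == "fragile" for w in site_writers.values())
    n_indep = sum(w == "independent" for w in site_writers.values())
    expected_partition = {
        "wildtype_only": n_fragile,
        "shared_all": n_indep,
        **{f"novel_in_{g}": len(mutant_sites[g] - wt_methylated) for g in MUTANT_GENOTYPES},
    }

    # ------------------------------------------------------------------
    # poly(A) reads
    # ------------------------------------------------------------------
    read_counter = 0
    for lib, stage in WT_LIBRARIES.items():
        lines = ["readname\tcontig\tpolya_length\tqc_tag"]
        for t in universe:
            rec = truth[t.transcript_id]
            if not _drs_visible(rec):
                continue
            if rec.stage_presence != "both" and rec.stage_presence != stage:
                continue
            is_lnc = rec.transcript_id in lnc_like
            shape = pcfg.tail_shape_lnc if is_lnc else pcfg.tail_shape_mrna
            scale = pcfg.tail_scale_lnc if is_lnc else pcfg.tail_scale_mrna
            # every poly(A) transcript is DRS-visible by construction: it is
            # guaranteed one QC-passing read in the first library of a stage
            # where it is present
            guarantee_lib = (
                "floral_1" if rec.stage_presence == "floral_bud" else "seedling_1"
            )
            n_reads = int(rng.poisson(pcfg.reads_per_library))
            if lib == guarantee_lib:
                n_reads = max(n_reads, 1)
            for k in range(n_reads):
                read_counter += 1
                tail = float(rng.gamma(shape, scale))
                guaranteed = lib == guarantee_lib and k == 0
                qc = "PASS" if guaranteed or rng.random() >= pcfg.qc_fail_rate else "ADAPTER"
                lines.append(
                    f"read_{read_counter:06d}\t{t.transcript_id}\t{tail:.2f}\t{qc}"
                )
        path = out / f"polya_{lib}.tsv"
        path.write_text("\n".join(lines) + "\n")
        paths[f"polya_{lib}"] = path

    for t in universe:
        rec = truth[t.transcript_id]
        if rec.polya_status == "polyA":
            is_lnc = rec.transcript_id in lnc_like
            shape = pcfg.tail_shape_lnc if is_lnc else pcfg.tail_shape_mrna
            scale = pcfg.tail_scale_lnc if is_lnc else pcfg.tail_scale_mrna
            rec.tail_mean = shape * scale

    # ------------------------------------------------------------------
    # expression matrices, metadata, coding evidence, training scores
    # ------------------------------------------------------------------
    tids = [t.transcript_id for t in universe]
    counts_path = out / "counts_drs.tsv"
    with open(counts_path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(drs_samples) + "\n")
        for i, tid in enumerate(tids):
            fh.write(tid + "\t" + "\t".join(str(int(c)) for c in counts[i]) + "\n")
    paths["counts_drs"] = counts_path

    tpm_path = out / "tpm_ngs.tsv"
    with open(tpm_path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(ngs_samples) + "\n")
        for i, tid in enumerate(tids):
            fh.write(tid + "\t" + "\t".join(f"{v:.4f}" for v in tpm[i]) + "\n")
    paths["tpm_ngs"] = tpm_path

    meta_path = out / "sample_meta.tsv"
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tstage\tplatform\tgenotype\n")
        for lib, stage in WT_LIBRARIES.items():
            fh.write(f"{lib}\t{stage}\tDRS\twildtype\n")
        for lib in ngs_samples:
            stage = "seedling" if "seedling" in lib else "floral_bud"
            fh.write(f"{lib}\t{stage}\tNGS\twildtype\n")
    paths["sample_meta"] = meta_path

    ev_path = out / "coding_evidence.tsv"
    with open(ev_path, "w") as fh:
        fh.write("transcript_id\tcpat_prob\tcpc2_label\n")
        for t in sorted(assembly, key=lambda t: t.transcript_id):
            rec = truth[t.transcript_id]
            if rec.coding_label == "coding":
                p = float(rng.beta(*ccfg.beta_coding))
            else:
                p = float(rng.beta(1.0, 30.0))
            fh.write(f"{t.transcript_id}\t{p:.4f}\t{rec.coding_label}\n")
    paths["coding_evidence"] = ev_path

    scores_path = out / "labeled_scores.tsv"
    with open(scores_path, "w") as fh:
        fh.write("score\ttruth\n")
        for _ in range(ccfg.n_train_per_class):
            fh.write(f"{float(rng.beta(*ccfg.beta_coding)):.6f}\tcoding\n")
        for _ in range(ccfg.n_train_per_class):
            fh.write(f"{float(rng.beta(*ccfg.beta_noncoding)):.6f}\tnoncoding\n")
    paths["labeled_scores"] = scores_path

    ref_path = out / "reference.gtf"
    asm_path = out / "assembly.gtf"
    write_annotation(reference_ann, ref_path, "GTF")
    write_annotation(assembly_ann, asm_path, "GTF")
    paths["reference"] = ref_path
    paths["assembly"] = asm_path

    truth_path = out / "ground_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "transcript_id\trole\tclass_code\tcategory\tcoding_label\tis_lncrna\t"
            "stage_presence\tlog2fc\tpolya_status\n"
        )
        for tid in sorted(truth):
            r = truth[tid]
            fh.write(
                f"{tid}\t{r.role}\t{r.class_code or ''}\t{r.category or ''}\t"
                f"{r.coding_label}\t{int(r.is_lncrna)}\t{r.stage_presence}\t"
                f"{r.log2fc:.4f}\t{r.polya_status or ''}\n"
            )
    paths["ground_truth"] = truth_path

    manifest = out / "MANIFEST.tsv"
    with open(manifest, "w") as fh:
        fh.write("role\tpath\n")
        for key in sorted(paths):
            fh.write(f"{key}\t{paths[key].name}\n")
    paths["manifest"] = manifest

    gt = GroundTruth(
        records=truth,
        wt_sites=wt_methylated,
        site_writers=site_writers,
        mutant_sites=mutant_sites,
        expected_partition=expected_partition,
    )
    return SimulatedBundle(
        config=config,
        out_dir=out,
        reference=reference_ann,
        assembly=assembly_ann,
        truth=gt,
        paths=paths,
    )
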