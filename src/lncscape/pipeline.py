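"""End-to-end orchestration: identify → methylome → poly(A) → dynamics.

``run_pipeline`` chains the library stages over a directory of input
tables, writes per-stage TSV outputs with provenance headers (every
threshold echoed), and returns a JSON-serializable summary whose numbers
are all recomputable from the stage tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation, compare, expression, identify, m6a, polya

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    min_length: int = 200
    cpat_cutoff: float = 0.325
    min_reads: int = 5
    cpm_threshold: float = 0.1
    pseudo_cpm: float = 0.1
    up_cut: float = 0.7
    down_cut: float = -0.7
    tpm_threshold: float = 0.1
    min_tpm_samples: int = 2
    high_methyl_ratio: float = 0.4
    run_on_distance: int = 2000


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    reference: Path
    assembly: Path
    m6a_tables: dict[str, Path] = field(default_factory=dict)  # library -> path
    m6a_groups: dict[str, str] = field(default_factory=dict)  # library -> stage
    mutant_tables: dict[str, Path] = field(default_factory=dict)  # genotype -> path
    polya_tables: dict[str, Path] = field(default_factory=dict)  # library -> path
    counts: Optional[Path] = None
    tpm: Optional[Path] = None
    sample_meta: Optional[Path] = None
    coding_evidence: Optional[Path] = None
    labeled_scores: Optional[Path] = None
    out_dir: Path = Path("lncscape_out")
    thresholds: Thresholds = field(default_factory=Thresholds)
    train_cutoff: bool = False  # derive the CPAT cutoff from labeled_scores
    stages: tuple[str, ...] = ("identify", "methylome", "polya", "dynamics")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        th = Thresholds(**raw.pop("thresholds", {}))
        base = Path(path).parent

        def p(v):  # paths in the config file are relative to it
            return base / v

        kwargs: dict = {"thresholds": th}
        for key in ("reference", "assembly", "counts", "tpm", "sample_meta",
                    "coding_evidence", "labeled_scores"):
            if key in raw:
                kwargs[key] = p(raw.pop(key))
        for key in ("m6a_tables", "mutant_tables", "polya_tables"):
            if key in raw:
                kwargs[key] = {k: p(v) for k, v in raw.pop(key).items()}
        kwargs.update(raw)
        if "out_dir" in kwargs:
            kwargs["out_dir"] = Path(kwargs["out_dir"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    @classmethod
    def from_bundle_dir(cls, bundle_dir: str | Path, out_dir: str | Path) -> "PipelineConfig":
        """Configuration over a directory produced by the simulator."""
        d = Path(bundle_dir)
        libs = {"seedling_1": "seedling", "seedling_2": "seedling",
                "floral_1": "floral_bud", "floral_2": "floral_bud"}
        m6a_tables = {
            lib: d / f"m6a_{lib}.tsv" for lib in libs if (d / f"m6a_{lib}.tsv").exists()
        }
        mutant_tables = {
            g: d / f"m6a_mutant_{g}.tsv"
            for g in ("vir", "fip37", "mtb", "fio1")
            if (d / f"m6a_mutant_{g}.tsv").exists()
        }
        polya_tables = {
            lib: d / f"polya_{lib}.tsv" for lib in libs if (d / f"polya_{lib}.tsv").exists()
        }
        return cls(
            reference=d / "reference.gtf",
            assembly=d / "assembly.gtf",
            m6a_tables=m6a_tables,
            m6a_groups={k: v for k, v in libs.items() if k in m6a_tables},
            mutant_tables=mutant_tables,
            polya_tables=polya_tables,
            counts=d / "counts_drs.tsv",
            tpm=d / "tpm_ngs.tsv",
            sample_meta=d / "sample_meta.tsv",
            coding_evidence=d / "coding_evidence.tsv",
            labeled_scores=d / "labeled_scores.tsv",
            out_dir=Path(out_dir),
        )


def _provenance(th: Thresholds) -> str:
    return " ".join(f"{k}={v}" for k, v in dataclasses.asdict(th).items())


def _write_df(df: pd.DataFrame, path: Path, th: Thresholds) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lncscape {_provenance(th)}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the summary report."""
    th = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": dataclasses.asdict(th)}

    for path in (config.reference, config.assembly):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")

    reference = annotation.read_annotation(config.reference, source="reference")
    assembly = annotation.read_annotation(config.assembly, source="assembly")

    # ------------------------------------------------------------- identify
    lnc_ids: set[str] = set()
    annotated_lnc_ids = {
        t.transcript_id for t in reference if t.biotype == "lncRNA"
    }
    categories: dict[str, str] = {}
    try:
        assignments = compare.classify_all(
            assembly, reference, th.run_on_distance
        )
        compare.write_assignments(assignments, out / "class_codes.tsv")
        summary["class_code_counts"] = dict(compare.summarize_codes(assignments))

        cutoff = th.cpat_cutoff
        if config.train_cutoff and config.labeled_scores is not None:
            scores, truths = identify.read_labeled_scores(config.labeled_scores)
            res = identify.tgroc_cutoff(scores, truths)
            cutoff = res.cutoff
            summary["tgroc"] = dataclasses.asdict(res)

        novel_assign = [a for a in assignments if a.code != "="]
        evidence = identify.read_coding_evidence(config.coding_evidence)
        coding_junctions = compare.build_junction_index(
            reference, biotype_filter="protein_coding"
        )
        filt = identify.filter_novel_lncrnas(
            (assembly[a.query_id] for a in novel_assign),
            evidence,
            coding_junctions,
            cutoff,
            th.min_length,
        )
        _write_df(filt, out / "lncrna_filter.tsv", th)
        novel_lnc = set(filt.loc[filt.accepted, "transcript_id"])
        novel_report = identify.categorize_lncrnas(
            [a for a in novel_assign if a.query_id in novel_lnc]
        )

        # annotated lncRNAs are categorized against the protein-coding reference
        coding_ref = reference.subset(
            [t.transcript_id for t in reference if t.biotype == "protein_coding"]
        )
        annotated_assign = compare.classify_all(
            reference.subset(annotated_lnc_ids), coding_ref, th.run_on_distance
        )
        annotated_report = identify.categorize_lncrnas(annotated_assign)

        lnc_ids = novel_lnc | annotated_lnc_ids
        categories = {**novel_report.category_by_id, **annotated_report.category_by_id}
        summary["lncrna"] = {
            "n_novel": len(novel_lnc),
            "n_annotated": len(annotated_lnc_ids),
            "novel_counts": dict(novel_report.counts),
            "novel_proportions": novel_report.proportions,
            "novel_unclassified": novel_report.n_unclassified,
            "annotated_counts": dict(annotated_report.counts),
            "annotated_proportions": annotated_report.proportions,
        }
        cat_df = pd.DataFrame(
            sorted(categories.items()), columns=["transcript_id", "category"]
        )
        _write_df(cat_df, out / "lncrna_categories.tsv", th)
    except Exception as exc:
        if "identify" in config.stages:
            raise StageError("identify", exc) from exc

    lnc_models = {
        tid: (assembly.transcripts.get(tid) or reference.transcripts.get(tid))
        for tid in lnc_ids
    }

    # ------------------------------------------------------------ methylome
    if "methylome" in config.stages and config.m6a_tables:
        try:
            all_sites: list[m6a.M6ASite] = []
            for lib, path in sorted(config.m6a_tables.items()):
                if not Path(path).exists():
                    raise FileNotFoundError(f"m6a table not found: {path}")
                all_sites.extend(m6a.read_m6a_table(path, library_id=lib))
            kept = m6a.filter_sites(all_sites, th.min_reads)
            pooled = m6a.pool_sites(kept)
            methylated, unmethylated = m6a.call_methylated(pooled)
            summary["m6a"] = {
                "n_candidate_sites": len(pooled),
                "n_methylated_sites": len(methylated),
                "pct_methylated_sites": (
                    100.0 * len(methylated) / len(pooled) if pooled else 0.0
                ),
            }
            lnc_sites = [s for s in pooled if s.transcript_id in lnc_ids]
            mrna_ids = {t.transcript_id for t in reference if t.biotype == "protein_coding"}
            meth_tids = m6a.methylated_transcripts(pooled)
            summary["m6a"]["n_methylated_lncrnas"] = len(meth_tids & lnc_ids)
            summary["m6a"]["n_methylated_mrnas"] = len(meth_tids & mrna_ids)
            meth_lnc_sites = [s for s in lnc_sites if s.methylated]
            summary["m6a"]["aaach_fraction_lncrna"] = m6a.aaach_fraction(meth_lnc_sites)
            usage, rejects = m6a.motif_usage(meth_lnc_sites)
            usage.attrs["n_rejected"] = rejects
            _write_df(usage, out / "motif_usage_lncrna.tsv", th)

            # per-transcript M (all candidate sites, pooled over libraries)
            mtab = m6a.methylation_table(pooled, include_zero_sites=True)
            _write_df(mtab, out / "transcript_methylation.tsv", th)
            lnc_M = mtab[mtab.transcript_id.isin(lnc_ids)]["M"]
            mrna_M = mtab[mtab.transcript_id.isin(mrna_ids)]["M"]
            summary["m6a"]["median_M_lncrna"] = (
                float(lnc_M.median()) if len(lnc_M) else None
            )
            summary["m6a"]["median_M_mrna"] = (
                float(mrna_M.median()) if len(mrna_M) else None
            )

            lnc_ann = annotation.TranscriptomeAnnotation(
                {tid: t for tid, t in lnc_models.items() if t is not None}
            )
            dens = m6a.density_table(pooled, lnc_ann)
            _write_df(dens, out / "site_density_lncrna.tsv", th)
            summary["m6a"]["median_density_lncrna_per_100nt"] = (
                float(dens.per_100nt.median()) if len(dens) else None
            )
            prof = m6a.metagene_profile(
                [s for s in meth_lnc_sites], lnc_ann, mode="full"
            )
            _write_df(prof, out / "metagene_lncrna.tsv", th)
            prof_mrna = m6a.metagene_profile(
                [s for s in methylated if s.transcript_id in mrna_ids],
                reference,
                mode="mrna",
            )
            _write_df(prof_mrna, out / "metagene_mrna.tsv", th)

            # stage dynamics of M and stage-shared site sets
            if config.m6a_groups:
                by_lib = m6a.methylation_table(
                    kept, include_zero_sites=True, by_library=True
                )
                dm = m6a.differential_modification(by_lib, config.m6a_groups)
                _write_df(dm, out / "differential_modification.tsv", th)
                summary["m6a"]["n_differential_modification"] = len(dm)
                stage_sites: dict[str, set] = {"seedling": set(), "floral_bud": set()}
                for s in kept:
                    if s.methylated and s.transcript_id in lnc_ids:
                        stage_sites[config.m6a_groups[s.library_id]].add(
                            (s.transcript_id, s.position)
                        )
                venn = m6a.shared_site_partition(
                    stage_sites["seedling"], stage_sites["floral_bud"]
                )
                total = sum(venn.values())
                summary["m6a"]["stage_site_partition"] = {
                    "seedling_only": venn["a_only"],
                    "floral_only": venn["b_only"],
                    "shared": venn["shared"],
                    "pct_shared": 100.0 * venn["shared"] / total if total else 0.0,
                }
                summary["_dm_table"] = dm  # consumed by the dynamics stage

            if config.mutant_tables:
                wt_set = {
                    (s.transcript_id, s.position) for s in pooled if s.methylated
                }
                site_sets = {"wildtype": wt_set}
                for g, path in sorted(config.mutant_tables.items()):
                    msites = m6a.filter_sites(
                        m6a.read_m6a_table(path, library_id=g), th.min_reads
                    )
                    site_sets[g] = {
                        (s.transcript_id, s.position) for s in msites if s.methylated
                    }
                part = m6a.compare_genotypes(site_sets)
                summary["m6a"]["genotype_partition"] = part.counts()
        except StageError:
            raise
        except Exception as exc:
            raise StageError("methylome", exc) from exc

    # ---------------------------------------------------------------- polya
    if "polya" in config.stages and config.polya_tables and config.tpm is not None:
        try:
            reads: list[polya.PolyARead] = []
            for lib, path in sorted(config.polya_tables.items()):
                if not Path(path).exists():
                    raise FileNotFoundError(f"polya table not found: {path}")
                reads.extend(polya.read_polya_table(path, library_id=lib))
            tails = polya.tail_length_table(reads)
            _write_df(tails, out / "tail_lengths.tsv", th)
            tpm = pd.read_csv(config.tpm, sep="\t", comment="#", index_col=0)
            lnc_tpm = tpm.loc[[t for t in tpm.index if t in lnc_ids]]
            statuses = polya.classify_all(
                lnc_tpm,
                [r for r in reads if r.transcript_id in lnc_ids],
                th.tpm_threshold,
                th.min_tpm_samples,
            )
            polya.write_status_table(statuses, out / "polya_status.tsv")
            summary["polya"] = polya.polya_summary(statuses, categories)
            lnc_tails = tails[tails.transcript_id.isin(lnc_ids)]
            mrna_tails = tails[~tails.transcript_id.isin(lnc_ids)]
            summary["polya"]["median_tail_lncrna"] = (
                round(float(lnc_tails.mean_tail_length.median()), 2)
                if len(lnc_tails) else None
            )
            summary["polya"]["median_tail_mrna"] = (
                round(float(mrna_tails.mean_tail_length.median()), 2)
                if len(mrna_tails) else None
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("polya", exc) from exc

    # ------------------------------------------------------------- dynamics
    if "dynamics" in config.stages and config.counts is not None:
        try:
            counts = pd.read_csv(config.counts, sep="\t", comment="#", index_col=0)
            meta = pd.read_csv(config.sample_meta, sep="\t", comment="#")
            stage_of = dict(zip(meta.sample_id, meta.stage))
            cpm = expression.cpm_normalize(counts)
            lnc_cpm = cpm.loc[[t for t in cpm.index if t in lnc_ids]]
            expressed = expression.moderately_expressed(
                lnc_cpm, stage_of, th.cpm_threshold
            )
            sets, split = expression.stage_sets(
                expressed["seedling"], expressed["floral_bud"], annotated_lnc_ids
            )
            summary["dynamics"] = {
                "stage_sets": sets.counts(),
                "stage_split": split,
                "n_expressed_all_samples": len(expressed["all_samples"]),
            }
            de = expression.differential_expression(
                lnc_cpm,
                stage_of,
                universe=expressed["all_samples"],
                pseudo=th.pseudo_cpm,
                up_cut=th.up_cut,
                down_cut=th.down_cut,
            )
            _write_df(de, out / "differential_expression.tsv", th)
            summary["dynamics"]["n_up"] = int((de.call == "up").sum())
            summary["dynamics"]["n_down"] = int((de.call == "down").sum())
            dm = summary.pop("_dm_table", None)
            if dm is not None and len(de) and len(dm):
                d_ser = pd.Series(de.d.to_numpy(), index=de.transcript_id)
                dm_ser = pd.Series(dm.delta_M.to_numpy(), index=dm.transcript_id)
                joined = d_ser.index.intersection(dm_ser.index)
                if len(joined) >= 3:
                    rho, p, n = expression.correlate_expression_methylation(
                        d_ser[joined], dm_ser[joined]
                    )
                    summary["dynamics"]["expression_methylation_spearman"] = {
                        "rho": rho, "p": p, "n": n,
                    }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("dynamics", exc) from exc

    summary.pop("_dm_table", None)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
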