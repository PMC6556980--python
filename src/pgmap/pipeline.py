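"""End-to-end pipeline: six-frame database, PSM filtering, peptide mapping,
annotation-relative classification and summary reporting."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

from Bio import SeqIO

from . import __version__
from .annotation import parse_gff3, parse_gtf
from .mapping import filter_unique_locus, flag_annotated, map_peptides, write_locus_bed
from .models import DbBuildConfig
from .peptide_classes import AnnotationIndex, classify_all, summarize_novelty
from .psm import (DEFAULT_EVALUE_MAX, compute_fdr, fdr_report,
                  filter_pipeline, read_psm_table)
from .sixframe import make_decoy, read_fasta, segment_genome, write_partitioned_fasta
from .transcripts import assign_cxt_ids, classify_transcripts, exon_stats

log = logging.getLogger(__name__)


def read_genome_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_protein_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults are the standard study parameters: E-value threshold 0.01,
    600-aa segments with 60-aa overlap, 50 000 segments per FASTA file.
    """

    genome: str = ""
    annotation_a: str = ""
    annotation_b: str = ""
    proteins_a: str = ""
    proteins_b: str = ""
    psms: str = ""
    transcripts_gtf: str = ""
    outdir: str = "pgmap_out"
    evalue_max: float = DEFAULT_EVALUE_MAX
    seg_len: int = 600
    overlap: int = 60
    per_file: int = 50_000
    decoy_seed: int = 0
    label_a: str = "setA"
    label_b: str = "setB"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """key = value config file; flags override file values."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                k, v = (x.strip() for x in line.split("=", 1))
                kv[k] = v
        cfg = cls()
        for k, v in {**kv, **overrides}.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, bool):
                v = str(v).lower() in ("1", "true", "yes")
            elif isinstance(cur, int):
                v = int(v)
            elif isinstance(cur, float):
                v = float(v)
            setattr(cfg, k, v)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle into cfg.outdir.

    Outputs: partitioned six-frame DB plus decoy, per-tissue FDR table,
    accepted-peptide table, locus BED, cross-annotation novelty summary
    (with single-annotation collapse when annotation B is absent),
    transcript categories with CXT identifiers, and a manifest recording
    versions, seeds and parameters.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    name = stage("load-genome")
    try:
        genome = read_genome_fasta(cfg.genome)
        if not genome:
            raise ValueError(f"no sequences in {cfg.genome}")
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("load-annotations")
    try:
        ann_a = parse_gff3(cfg.annotation_a, dialect="ncbi-like")
        ann_b = parse_gff3(cfg.annotation_b, dialect="ensembl-like") \
            if cfg.annotation_b else None
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("build-sixframe-db")
    try:
        db_cfg = DbBuildConfig(seg_len=cfg.seg_len, overlap=cfg.overlap,
                               per_file=cfg.per_file, decoy_seed=cfg.decoy_seed)
        segs = list(segment_genome(genome, db_cfg))
        db_dir = os.path.join(cfg.outdir, "sixframe_db")
        paths = write_partitioned_fasta(segs, db_cfg, db_dir)
        decoy = make_decoy(read_fasta(paths[0]), db_cfg.decoy_seed)
        decoy_path = os.path.join(db_dir, "decoy_part001.fasta")
        with open(decoy_path, "w") as fh:
            for h, s in decoy:
                fh.write(f">{h}\n{s}\n")
        report["n_segments"] = len(segs)
        report["n_db_files"] = len(paths)
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("filter-psms")
    try:
        psms = read_psm_table(cfg.psms)
        hits = filter_pipeline(psms, cfg.evalue_max)
        targets = [h for h in hits if not h.is_decoy]
        decoys = [h for h in hits if h.is_decoy]
        fdr_df = fdr_report(psms, cfg.evalue_max)
        fdr_df.to_csv(os.path.join(cfg.outdir, "fdr_by_tissue.tsv"),
                      sep="\t", index=False)
        report["n_accepted_peptide_hits"] = len(targets)
        report["n_decoy_peptide_hits"] = len(decoys)
        report["fdr_pct_overall"] = (compute_fdr(len(targets), len(decoys))
                                     if targets else None)
        import pandas as pd
        pd.DataFrame([{"tissue": h.tissue, "peptide": h.peptide,
                       "n_spectra": len(h.spectra),
                       "n_engines": len(h.engines),
                       "best_evalue": h.best_evalue} for h in targets]
                     ).to_csv(os.path.join(cfg.outdir, "accepted_peptides.tsv"),
                              sep="\t", index=False)
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("map-peptides")
    try:
        peptides = sorted({h.peptide for h in targets})
        prot_sets = {}
        if cfg.proteins_a:
            prot_sets[cfg.label_a] = read_protein_fasta(cfg.proteins_a)
        if cfg.proteins_b:
            prot_sets[cfg.label_b] = read_protein_fasta(cfg.proteins_b)
        annotated, novel = flag_annotated(peptides, prot_sets)
        result = map_peptides(sorted(novel), genome)
        unique = filter_unique_locus(result.loci)
        write_locus_bed(result.loci, os.path.join(cfg.outdir, "peptide_loci.tsv"))
        report["n_peptides"] = len(peptides)
        report["n_annotated_peptides"] = len(annotated)
        report["n_novel_peptides"] = len(novel)
        report["n_novel_single_locus"] = len(unique)
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("classify-peptides")
    try:
        idx_a = AnnotationIndex(ann_a)
        idx_b = AnnotationIndex(ann_b) if ann_b is not None else idx_a
        triples = classify_all(unique, idx_a, idx_b)
        summary = summarize_novelty([(ca, cb) for _, ca, cb in triples],
                                   label_a=cfg.label_a, label_b=cfg.label_b)
        frame = summary.to_frame()
        if ann_b is None:
            # single-annotation mode: the cross-tab collapses to one column
            frame = frame[["category", "both", "total"]].rename(
                columns={"both": cfg.label_a})
        frame.to_csv(os.path.join(cfg.outdir, "novelty_summary.tsv"),
                     sep="\t", index=False)
        report["novelty_row_totals"] = {c: summary.row_total(c)
                                        for c in summary.counts}
        report["novelty_grand_total"] = summary.grand_total
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    if cfg.transcripts_gtf:
        name = stage("classify-transcripts")
        try:
            asm = parse_gtf(cfg.transcripts_gtf)
            cats = classify_transcripts(asm.transcripts(), ann_a)
            novel_txs = [t for t in asm.transcripts()
                         if cats[t.id] != "matches_annotated"]
            cxt = assign_cxt_ids(novel_txs)
            stats = exon_stats(list(asm.transcripts()),
                               {tid: c for tid, c in cats.items()})
            import pandas as pd
            pd.DataFrame([{"transcript_id": t.id,
                           "cxt_id": cxt.get(t.id, ""),
                           "category": cats[t.id],
                           "n_exons": t.n_exons}
                          for t in asm.transcripts()]
                         ).to_csv(os.path.join(cfg.outdir,
                                               "transcript_categories.tsv"),
                                  sep="\t", index=False)
            report["transcript_category_counts"] = {
                c: sum(1 for v in cats.values() if v == c) for c in set(cats.values())}
            report["mean_exons_by_category"] = stats
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    manifest = {"pgmap_version": __version__, "config": asdict(cfg),
                "report": report}
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
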