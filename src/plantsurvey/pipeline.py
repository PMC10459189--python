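"""Survey pipeline orchestration: QC -> organelle filtering -> k-mer
spectrum -> (optional) GC-depth screen -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__, gc_depth, kmer_survey, organelle_filter, readqc, report
from .config import PipelineConfig
from .reads import ReadSet, read_fasta

log = logging.getLogger("plantsurvey")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineInputs:
    reads1: str | Path
    reads2: str | Path | None = None
    organelle_refs: str | Path | None = None
    contigs: str | Path | None = None


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> report.SurveyReport:
    """Run the survey stages in order, writing every stage's outputs under
    the configured output directory.  A stage failure raises
    :class:`StageError` naming the stage; earlier outputs are retained."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "params.yaml")
    log.info("plantsurvey %s, seed %d, outputs in %s", __version__, config.seed, outdir)
    notes: list[str] = []

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    def _qc():
        log.info("stage qc")
        r1 = ReadSet.from_fastq(inputs.reads1)
        if inputs.reads2 is not None:
            r2 = ReadSet.from_fastq(inputs.reads2)
            c1, c2, stats, _ = readqc.qc_pairs(r1, r2, config.qc)
            sets = [c1, c2]
        else:
            keep, trimmed = readqc.qc_readset(r1, config.qc)
            c1 = trimmed.subset(keep)
            stats = readqc.QCStats(
                raw_bases=r1.n_bases,
                clean_bases=c1.n_bases,
                reads_in=r1.n_reads,
                reads_out=c1.n_reads,
            )
            stats.raw_q20_pct, stats.raw_q30_pct = readqc._q_pcts(
                r1.qual_matrix().ravel()
            )
            stats.q20_pct, stats.q30_pct = readqc._q_pcts(c1.qual_matrix().ravel())
            sets = [c1]
        stats.to_json(outdir / "qc_stats.json")
        return sets, stats

    clean_sets, qc_stats = stage("qc")(_qc)

    removal = None
    nuclear_sets = clean_sets
    if inputs.organelle_refs is not None:

        def _filter():
            log.info("stage filter-organelle")
            read_len = clean_sets[0].read_len if clean_sets else 150
            index = organelle_filter.build_organelle_index(
                inputs.organelle_refs, read_len=read_len
            )
            masks, _, stats = organelle_filter.partition_readsets(
                clean_sets, index, config.rule
            )
            stats.to_json(outdir / "organelle_removal.json")
            return [rs.subset(~m) for rs, m in zip(clean_sets, masks)], stats

        nuclear_sets, removal = stage("filter-organelle")(_filter)
    else:
        notes.append(
            "unfiltered: no organelle references supplied; the k-mer spectrum "
            "includes any organelle-derived reads"
        )

    def _kmer_all():
        log.info("stage kmer")
        import numpy as np

        mats = [rs.codes for rs in nuclear_sets]
        mat = np.concatenate(mats) if len(mats) > 1 else mats[0]
        hist = kmer_survey.count_kmers(mat, k=config.k)
        hist.to_tsv(outdir / "kmer_hist.tsv")
        fit = kmer_survey.fit_spectrum(hist)
        fit.to_json(outdir / "spectrum_fit.json")
        kmer_survey.plot_spectrum(hist, fit, outdir / "spectrum.png")
        return fit

    fit = stage("kmer")(_kmer_all)

    centers = None
    if inputs.contigs is not None:

        def _gcdepth():
            log.info("stage gcdepth")
            contigs = read_fasta(inputs.contigs)
            depths = gc_depth.map_depths(nuclear_sets, contigs, seed=config.seed)
            table = gc_depth.gc_depth_table(contigs, depths, config.min_contig_len)
            gc_depth.table_to_frame(table).to_csv(
                outdir / "gc_depth.tsv", sep="\t", index=False
            )
            rep = gc_depth.detect_centers(
                table,
                gc_bin_width=config.gc_bin_width,
                depth_bin_width=config.depth_bin_width,
                min_cluster_fraction=config.min_cluster_fraction,
                gc_flag_threshold=config.gc_flag_threshold,
            )
            rep.to_json(outdir / "gc_depth_centers.json")
            gc_depth.plot_gc_depth(table, outdir / "gc_depth.png")
            return rep

        centers = stage("gcdepth")(_gcdepth)

    def _report():
        log.info("stage report")
        rep = report.build_report(
            qc=qc_stats,
            organelle_removal=removal,
            spectrum=fit,
            gc_depth=centers,
            notes=notes,
        )
        rep.to_json(outdir / "report.json")
        (outdir / "report.txt").write_text(rep.render_text())
        return rep

    return stage("report")(_report)
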