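"""End-to-end report assembly: ingest -> subtract -> scan -> proximity ->
annotate -> statistics, with every stage logged and written to the bundle.

The bundle is deterministic given the configuration and seed; any stage
error aborts with the stage name and the offending input.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import annotate as ann
from . import demux as dmx
from . import ingest, proximity, stats
from .config import RunConfig
from .offtargets import SpacerQuery, scan_cas9, write_hits_bed, write_hits_tsv
from .records import CloneRecord, GroupCounts, PoolDesign

log = logging.getLogger("editaudit")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(cfg: RunConfig):
    genome, gb_annotation = ingest.read_genome(cfg.genome)
    log.info("genome %s: %d bp, circular=%s", genome.name, len(genome),
             genome.circular)
    annotation = gb_annotation
    if cfg.annotation:
        annotation = ingest.read_annotation_gff3(
            cfg.annotation, len(genome), genome.circular
        )
        log.info("annotation: %d features", len(annotation.features))
    clones = []
    for spec in cfg.mutation_tables:
        records = ingest.read_mutation_table(spec.path, cfg.min_read_fraction)
        unintended = ingest.subtract_known(
            records,
            [tuple(m) for m in cfg.parental_mutations],
            [tuple(m) for m in cfg.intended_edits],
        )
        log.info(
            "table %s (%s): %d calls above floor, %d unintended",
            spec.path, spec.group_label, len(records), len(unintended),
        )
        clones.append(
            CloneRecord(
                clone_id=spec.sample_id or Path(spec.path).stem,
                group_label=spec.group_label,
                intended_edit_position=spec.intended_edit_position,
                spacer_id=spec.spacer_id,
                unintended_mutations=list(unintended),
            )
        )
    ingest.flag_recurrent(clones)
    return genome, annotation, clones


@_stage("demux")
def _demux(cfg: RunConfig, clones, outdir: Path):
    reports = []
    for raw in cfg.pool_designs:
        design = PoolDesign(
            pool_id=raw["pool_id"],
            members=[tuple(m) for m in raw["members"]],
            tolerance=raw.get("tolerance", 0.25),
        )
        pooled = [
            m for c in clones if c.clone_id == design.pool_id
            for m in c.unintended_mutations
        ]
        assignments = dmx.assign_mutations(pooled, design)
        path = outdir / f"demux_{design.pool_id}.tsv"
        dmx.write_assignment_report(assignments, path)
        reports.append(str(path))
        log.info("pool %s: %d mutations demultiplexed", design.pool_id,
                 len(assignments))
    return reports


@_stage("scan")
def _scan(cfg: RunConfig, genome, outdir: Path):
    hits_by_spacer = {}
    for spacer_id, spacer in cfg.spacers.items():
        query = SpacerQuery(
            spacer=spacer,
            pam_pattern=cfg.pam_pattern,
            max_mismatch_plus_gap=cfg.max_mismatch_plus_gap,
            max_gaps=cfg.max_gaps,
        )
        hits = scan_cas9(genome, query)
        hits_by_spacer[spacer_id] = hits
        write_hits_bed(hits, genome, outdir / f"offtargets_{spacer_id}.bed",
                       name=spacer_id)
        write_hits_tsv(hits, outdir / f"offtargets_{spacer_id}.tsv")
        log.info("spacer %s: %d candidate off-target sites", spacer_id, len(hits))
    return hits_by_spacer


@_stage("proximity")
def _proximity(cfg: RunConfig, genome, clones, hits_by_spacer, outdir: Path):
    summaries = {}
    for spacer_id, hits in hits_by_spacer.items():
        muts = [
            m
            for c in clones
            if c.spacer_id == spacer_id
            for m in c.unintended_mutations
        ]
        if not muts or not hits:
            continue
        edit_positions = {
            m.sample_id: c.intended_edit_position
            for c in clones if c.spacer_id == spacer_id
            and c.intended_edit_position is not None
            for m in c.unintended_mutations
        }
        results, mean_bp, n_within = proximity.nearest_offtarget(
            muts, hits, len(genome), within=cfg.proximity_within,
            intended_edit_positions=edit_positions,
        )
        proximity.write_proximity_tsv(results, outdir / f"proximity_{spacer_id}.tsv")
        hist = proximity.histogram_1kb(results)
        proximity.write_summary_json(
            outdir / f"proximity_{spacer_id}.json", mean_bp, n_within,
            cfg.proximity_within, len(muts), hist,
        )
        summaries[spacer_id] = {
            "n_mutations": len(muts),
            "mean_distance_kb": proximity.mean_distance_kb(mean_bp),
            "n_within": n_within,
        }
        log.info(
            "spacer %s: mean distance %d kb, %d/%d within %d bp",
            spacer_id, proximity.mean_distance_kb(mean_bp), n_within,
            len(muts), cfg.proximity_within,
        )
    return summaries


@_stage("annotate")
def _annotate(cfg: RunConfig, genome, annotation, clones, outdir: Path):
    if annotation is None:
        log.info("no annotation supplied; skipping classification")
        return None
    records = [m for c in clones for m in c.unintended_mutations]
    if not records:
        return None
    annotations = [ann.classify_mutation(m, annotation, genome) for m in records]
    ann.write_annotated_tsv(records, annotations, outdir / "annotations.tsv")
    return ann.spectrum_summary(records, annotations)


@_stage("stats")
def _stats(cfg: RunConfig, genome, clones):
    groups = stats.group_summary(clones)
    ordered = sorted(groups.values(), key=lambda g: g.label)
    null = stats.NullModel(mu_nt=cfg.mu_nt, genome_length=len(genome))
    report = {
        "groups": {
            g.label: {
                "n_clones": g.n_clones,
                "n_with_mutation": g.n_with_mutation,
                "percent": g.percent,
            }
            for g in ordered
        },
        "null_model": {
            "mu_nt": cfg.mu_nt,
            "mu_genome": stats.round_sig(null.mu_genome, 2),
            "generations": cfg.generations,
            "model": cfg.null_model,
            "expected_fraction": null.expected_fraction(
                cfg.generations, cfg.null_model
            ),
        },
    }
    if len(ordered) >= 2:
        result = stats.marascuilo(ordered, alpha=cfg.alpha)
        report["chi_square"] = {
            "chi2": result.chi2, "df": result.df, "p_value": result.p_value,
        }
        report["marascuilo"] = [
            {
                "pair": [p.label_i, p.label_j],
                "abs_difference": p.abs_difference,
                "critical_range": p.critical_range,
                "significant": p.significant,
                "min_alpha": p.min_alpha,
            }
            for p in result.pairs
        ]
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under cfg.output_dir."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, clones = _ingest(cfg)

    # unintended-mutation table across all samples
    all_unintended = [m for c in clones for m in c.unintended_mutations]
    ingest.write_mutation_table(all_unintended, outdir / "unintended_mutations.tsv")

    demux_reports = _demux(cfg, clones, outdir)
    hits_by_spacer = _scan(cfg, genome, outdir)
    proximity_summaries = _proximity(cfg, genome, clones, hits_by_spacer, outdir)
    spectrum = _annotate(cfg, genome, annotation, clones, outdir)
    stats_report = _stats(cfg, genome, clones)

    report = {
        "genome": {"name": genome.name, "length": len(genome),
                   "circular": genome.circular},
        "n_samples": len(clones),
        "n_unintended_mutations": len(all_unintended),
        "offtargets": {k: len(v) for k, v in hits_by_spacer.items()},
        "proximity": proximity_summaries,
        "spectrum": spectrum,
        "stats": stats_report,
        "demux_reports": demux_reports,
        "seed": cfg.seed,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report
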