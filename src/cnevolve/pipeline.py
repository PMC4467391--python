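"""End-to-end orchestration: counts -> log2 -> BAF -> segments -> events -> progression."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import tables
from .baf import baf_track, segment_folded_baf
from .config import PipelineConfig
from .events import Thresholds, call_events, assign_ocl
from .progression import SampleEventSet, classify_progression, ProgressionReport
from .segment import merge_adjacent, segment_track
from .windows import compute_log2, recenter_baseline

log = logging.getLogger("cnevolve")

__all__ = ["PipelineError", "analyze_sample", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def analyze_sample(
    counts: pd.DataFrame,
    snps: pd.DataFrame | None,
    purity: float,
    min_probes: int = 10,
    penalty: float | None = None,
    merge_tol: float = 0.1,
    min_snp_depth: int = 30,
    thresholds: Thresholds | None = None,
    sample: str | None = None,
):
    """Run the per-sample copy-number stages on in-memory tables.

    Returns (track, segments, events).  ``snps`` may be ``None``, in which
    case the baseline is left on the coverage median and event clonality is
    indeterminate.
    """
    track = compute_log2(counts)
    sites = None
    if snps is not None and len(snps):
        sites = baf_track(snps, min_depth=min_snp_depth)
        track = recenter_baseline(track, sites, min_probes=min_probes)
    segs = segment_track(track.data, min_probes=min_probes, penalty=penalty)
    if sites is not None:
        segs = segment_folded_baf(segs, sites)
    segs = merge_adjacent(segs, tol=merge_tol)
    events = call_events(segs, purity=purity, thresholds=thresholds, sample=sample)
    return track, segs, events


def run_pipeline(config: PipelineConfig) -> ProgressionReport:
    """Execute the full multi-sample pipeline from a config.

    Every intermediate table is written under ``config.outdir``; the
    progression report (JSON + text summary) ties the stages together.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: %d samples, seed %d", len(config.samples), config.seed)

    th = Thresholds(loss_log2=config.loss_log2, gain_log2=config.gain_log2)
    sets: list[SampleEventSet] = []
    for s in config.samples:
        try:
            counts = tables.read_window_counts(s.counts)
        except Exception as exc:
            raise PipelineError("windows", f"sample {s.name}: {exc}") from exc
        snps = None
        if s.snps:
            try:
                snps = tables.read_snp_table(s.snps)
            except Exception as exc:
                raise PipelineError("baf", f"sample {s.name}: {exc}") from exc
        try:
            track, segs, events = analyze_sample(
                counts, snps, s.purity,
                min_probes=config.min_probes, penalty=config.penalty,
                merge_tol=config.merge_tol, min_snp_depth=config.min_snp_depth,
                thresholds=th, sample=s.name,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("segmentation", f"sample {s.name}: {exc}") from exc
        tables.write_window_counts(track.data, outdir / f"{s.name}.log2.tsv")
        segs.to_csv(outdir / f"{s.name}.segments.tsv", sep="\t", index=False)
        sets.append(SampleEventSet(s.name, events))
        log.info("sample %s: %d segments, %d events", s.name, len(segs), len(events))

    # one-copy losses on previously amplified territory need earlier stages
    for k, st in enumerate(sets):
        earlier_gains = [e for prev in sets[:k] for e in prev.events if e.is_gain]
        assign_ocl(st.events, earlier_gains)

    try:
        report = classify_progression(sets, bp_tol=config.bp_tol)
    except Exception as exc:
        raise PipelineError("progression", str(exc)) from exc
    tables.write_event_table(sets, outdir / "events.tsv")
    report.to_json(outdir / "progression.json")
    (outdir / "progression.txt").write_text(report.summary() + "\n")

    if config.snv_table:
        from .snv import filter_somatic, presence_matrix, detect_purification

        try:
            calls = tables.read_variant_table(config.snv_table)
            retained, rejected = filter_somatic(calls)
            _, patterns = presence_matrix(retained)
            snv_doc = {"n_retained": int(len(retained)), "patterns": patterns}
            if len(config.samples) >= 2:
                early = config.samples[-2].name
                late = config.samples[-1].name
                flags = detect_purification(
                    retained, early, late,
                    subclonal_band=config.subclonal_band,
                    clonal_band=config.clonal_band,
                )
                snv_doc["purified"] = int(flags.sum())
            retained.to_csv(outdir / "snv.filtered.tsv", sep="\t", index=False)
            (outdir / "snv.json").write_text(json.dumps(snv_doc, indent=2))
        except Exception as exc:
            raise PipelineError("snv", str(exc)) from exc

    run_doc = {
        "seed": config.seed,
        "stages": config.stage_order,
        "parameters": {
            "reads_per_window": config.reads_per_window,
            "min_probes": config.min_probes,
            "penalty": config.penalty,
            "bp_tol": config.bp_tol,
        },
        "verdict": report.verdict,
    }
    (outdir / "run.json").write_text(json.dumps(run_doc, indent=2))
    return report
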