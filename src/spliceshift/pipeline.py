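"""End-to-end orchestration: simulate -> infer -> quantify -> screen -> classify.

A run is a pure function of its inputs and seed: the same configuration and
seed reproduce the same outputs.  Every filtering stage logs its input and
output cardinality, and all stage outputs are written as TSV (plus a BED
track of alternative ends for genome-browser inspection and a JSON summary
whose per-event-class counts mirror the screen's headline table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import (
    CountMatrix,
    Genome,
    Intron,
    build_count_matrix,
    introns_of,
    read_fasta,
    read_gtf,
    read_junction_table,
    read_retention_table,
    ValidationError,
)
from .junction_motifs import DEFAULT_ALLOWED, MotifClass, filter_by_motif
from .event_inference import (
    SpliceEvent,
    attach_counts,
    infer_annotation_events,
    infer_de_novo_alt_ends,
)
from .psi_quant import PsiMatrix, psi_matrix
from .delta_psi_screen import ScreenConfig, ScreenResult, screen
from .shift_and_logo import (
    ShiftCall,
    build_pfm,
    classify_shift,
    intron_length_summary,
    shift_histogram,
)
from .synthetic_data import (
    SimulationConfig,
    ToyReference,
    default_planted_events,
    make_toy_reference,
    simulate_junction_tables,
)

logger = logging.getLogger("spliceshift")

EVENT_CLASS_ORDER = ("A5", "A3", "SE", "RI", "MS", "MX", "AF", "AL")


@dataclass
class PipelineConfig:
    """One reproducible run: either real input paths or a simulation config."""

    outdir: Path
    seed: int = 0
    # real inputs (all four required together)
    genome_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    junction_paths: Optional[dict[str, Path]] = None  # sample_id -> table
    retention_path: Optional[Path] = None
    # or a simulation
    simulation: Optional[SimulationConfig] = None
    # sample manifest
    control_samples: Sequence[str] = ()
    mutant_samples: Sequence[str] = ()
    # thresholds (screen defaults: 5 reads, 50 nt, 0.15, 0.20, all pairs)
    min_support: int = 5
    max_span: int = 50
    count_policy: str = "unique_only"
    allowed_motifs: frozenset = DEFAULT_ALLOWED
    screen_config: ScreenConfig = field(default_factory=ScreenConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        have_real = self.genome_path is not None
        have_sim = self.simulation is not None
        if have_real == have_sim:
            raise ValidationError(
                "exactly one of real inputs or a simulation config must be supplied"
            )
        overlap = set(self.control_samples) & set(self.mutant_samples)
        if overlap:
            raise ValidationError(f"control and mutant groups overlap: {sorted(overlap)}")


@dataclass
class PipelineResult:
    outdir: Path
    events: list[SpliceEvent]
    psi: PsiMatrix
    screen_results: list[ScreenResult]
    shift_calls: list[ShiftCall]
    summary: dict


# ---------------------------------------------------------------------------
# Stage-output serialization
# ---------------------------------------------------------------------------


def _fmt_form(junctions: frozenset[Intron]) -> str:
    return ";".join(f"{j.start}-{j.end}" for j in sorted(junctions))


def write_events_tsv(events: Sequence[SpliceEvent], path: Path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "gene_id": e.gene_id or "",
            "form1_junctions": _fmt_form(e.form1_junctions),
            "form2_junctions": _fmt_form(e.form2_junctions),
            "retention_intron": (
                f"{e.form1_retention_intron.start}-{e.form1_retention_intron.end}"
                if e.form1_retention_intron
                else ""
            ),
            "shared_end": e.shared_end if e.shared_end is not None else "",
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_alt_ends_bed(events: Sequence[SpliceEvent], path: Path) -> None:
    """BED track of the alternative ends of A5/A3 events (browser inspection)."""
    with open(path, "w") as fh:
        for e in events:
            if e.event_type not in {"A5", "A3"}:
                continue
            for label, form in (("form1", e.form1_junctions), ("form2", e.form2_junctions)):
                for j in sorted(form):
                    pos = j.donor_pos if e.event_type == "A5" else j.acceptor_pos
                    fh.write(
                        f"{e.chrom}\t{pos - 1}\t{pos}\t{e.event_id}|{label}\t0\t{e.strand}\n"
                    )


def write_screen_tsv(results: Sequence[ScreenResult], path: Path) -> None:
    rows = [
        {
            "event_id": r.event_id,
            "pair_sum": r.pair_sum,
            "mean_delta_psi": round(r.mean_delta, 4),
            "direction": r.direction,
            "passes": r.passes,
            "deltas": ",".join(f"{d:.4f}" for d in r.deltas),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_shift_calls_tsv(calls: Sequence[ShiftCall], path: Path) -> None:
    rows = [
        {
            "event_id": c.event_id,
            "offset_nt": c.offset_nt,
            "shift_class": c.shift_class,
            "in_frame": c.in_frame,
            "predominant_start_kmer": c.predominant_start_kmer,
            "promoted_start_dinucleotide": c.promoted_start_dinucleotide,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "offset_nt",
            "shift_class",
            "in_frame",
            "predominant_start_kmer",
            "promoted_start_dinucleotide",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all stages and write every stage output under ``cfg.outdir``.

    A MANIFEST file lists the outputs; if a stage fails, partial outputs are
    retained and the MANIFEST records the incompleteness before the exception
    propagates.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    manifest_path = outdir / "MANIFEST"

    def note(name: str) -> None:
        manifest.append(name)
        manifest_path.write_text("\n".join(manifest) + "\n")

    try:
        result = _run_stages(cfg, outdir, note)
    except Exception:
        manifest.append("INCOMPLETE: pipeline failed after the outputs above")
        manifest_path.write_text("\n".join(manifest) + "\n")
        raise
    note("MANIFEST")
    return result


def _run_stages(cfg: PipelineConfig, outdir: Path, note) -> PipelineResult:
    # --- inputs -----------------------------------------------------------
    if cfg.simulation is not None:
        sim = cfg.simulation
        inputs = outdir / "inputs"
        ref = make_toy_reference(sim, outdir=inputs)
        simulate_junction_tables(ref, sim, outdir=inputs)
        note("inputs/genome.fa")
        note("inputs/annotation.gtf")
        note("inputs/truth.tsv")
        genome_path = inputs / "genome.fa"
        annotation_path = inputs / "annotation.gtf"
        samples = [f"control_{i+1}" for i in range(sim.n_replicates)] + [
            f"mutant_{i+1}" for i in range(sim.n_replicates)
        ]
        junction_paths = {s: inputs / "junctions" / f"{s}.sj.tab" for s in samples}
        retention_path = inputs / "retention.tsv"
        control_samples = list(cfg.control_samples) or [
            s for s in samples if s.startswith("control")
        ]
        mutant_samples = list(cfg.mutant_samples) or [
            s for s in samples if s.startswith("mutant")
        ]
    else:
        genome_path = cfg.genome_path
        annotation_path = cfg.annotation_path
        junction_paths = cfg.junction_paths or {}
        retention_path = cfg.retention_path
        control_samples = list(cfg.control_samples)
        mutant_samples = list(cfg.mutant_samples)

    genome = read_fasta(genome_path)
    transcripts = read_gtf(annotation_path)
    logger.info("loaded %d chromosomes, %d transcripts",
                len(genome.sequences), len(transcripts))

    records = []
    for sample, path in junction_paths.items():
        records.extend(read_junction_table(path, sample))
    logger.info("junction records read: %d", len(records))

    kept = filter_by_motif(records, genome, allowed=cfg.allowed_motifs)
    logger.info("motif filter: %d -> %d records", len(records), len(kept))

    samples = list(junction_paths)
    matrix = build_count_matrix(kept, samples, count_policy=cfg.count_policy)

    retention = None
    if retention_path is not None and Path(retention_path).exists():
        retention = read_retention_table(retention_path)

    # --- event inference --------------------------------------------------
    a5 = infer_de_novo_alt_ends(matrix, "A5", genome=genome,
                                min_support=cfg.min_support, max_span=cfg.max_span)
    a3 = infer_de_novo_alt_ends(matrix, "A3", genome=genome,
                                min_support=cfg.min_support, max_span=cfg.max_span)
    annot = infer_annotation_events(transcripts)
    logger.info("events: %d de novo A5, %d de novo A3, %d annotation-derived",
                len(a5), len(a3), len(annot))

    events: dict[tuple, SpliceEvent] = {}
    for ev in [*a5, *a3, *annot]:
        events.setdefault(ev.forms_key(), ev)
    event_list = list(events.values())
    logger.info("events after dedup: %d", len(event_list))
    write_events_tsv(event_list, outdir / "events.tsv")
    note("events.tsv")
    write_alt_ends_bed(event_list, outdir / "alt_ends.bed")
    note("alt_ends.bed")

    # --- PSI --------------------------------------------------------------
    qevents = attach_counts(event_list, matrix, retention=retention)
    logger.info("quantifiable events: %d of %d", len(qevents), len(event_list))
    psi = psi_matrix(qevents)
    psi.write_tsv(outdir / "psi.tsv")
    note("psi.tsv")

    # --- screen -----------------------------------------------------------
    results = screen(psi, control_samples, mutant_samples, cfg.screen_config)
    passing = [r for r in results if r.passes]
    logger.info("screen: %d events evaluated, %d pass", len(results), len(passing))
    write_screen_tsv(results, outdir / "screen_results.tsv")
    note("screen_results.tsv")

    # --- shift classification --------------------------------------------
    by_id = {e.event_id: e for e in event_list}
    calls: list[ShiftCall] = []
    predominant_introns: list[Intron] = []
    promoted_introns: list[Intron] = []
    for r in passing:
        ev = by_id[r.event_id]
        if ev.event_type not in {"A5", "A3"}:
            continue
        control_psi = [psi.psi.loc[r.event_id, s] for s in control_samples]
        try:
            call = classify_shift(ev, r, genome, control_psi)
        except ValidationError as exc:
            logger.warning("event %s not classifiable: %s", r.event_id, exc)
            continue
        calls.append(call)
        (j1,) = ev.form1_junctions
        (j2,) = ev.form2_junctions
        pred = j1 if float(np.nanmean(control_psi)) >= 0.5 else j2
        prom = j1 if r.mean_delta > 0 else j2
        predominant_introns.append(pred)
        promoted_introns.append(prom)
    write_shift_calls_tsv(calls, outdir / "shift_calls.tsv")
    note("shift_calls.tsv")

    # --- logos and length summaries ---------------------------------------
    background_introns = sorted(
        {i for t in transcripts for i in introns_of(t)}
    )
    pfm_out = {}
    if background_introns:
        pfm_out["background_donor"] = build_pfm(background_introns, genome, side="donor")
    if predominant_introns:
        pfm_out["predominant_donor"] = build_pfm(predominant_introns, genome, side="donor")
    if promoted_introns:
        pfm_out["promoted_donor"] = build_pfm(promoted_introns, genome, side="donor")
    for name, pfm in pfm_out.items():
        pfm.write_tsv(outdir / f"pfm_{name}.tsv")
        pfm.write_transfac(outdir / f"pfm_{name}.transfac", name=name)
        note(f"pfm_{name}.tsv")

    slip_introns = [
        i for i, c in zip(predominant_introns, calls) if c.shift_class == "SLIP_UU"
    ]
    other_introns = [
        i for i, c in zip(predominant_introns, calls) if c.shift_class != "SLIP_UU"
    ]
    lengths = intron_length_summary(
        {
            "all_annotated": background_introns,
            "affected_slip_uu": slip_introns,
            "affected_other": other_introns,
        }
    )
    lengths.to_csv(outdir / "intron_length_summary.tsv", sep="\t", index=False)
    note("intron_length_summary.tsv")

    # --- summary ----------------------------------------------------------
    passing_by_class = {c: 0 for c in EVENT_CLASS_ORDER}
    for r in passing:
        passing_by_class[by_id[r.event_id].event_type] += 1
    calls_by_class: dict[str, int] = {}
    for c in calls:
        calls_by_class[c.shift_class] = calls_by_class.get(c.shift_class, 0) + 1
    summary = {
        "seed": cfg.seed,
        "n_samples": len(samples),
        "n_junction_records": len(records),
        "n_records_after_motif_filter": len(kept),
        "n_events": len(event_list),
        "n_events_quantified": len(qevents),
        "n_events_screened": len(results),
        "n_events_passing": len(passing),
        "passing_by_event_class": passing_by_class,
        "shift_calls_by_class": calls_by_class,
        "shift_offset_histogram": {str(k): v for k, v in shift_histogram(calls).items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    note("summary.json")

    return PipelineResult(
        outdir=outdir,
        events=event_list,
        psi=psi,
        screen_results=results,
        shift_calls=calls,
        summary=summary,
    )


def demo_config(outdir: str | Path, seed: int = 7) -> PipelineConfig:
    """The single-command demonstration run: simulation with every template."""
    sim = SimulationConfig(seed=seed, planted_events=default_planted_events())
    return PipelineConfig(outdir=Path(outdir), seed=seed, simulation=sim)
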