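"""Synthetic genomes, annotations and junction tables with planted splicing events.

The generator emulates the statistical structure the screen assumes:

* a toy genome whose genes carry exon/intron structures with intron lengths
  drawn from a two-component log-normal mixture (short mode with median
  ~47 nt, long mode with median ~500 nt), mirroring the strongly bimodal
  intron-length distribution of compact metazoan genomes;
* planted alternative-splicing events whose donor/acceptor sequence contexts
  are written into the genome (e.g. a GTTAAG donor for the +1 slip template,
  so the promoted intron starts TT);
* replicate junction count tables for a control and a mutant condition:
  per event and library, total depth is Poisson, and the form-1 count is
  beta-binomial with the planted true PSI as its mean and overdispersion
  ``rho`` (``rho = 0`` reduces to binomial);
* background (non-event) junctions at ``background_per_event`` times the
  number of planted events, so screen filters face realistic negatives.

Outputs are exactly the formats :mod:`spliceshift.io_formats` reads, plus a
``truth.tsv`` listing every planted event with its true PSI values.  All
randomness flows from ``SimulationConfig.seed``; a fixed seed reproduces the
output files byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Genome,
    Intron,
    JunctionRecord,
    TranscriptModel,
    ValidationError,
    introns_of,
    write_fasta,
    write_gtf,
    write_junction_table,
)
from .junction_motifs import MotifClass, motif_of

TEMPLATES = ("A5_slipUU", "A5_GUshift", "A3_upstream_inframe", "SE", "RI", "null")

_DEFAULT_DONOR_CONTEXT = {
    "A5_slipUU": "GTTAAG",   # promoted +1 donor starts TT
    "A5_GUshift": "GTGTAA",  # promoted +2 donor starts GT
    "null": "GTAAGT",        # second GT donor at +4, no planted effect
}

#: (motif class, strand) -> junction-table motif code
_MOTIF_TO_CODE = {
    (MotifClass.GT_AG, "+"): 1,
    (MotifClass.GT_AG, "-"): 2,
    (MotifClass.GC_AG, "+"): 3,
    (MotifClass.GC_AG, "-"): 4,
    (MotifClass.TT_AG, "+"): 5,
    (MotifClass.TT_AG, "-"): 6,
}


@dataclass(frozen=True)
class PlantedEvent:
    """One planted event: a template, true PSI per condition, donor context.

    ``psi_control``/``psi_mutant`` are the true form-1 PSI values (form 1 is
    the promoted/inclusion form).  ``donor_context`` overrides the template's
    default intron-start k-mer written into the genome.
    """

    template: str
    psi_control: float = 0.05
    psi_mutant: float = 0.35
    donor_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValidationError(f"unknown template {self.template!r}")
        for p in (self.psi_control, self.psi_mutant):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"PSI {p} outside [0,1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    planted_events: Sequence[PlantedEvent] = field(default_factory=list)
    depth: float = 200.0  # mean reads per event and per background junction
    dispersion: float = 0.01  # beta-binomial rho in [0, 1)
    n_replicates: int = 3
    background_per_event: int = 10
    intron_short_median: float = 47.0
    intron_short_sigma: float = 0.35
    intron_long_median: float = 500.0
    intron_long_sigma: float = 0.6
    short_weight: float = 0.85
    exon_min: int = 80
    exon_max: int = 200
    genes_per_chromosome: int = 200

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValidationError("dispersion rho must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")


def default_planted_events() -> list[PlantedEvent]:
    """A small demonstration mix covering every template."""
    events = []
    events += [PlantedEvent("A5_slipUU")] * 4
    events += [PlantedEvent("A5_GUshift")] * 3
    events += [PlantedEvent("A3_upstream_inframe")] * 3
    events += [PlantedEvent("SE", psi_control=0.80, psi_mutant=0.40)] * 2
    events += [PlantedEvent("RI", psi_control=0.90, psi_mutant=0.55)] * 2
    events += [PlantedEvent("null", psi_control=0.5, psi_mutant=0.5)] * 6
    return events


@dataclass
class _PlantedSite:
    """Resolved genomic realization of one planted event."""

    event: PlantedEvent
    gene_id: str
    chrom: str
    strand: str
    form1_junctions: tuple[Intron, ...]  # promoted / inclusion form
    form2_junctions: tuple[Intron, ...]
    retention_intron: Optional[Intron] = None


@dataclass
class ToyReference:
    genome: Genome
    transcripts: list[TranscriptModel]
    truth: pd.DataFrame
    planted_sites: list[_PlantedSite]
    config: SimulationConfig

    def constitutive_introns(self) -> list[Intron]:
        """Annotated introns not belonging to any planted event form."""
        event_keys = set()
        for site in self.planted_sites:
            for j in site.form1_junctions + site.form2_junctions:
                event_keys.add(j.key())
            if site.retention_intron is not None:
                event_keys.add(site.retention_intron.key())
        seen = set()
        out = []
        for t in self.transcripts:
            for intron in introns_of(t):
                if intron.key() in event_keys or intron.key() in seen:
                    continue
                seen.add(intron.key())
                out.append(intron)
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.transcripts, paths["annotation"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Genome / annotation construction
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class _ChromBuilder:
    """Accumulates mutable per-chromosome sequence as a list of bases."""

    def __init__(self) -> None:
        self.bases: list[str] = []

    def append_random(self, rng: np.random.Generator, n: int) -> int:
        start = len(self.bases) + 1  # 1-based position of first appended base
        self.bases.extend(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        return start

    def set_base(self, pos: int, base: str) -> None:
        self.bases[pos - 1] = base


def _write_transcript_oriented(
    chrom: _ChromBuilder, intron: Intron, offset: int, subseq: str
) -> None:
    """Write ``subseq`` starting at intron position ``offset`` (1-based from
    the donor end) in transcript orientation."""
    for i, base in enumerate(subseq):
        if intron.strand == "+":
            chrom.set_base(intron.start + offset - 1 + i, base)
        else:
            chrom.set_base(intron.end - offset + 1 - i, _COMPLEMENT[base])


def _write_intron_end(
    chrom: _ChromBuilder, intron: Intron, subseq: str, offset_from_end: int = 0
) -> None:
    """Write ``subseq`` so its last base lands ``offset_from_end`` before the
    acceptor end of the intron, transcript-oriented."""
    start_offset = intron.length - offset_from_end - len(subseq) + 1
    _write_transcript_oriented(chrom, intron, start_offset, subseq)


def _intron_length(rng: np.random.Generator, cfg: SimulationConfig, minimum: int) -> int:
    if rng.random() < cfg.short_weight:
        mu, sigma = math.log(cfg.intron_short_median), cfg.intron_short_sigma
    else:
        mu, sigma = math.log(cfg.intron_long_median), cfg.intron_long_sigma
    return max(minimum, int(round(rng.lognormal(mu, sigma))))


def _build_gene(
    chrom: _ChromBuilder,
    chrom_name: str,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    gene_id: str,
    n_exons: int,
    strand: str,
    min_intron: int = 12,
) -> TranscriptModel:
    """Append one gene to the chromosome; canonical motifs at every intron."""
    chrom.append_random(rng, 300)  # intergenic spacer
    exons = []
    pos = len(chrom.bases) + 1
    for i in range(n_exons):
        exon_len = int(rng.integers(cfg.exon_min, cfg.exon_max + 1))
        start = chrom.append_random(rng, exon_len)
        exons.append((start, start + exon_len - 1))
        if i < n_exons - 1:
            intron_len = _intron_length(rng, cfg, minimum=min_intron)
            chrom.append_random(rng, intron_len)
    t = TranscriptModel(
        transcript_id=f"{gene_id}.1",
        gene_id=gene_id,
        chrom=chrom_name,
        strand=strand,
        exons=exons,
    )
    for intron in introns_of(t):
        _write_transcript_oriented(chrom, intron, 1, "GT")
        _write_intron_end(chrom, intron, "TTTCAG")
    return t


def make_toy_reference(cfg: SimulationConfig, outdir: str | Path | None = None) -> ToyReference:
    """Build genome, annotation and truth table for the configured events.

    Each planted event occupies its own gene; additional single-isoform
    background genes are added until the pool of constitutive introns reaches
    ``background_per_event`` times the number of planted events.  Genes are
    laid out sequentially so they can never overlap.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    planted = list(cfg.planted_events)

    chroms: dict[str, _ChromBuilder] = {}
    transcripts: list[TranscriptModel] = []
    sites: list[_PlantedSite] = []
    gene_counter = 0

    def next_chrom(gene_index: int) -> tuple[str, _ChromBuilder]:
        name = f"chr{gene_index // cfg.genes_per_chromosome + 1}"
        if name not in chroms:
            chroms[name] = _ChromBuilder()
        return name, chroms[name]

    for idx, pe in enumerate(planted):
        gene_counter += 1
        gene_id = f"evg{gene_counter:05d}"
        chrom_name, chrom = next_chrom(gene_counter - 1)
        strand = "+" if rng.random() < 0.5 else "-"

        if pe.template in {"A5_slipUU", "A5_GUshift", "null", "A3_upstream_inframe"}:
            t = _build_gene(chrom, chrom_name, rng, cfg, gene_id, n_exons=4,
                            strand=strand, min_intron=40)
            transcripts.append(t)
            target = introns_of(t)[1]  # manipulated intron: index 1 of 3
            if pe.template == "A3_upstream_inframe":
                # promoted acceptor 6 nt upstream of the predominant one
                _write_intron_end(chrom, target, "AG", offset_from_end=6)
                promoted = _shrink_3p(target, 6)
                form1, form2 = (promoted,), (target,)
            else:
                context = pe.donor_context or _DEFAULT_DONOR_CONTEXT[pe.template]
                _write_transcript_oriented(chrom, target, 1, context)
                offset = {"A5_slipUU": 1, "A5_GUshift": 2, "null": 4}[pe.template]
                promoted = _shrink_5p(target, offset)
                form1, form2 = (promoted,), (target,)
            sites.append(
                _PlantedSite(pe, gene_id, chrom_name, strand, form1, form2)
            )
        elif pe.template == "SE":
            t = _build_gene(chrom, chrom_name, rng, cfg, gene_id, n_exons=5,
                            strand=strand, min_intron=20)
            exons = t.exons
            skip_exons = exons[:2] + exons[3:]  # drop middle exon
            t2 = TranscriptModel(
                transcript_id=f"{gene_id}.2",
                gene_id=gene_id,
                chrom=chrom_name,
                strand=strand,
                exons=skip_exons,
            )
            transcripts += [t, t2]
            inc1 = Intron(chrom_name, exons[1][1] + 1, exons[2][0] - 1, strand)
            inc2 = Intron(chrom_name, exons[2][1] + 1, exons[3][0] - 1, strand)
            skip = Intron(chrom_name, exons[1][1] + 1, exons[3][0] - 1, strand)
            # the skip junction also needs splice motifs (it shares the
            # inclusion junctions' outer boundaries, already canonical)
            sites.append(
                _PlantedSite(pe, gene_id, chrom_name, strand, (inc1, inc2), (skip,))
            )
        elif pe.template == "RI":
            t = _build_gene(chrom, chrom_name, rng, cfg, gene_id, n_exons=4,
                            strand=strand, min_intron=20)
            exons = t.exons
            retained = Intron(chrom_name, exons[1][1] + 1, exons[2][0] - 1, strand)
            merged = exons[:1] + [(exons[1][0], exons[2][1])] + exons[3:]
            t2 = TranscriptModel(
                transcript_id=f"{gene_id}.2",
                gene_id=gene_id,
                chrom=chrom_name,
                strand=strand,
                exons=merged,
            )
            transcripts += [t, t2]
            sites.append(
                _PlantedSite(pe, gene_id, chrom_name, strand, (retained,), (),
                             retention_intron=retained)
            )
        else:  # pragma: no cover - guarded by PlantedEvent validation
            raise ValidationError(f"unhandled template {pe.template}")

    # background genes until constitutive introns reach the target pool size
    n_target = cfg.background_per_event * max(len(planted), 1)
    event_keys = {
        j.key()
        for s in sites
        for j in s.form1_junctions + s.form2_junctions
    }
    seen_keys: set = set()
    n_constitutive = 0
    for t in transcripts:
        for intron in introns_of(t):
            key = intron.key()
            if key not in event_keys and key not in seen_keys:
                seen_keys.add(key)
                n_constitutive += 1
    while n_constitutive < n_target:
        gene_counter += 1
        gene_id = f"bgg{gene_counter:05d}"
        chrom_name, chrom = next_chrom(gene_counter - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        t = _build_gene(chrom, chrom_name, rng, cfg, gene_id, n_exons=3, strand=strand)
        transcripts.append(t)
        n_constitutive += 2

    genome = Genome({name: "".join(cb.bases) for name, cb in chroms.items()})

    truth = pd.DataFrame(
        [
            {
                "event_id": f"planted{idx + 1:05d}",
                "template": s.event.template,
                "gene_id": s.gene_id,
                "chrom": s.chrom,
                "strand": s.strand,
                "form1_junctions": _fmt_junctions(s.form1_junctions),
                "form2_junctions": _fmt_junctions(s.form2_junctions),
                "retention_intron": (
                    f"{s.retention_intron.start}-{s.retention_intron.end}"
                    if s.retention_intron
                    else ""
                ),
                "psi_control": s.event.psi_control,
                "psi_mutant": s.event.psi_mutant,
            }
            for idx, s in enumerate(sites)
        ]
    )

    ref = ToyReference(
        genome=genome,
        transcripts=transcripts,
        truth=truth,
        planted_sites=sites,
        config=cfg,
    )
    if outdir is not None:
        ref.write(outdir)
    return ref


def _shrink_5p(intron: Intron, offset: int) -> Intron:
    """Move the donor ``offset`` nt downstream (into the intron)."""
    if intron.strand == "+":
        return Intron(intron.chrom, intron.start + offset, intron.end, intron.strand)
    return Intron(intron.chrom, intron.start, intron.end - offset, intron.strand)


def _shrink_3p(intron: Intron, offset: int) -> Intron:
    """Move the acceptor ``offset`` nt upstream (into the intron)."""
    if intron.strand == "+":
        return Intron(intron.chrom, intron.start, intron.end - offset, intron.strand)
    return Intron(intron.chrom, intron.start + offset, intron.end, intron.strand)


def _fmt_junctions(junctions: tuple[Intron, ...]) -> str:
    return ",".join(f"{j.start}-{j.end}" for j in junctions)


# ---------------------------------------------------------------------------
# Junction-table simulation
# ---------------------------------------------------------------------------


def _beta_binomial(
    rng: np.random.Generator, n: int, mean: float, rho: float
) -> int:
    """One draw with mean ``n * mean`` and overdispersion ``rho``."""
    if n == 0:
        return 0
    if mean <= 0.0:
        return 0
    if mean >= 1.0:
        return n
    if rho == 0.0:
        return int(rng.binomial(n, mean))
    a = mean * (1.0 - rho) / rho
    b = (1.0 - mean) * (1.0 - rho) / rho
    return int(rng.binomial(n, rng.beta(a, b)))


def _motif_code(genome: Genome, intron: Intron) -> int:
    return _MOTIF_TO_CODE.get((motif_of(genome, intron), intron.strand), 0)


def simulate_junction_tables(
    ref: ToyReference,
    cfg: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[dict[str, list[JunctionRecord]], pd.DataFrame]:
    """Simulate per-replicate junction records for control and mutant.

    Returns ``(records_by_sample, retention_table)``.  Sample ids are
    ``control_1..control_n`` and ``mutant_1..mutant_n``.  If ``outdir`` is
    given, writes one junction table per sample plus ``retention.tsv``.
    """
    cfg = cfg or ref.config
    rng = np.random.default_rng([cfg.seed, 1])
    annotated_keys = {
        i.key() for t in ref.transcripts for i in introns_of(t)
    }
    samples = [f"control_{i+1}" for i in range(cfg.n_replicates)] + [
        f"mutant_{i+1}" for i in range(cfg.n_replicates)
    ]
    records: dict[str, list[JunctionRecord]] = {s: [] for s in samples}
    retention_rows: dict[tuple, dict[str, int]] = {}

    def emit(sample: str, intron: Intron, count: int) -> None:
        if count <= 0:
            return
        records[sample].append(
            JunctionRecord(
                intron=intron,
                motif_code=_motif_code(ref.genome, intron),
                annotated_flag=1 if intron.key() in annotated_keys else 0,
                unique_reads=count,
                multi_reads=0,
                max_overhang=38,
                sample_id=sample,
            )
        )

    for site in ref.planted_sites:
        for sample in samples:
            psi = (
                site.event.psi_control
                if sample.startswith("control")
                else site.event.psi_mutant
            )
            total = int(rng.poisson(cfg.depth))
            c1 = _beta_binomial(rng, total, psi, cfg.dispersion)
            c2 = total - c1
            for j in site.form1_junctions:
                emit(sample, j, c1)
            if site.event.template == "RI":
                key = site.retention_intron.key()
                retention_rows.setdefault(key, {})[sample] = c2
            else:
                for j in site.form2_junctions:
                    emit(sample, j, c2)

    for intron in ref.constitutive_introns():
        for sample in samples:
            emit(sample, intron, int(rng.poisson(cfg.depth)))

    retention = pd.DataFrame.from_dict(retention_rows, orient="index").fillna(0).astype(int)
    if len(retention):
        retention = retention.reindex(columns=samples).fillna(0).astype(int)
        retention.index = pd.MultiIndex.from_tuples(
            retention.index, names=["chrom", "start", "end", "strand"]
        )

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "junctions").mkdir(parents=True, exist_ok=True)
        for sample in samples:
            write_junction_table(records[sample], outdir / "junctions" / f"{sample}.sj.tab")
        ret_out = retention.reset_index() if len(retention) else pd.DataFrame(
            columns=["chrom", "start", "end", "strand", *samples]
        )
        ret_out.to_csv(outdir / "retention.tsv", sep="\t", index=False)

    return records, retention


# ---------------------------------------------------------------------------
# Reporter-assay simulation
# ---------------------------------------------------------------------------


def simulate_reporter_assay(
    site_usage: Sequence[float],
    depth: int = 1000,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial counts over 2-4 competing donor sites, one row per replicate.

    Emulates splice-site competition reporters: a 3-choice assay (two cryptic
    GT donors flanking the non-canonical site), a 2-choice doublet, or a 2x2
    doubled-doublet with four sites.  Usage fractions must sum to one.
    """
    usage = np.asarray(site_usage, dtype=float)
    if not 2 <= len(usage) <= 4:
        raise ValidationError("reporter assays have 2-4 competing sites")
    if abs(usage.sum() - 1.0) > 1e-9:
        raise ValidationError(f"site usage sums to {usage.sum()}, not 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, usage, size=n_replicates)
    return pd.DataFrame(
        counts,
        index=[f"rep_{i+1}" for i in range(n_replicates)],
        columns=[f"site_{i+1}" for i in range(len(usage))],
    )
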