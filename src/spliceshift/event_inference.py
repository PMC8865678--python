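"""Pairwise alternative-splicing event construction.

Two routes produce events:

* **de novo** alternative 5'/3' events from the observed junction matrix —
  junctions sharing one intron end but differing at the other, filtered for
  at least ``min_support`` reads of combined support (summed over both
  junctions and all samples) and at most ``max_span`` nucleotides between the
  alternative ends;
* **annotation-derived** events from pairwise comparison of a gene's
  transcript models: skipped exon (SE), multiple skipped exons (MS),
  mutually exclusive exons (MX), retained intron (RI), alternative
  first/last exon (AF/AL) and annotated A5/A3.

Every event is a *pair* of mutually exclusive splice forms; a site offering
more than two alternatives is decomposed into all unordered pairs, each
screened independently downstream.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_formats import CountMatrix, Genome, Intron, TranscriptModel, ValidationError, introns_of

logger = logging.getLogger("spliceshift")

EVENT_TYPES = ("A5", "A3", "SE", "RI", "MX", "MS", "AF", "AL")


@dataclass
class SpliceEvent:
    event_id: str
    event_type: str
    chrom: str
    strand: str
    form1_junctions: frozenset[Intron]
    form2_junctions: frozenset[Intron]
    form1_retention_intron: Optional[Intron] = None  # RI only: intron retained by form2
    shared_end: Optional[int] = None  # A5/A3 only: genomic position of shared boundary
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.form1_junctions == self.form2_junctions:
            raise ValidationError(f"event {self.event_id}: identical forms")

    def forms_key(self) -> tuple:
        """Canonical identity of the event, independent of form labelling."""
        f1 = tuple(sorted(j.key() for j in self.form1_junctions))
        f2 = tuple(sorted(j.key() for j in self.form2_junctions))
        return (self.event_type,) + tuple(sorted((f1, f2)))


@dataclass
class QuantifiedEvent:
    """A SpliceEvent with per-sample read counts attached to each form.

    ``form1_counts[sample]`` / ``form2_counts[sample]`` are tuples of
    junction-level counts (RI form2: a single retention-coverage value).
    """

    event: SpliceEvent
    samples: list[str]
    form1_counts: dict[str, tuple[int, ...]]
    form2_counts: dict[str, tuple[int, ...]]


# ---------------------------------------------------------------------------
# De novo alternative 5'/3' ends
# ---------------------------------------------------------------------------


def _alt_end_positions(intron: Intron, side: str) -> tuple[int, int]:
    """(shared boundary, alternative boundary) genomic positions for a junction."""
    if side == "A5":  # donors vary, acceptor shared
        return intron.acceptor_pos, intron.donor_pos
    return intron.donor_pos, intron.acceptor_pos


def infer_de_novo_alt_ends(
    matrix: CountMatrix,
    side: str,
    genome: Genome | None = None,
    min_support: int = 5,
    max_span: int = 50,
) -> list[SpliceEvent]:
    """Alternative-donor (A5) or alternative-acceptor (A3) events from junctions.

    Junctions sharing (chrom, strand, shared boundary) are grouped; every
    unordered pair of alternative boundaries at most ``max_span`` nucleotides
    apart (inclusive) with combined all-sample support of at least
    ``min_support`` reads yields one event.  Form 1 is the form with higher
    total support; ties go to the upstream site in transcript orientation.
    Strand-undefined junctions are skipped.
    """
    if side not in {"A5", "A3"}:
        raise ValidationError(f"side must be A5 or A3, got {side!r}")
    groups: dict[tuple, list[tuple[Intron, int]]] = {}
    totals = matrix.df.sum(axis=1)
    for key, total in totals.items():
        intron = Intron(*key)
        if intron.strand == ".":
            continue
        shared, _alt = _alt_end_positions(intron, side)
        groups.setdefault((intron.chrom, intron.strand, shared), []).append(
            (intron, int(total))
        )

    events = []
    for (chrom, strand, shared), members in sorted(groups.items()):
        members = sorted(members, key=lambda m: m[0].key())
        for (j1, n1), (j2, n2) in itertools.combinations(members, 2):
            _, alt1 = _alt_end_positions(j1, side)
            _, alt2 = _alt_end_positions(j2, side)
            if abs(alt1 - alt2) > max_span:
                continue
            if n1 + n2 < min_support:
                continue
            # form1 = higher total support; tie -> upstream in transcript orientation
            if n1 > n2:
                f1, f2 = j1, j2
            elif n2 > n1:
                f1, f2 = j2, j1
            else:
                upstream_first = (alt1 < alt2) if strand == "+" else (alt1 > alt2)
                f1, f2 = (j1, j2) if upstream_first else (j2, j1)
            event_id = (
                f"{side}:{chrom}:{strand}:{shared}:"
                f"{min(alt1, alt2)}-{max(alt1, alt2)}"
            )
            events.append(
                SpliceEvent(
                    event_id=event_id,
                    event_type=side,
                    chrom=chrom,
                    strand=strand,
                    form1_junctions=frozenset([f1]),
                    form2_junctions=frozenset([f2]),
                    shared_end=shared,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Annotation-derived events
# ---------------------------------------------------------------------------


def _pairwise_events(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[str, frozenset[Intron], frozenset[Intron], Optional[Intron]]]:
    """Event templates found between one ordered transcript pair.

    Returns (type, inclusion/upstream form, alternative form, retained intron).
    """
    out = []
    introns1, introns2 = introns_of(t1), introns_of(t2)
    set1 = {(i.start, i.end) for i in introns1}
    set2 = {(i.start, i.end) for i in introns2}
    exons2 = t2.exons
    chrom, strand = t1.chrom, t1.strand

    def mk(start: int, end: int) -> Intron:
        return Intron(chrom, start, end, strand)

    # SE / MS: a run of >=1 consecutive t1 introns replaced by one t2 intron
    # spanning the same outer boundaries (flanking exon ends shared).
    for i in range(len(introns1)):
        for j in range(i + 1, len(introns1)):
            a, d = introns1[i].start, introns1[j].end
            if (a, d) in set2:
                n_skipped = j - i  # internal exons of t1 absent from t2
                etype = "SE" if n_skipped == 1 else "MS"
                inclusion = frozenset(mk(iv.start, iv.end) for iv in introns1[i : j + 1])
                skip = frozenset([mk(a, d)])
                out.append((etype, inclusion, skip, None))

    # MX: (a,b),(c,d) in t1 and (a,e),(f,d) in t2 with non-overlapping middle exons.
    for i in range(len(introns1) - 1):
        a, b = introns1[i].start, introns1[i].end
        c, d = introns1[i + 1].start, introns1[i + 1].end
        for k in range(len(introns2) - 1):
            a2, e = introns2[k].start, introns2[k].end
            f, d2 = introns2[k + 1].start, introns2[k + 1].end
            if a2 != a or d2 != d:
                continue
            # middle exons: t1 (b+1, c-1), t2 (e+1, f-1); mutually exclusive
            if (b, c) == (e, f):
                continue
            if c - 1 < e + 1 or f - 1 < b + 1:  # non-overlapping intervals
                form1 = frozenset([mk(a, b), mk(c, d)])
                form2 = frozenset([mk(a2, e), mk(f, d2)])
                out.append(("MX", form1, form2, None))

    # RI: t1 splices an intron that lies inside a single t2 exon whose ends
    # match the outer ends of t1's flanking exons.
    exon_bounds1 = t1.exons
    for idx, intron in enumerate(introns1):
        left = exon_bounds1[idx]
        right = exon_bounds1[idx + 1]
        for ex in exons2:
            if ex[0] == left[0] and ex[1] == right[1]:
                out.append(
                    ("RI", frozenset([mk(intron.start, intron.end)]), frozenset(), intron)
                )

    # AF/AL and annotated A5/A3: intron pairs sharing exactly one end.
    first1 = t1.exons[0] if strand == "+" else t1.exons[-1]
    first2 = t2.exons[0] if strand == "+" else t2.exons[-1]
    last1 = t1.exons[-1] if strand == "+" else t1.exons[0]
    last2 = t2.exons[-1] if strand == "+" else t2.exons[0]

    def overlaps(e1: tuple[int, int], e2: tuple[int, int]) -> bool:
        return e1[0] <= e2[1] and e2[0] <= e1[1]

    for i1 in introns1:
        for i2 in introns2:
            if (i1.start, i1.end) == (i2.start, i2.end):
                continue
            share_start = i1.start == i2.start
            share_end = i1.end == i2.end
            if share_start == share_end:
                continue  # share both (identical) or neither
            # which transcript-oriented end differs?
            if strand == "+":
                donor_differs = share_end
            else:
                donor_differs = share_start
            form1 = frozenset([mk(i1.start, i1.end)])
            form2 = frozenset([mk(i2.start, i2.end)])
            if donor_differs:
                # exons upstream of the differing donors
                d1 = next(e for e in t1.exons if (e[1] == i1.start - 1 if strand == "+" else e[0] == i1.end + 1))
                d2 = next(e for e in t2.exons if (e[1] == i2.start - 1 if strand == "+" else e[0] == i2.end + 1))
                if d1 == first1 and d2 == first2 and not overlaps(d1, d2):
                    out.append(("AF", form1, form2, None))
                elif overlaps(d1, d2):
                    # same exon region, alternative donor boundary
                    out.append(("A5", form1, form2, None))
                # non-overlapping internal exons (e.g. an SE pair seen from
                # one junction) are not an alternative-donor event
            else:
                a1 = next(e for e in t1.exons if (e[0] == i1.end + 1 if strand == "+" else e[1] == i1.start - 1))
                a2 = next(e for e in t2.exons if (e[0] == i2.end + 1 if strand == "+" else e[1] == i2.start - 1))
                if a1 == last1 and a2 == last2 and not overlaps(a1, a2):
                    out.append(("AL", form1, form2, None))
                elif overlaps(a1, a2):
                    out.append(("A3", form1, form2, None))
    return out


def infer_annotation_events(transcripts: Sequence[TranscriptModel]) -> list[SpliceEvent]:
    """Pairwise events from each gene's transcript models, deduplicated.

    Output is invariant to transcript input order: transcripts are compared
    in sorted order and duplicate events (same type and form sets) emitted by
    different pairs are collapsed.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    events: dict[tuple, SpliceEvent] = {}
    for gene_id in sorted(by_gene):
        ts = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        if len(ts) < 2:
            continue
        for t1, t2 in itertools.combinations(ts, 2):
            if t1.chrom != t2.chrom or t1.strand != t2.strand:
                continue
            for ordered in ((t1, t2), (t2, t1)):
                for etype, form1, form2, retained in _pairwise_events(*ordered):
                    ev = SpliceEvent(
                        event_id="",  # assigned after dedup
                        event_type=etype,
                        chrom=t1.chrom,
                        strand=t1.strand,
                        form1_junctions=form1,
                        form2_junctions=form2,
                        form1_retention_intron=retained,
                        gene_id=gene_id,
                    )
                    events.setdefault(ev.forms_key(), ev)

    result = []
    counters: dict[str, int] = {}
    for key in sorted(events):
        ev = events[key]
        counters[ev.event_type] = counters.get(ev.event_type, 0) + 1
        ev.event_id = f"{ev.event_type}:{ev.gene_id}:{counters[ev.event_type]}"
        result.append(ev)
    return result


# ---------------------------------------------------------------------------
# Count attachment
# ---------------------------------------------------------------------------


def attach_counts(
    events: Sequence[SpliceEvent],
    matrix: CountMatrix,
    retention: pd.DataFrame | None = None,
) -> list[QuantifiedEvent]:
    """Attach per-sample junction counts to each form of each event.

    ``retention`` (RI events only) is a table indexed by
    (chrom, start, end, strand) with one column per sample holding
    intron-body read coverage; RI events are dropped with a warning when it
    is absent.  Junctions absent from the matrix contribute zero counts.
    """
    samples = matrix.samples
    out = []
    for ev in events:
        if ev.event_type == "RI":
            if retention is None:
                logger.warning("RI event %s dropped: no retention table", ev.event_id)
                continue
            intron = ev.form1_retention_intron
            key = intron.key()
            if key in retention.index:
                ret_row = retention.loc[key]
            else:
                ret_row = pd.Series(0, index=samples)
            form1 = {
                s: tuple(int(matrix.row(j)[s]) for j in sorted(ev.form1_junctions))
                for s in samples
            }
            form2 = {s: (int(ret_row.get(s, 0)),) for s in samples}
        else:
            form1 = {
                s: tuple(int(matrix.row(j)[s]) for j in sorted(ev.form1_junctions))
                for s in samples
            }
            form2 = {
                s: tuple(int(matrix.row(j)[s]) for j in sorted(ev.form2_junctions))
                for s in samples
            }
        out.append(
            QuantifiedEvent(
                event=ev, samples=list(samples), form1_counts=form1, form2_counts=form2
            )
        )
    return out
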