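"""Donor/acceptor motif classes from genomic sequence, and intron-start k-mers.

Motif labels are carried in the DNA alphabet and transcript orientation:
``GT_AG`` is the canonical intron, ``GC_AG`` the common minor variant and
``TT_AG`` the non-canonical class (UU/AG on the RNA) created when splicing
slips one nucleotide into a GTT donor context.  Anything else is ``OTHER``.

The aligner whose junction dialect this package consumes scores non-canonical
junctions with a heavy penalty; accepting TT/AG introns on equal footing with
GT/AG is expressed here as set membership in the ``allowed`` motif classes of
:func:`filter_by_motif` rather than as an alignment score — this pipeline
never scores alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import Genome, Intron, JunctionRecord, ValidationError, reverse_complement

logger = logging.getLogger("spliceshift")


class MotifClass(Enum):
    GT_AG = "GT_AG"
    GC_AG = "GC_AG"
    TT_AG = "TT_AG"
    OTHER = "OTHER"


#: Motif classes accepted by default: canonical, GC donor, and the
#: non-canonical TT/AG class treated on equal footing.
DEFAULT_ALLOWED = frozenset({MotifClass.GT_AG, MotifClass.GC_AG, MotifClass.TT_AG})

_DINUC_TO_CLASS = {
    ("GT", "AG"): MotifClass.GT_AG,
    ("GC", "AG"): MotifClass.GC_AG,
    ("TT", "AG"): MotifClass.TT_AG,
}


def intron_start_seq(genome: Genome, intron: Intron, k: int) -> str:
    """First ``k`` intronic bases in transcript orientation."""
    if intron.strand == ".":
        raise ValidationError("intron strand undefined; cannot orient sequence")
    if k > intron.length:
        raise ValidationError(f"k={k} exceeds intron length {intron.length}")
    if intron.strand == "+":
        return genome.fetch(intron.chrom, intron.start, intron.start + k - 1)
    return reverse_complement(genome.fetch(intron.chrom, intron.end - k + 1, intron.end))


def intron_end_seq(genome: Genome, intron: Intron, k: int) -> str:
    """Last ``k`` intronic bases in transcript orientation."""
    if intron.strand == ".":
        raise ValidationError("intron strand undefined; cannot orient sequence")
    if intron.strand == "+":
        return genome.fetch(intron.chrom, intron.end - k + 1, intron.end)
    return reverse_complement(genome.fetch(intron.chrom, intron.start, intron.start + k - 1))


def motif_of(genome: Genome, intron: Intron) -> MotifClass:
    """Classify an intron by its first and last dinucleotides.

    On the minus strand the genomic bases are reverse-complemented so the
    label is always transcript-oriented.  Any N in the four motif bases yields
    ``OTHER``.
    """
    donor = intron_start_seq(genome, intron, 2)
    acceptor = intron_end_seq(genome, intron, 2)
    if "N" in donor or "N" in acceptor:
        logger.warning(
            "intron %s:%d-%d has N in motif bases; classified OTHER",
            intron.chrom, intron.start, intron.end,
        )
        return MotifClass.OTHER
    return _DINUC_TO_CLASS.get((donor, acceptor), MotifClass.OTHER)


def filter_by_motif(
    records: Sequence[JunctionRecord],
    genome: Genome,
    allowed: frozenset[MotifClass] | set[MotifClass] = DEFAULT_ALLOWED,
) -> list[JunctionRecord]:
    """Keep junction records whose motif class is in ``allowed``.

    Strand-undefined records are excluded (their motif cannot be oriented).
    """
    kept = []
    for r in records:
        if r.intron.strand == ".":
            continue
        if motif_of(genome, r.intron) in allowed:
            kept.append(r)
    return kept


@dataclass
class KmerFractionTable:
    """Fraction of introns whose first k intronic bases equal each k-mer."""

    k: int
    fractions: dict[str, float]
    n_introns: int

    def __post_init__(self) -> None:
        if self.n_introns <= 0:
            raise ValidationError("n_introns must be positive")
        for kmer, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"fraction for {kmer} outside [0,1]")

    def fraction(self, kmer: str) -> float:
        return self.fractions.get(kmer.upper().replace("U", "T"), 0.0)


def intron_start_fractions(
    introns: Iterable[Intron], genome: Genome, k: int
) -> KmerFractionTable:
    """Tally the first ``k`` transcript-oriented intronic bases of each intron.

    Introns shorter than ``k`` or with an N among the first ``k`` bases are
    excluded from the denominator.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    counts: dict[str, int] = {}
    n_used = 0
    n_skipped = 0
    for intron in introns:
        if intron.length < k:
            n_skipped += 1
            continue
        start = intron_start_seq(genome, intron, k)
        if "N" in start:
            n_skipped += 1
            continue
        counts[start] = counts.get(start, 0) + 1
        n_used += 1
    if n_skipped:
        logger.warning("%d introns excluded from k-mer tally (short or N)", n_skipped)
    if n_used == 0:
        raise ValidationError("no introns usable for k-mer fractions")
    fractions = {kmer: c / n_used for kmer, c in sorted(counts.items())}
    return KmerFractionTable(k=k, fractions=fractions, n_introns=n_used)
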