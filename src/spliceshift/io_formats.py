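"""Core genomic data model and readers/writers for the formats the pipeline touches.

All coordinates are 1-based inclusive throughout the package: this matches
both GTF and the 9-column splice-junction table dialect (STAR ``SJ.out.tab``),
so no half-open conversions happen anywhere.

The junction table dialect is tab-separated with nine columns per line:
chromosome, intron start, intron end, strand code (0 undefined / 1 ``+`` /
2 ``-``), motif code, annotated flag, unique-mapping read count, multimapping
read count, maximum spliced-alignment overhang.  Motif codes: 0 non-canonical,
1 GT/AG, 2 CT/AC, 3 GC/AG, 4 CT/GC, 5 TT/AG, 6 CT/AA.  Codes 5-6 describe the
non-canonical TT/AG intron class (UU/AG on the RNA) and its reverse-complement
reading, taking the slot the minor-spliceosome AT/AC pair occupies in the
stock aligner dialect; *C. elegans* has no minor spliceosome, so that slot is
repurposed for the UU/AG introns this pipeline is built to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("spliceshift")

VALID_BASES = frozenset("ACGTN")

#: strand-code column of the junction dialect -> strand symbol
STRAND_CODE_TO_SYMBOL = {0: ".", 1: "+", 2: "-"}
STRAND_SYMBOL_TO_CODE = {v: k for k, v in STRAND_CODE_TO_SYMBOL.items()}

#: motif-code column of the junction dialect -> (donor, acceptor) dinucleotides
#: as read on the genomic plus strand.
MOTIF_CODES = {
    0: None,  # non-canonical
    1: ("GT", "AG"),
    2: ("CT", "AC"),
    3: ("GC", "AG"),
    4: ("CT", "GC"),
    5: ("TT", "AG"),
    6: ("CT", "AA"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Data violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Chromosome name -> uppercase DNA sequence (alphabet A/C/G/T/N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[start..end], 1-based inclusive, on the plus strand."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValidationError(
                f"range {chrom}:{start}-{end} out of bounds (length {len(seq)})"
            )
        return seq[start - 1 : end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True, order=True)
class Intron:
    """One intron: first and last intronic base, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str  # "+", "-" or "." (undefined)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"intron start {self.start} > end {self.end}")
        if self.length < 4:
            raise ValidationError(
                f"intron {self.chrom}:{self.start}-{self.end} shorter than 4 nt; "
                "cannot hold donor and acceptor dinucleotides"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def donor_pos(self) -> int:
        """Genomic position of the first intronic base in transcript orientation."""
        return self.start if self.strand != "-" else self.end

    @property
    def acceptor_pos(self) -> int:
        """Genomic position of the last intronic base in transcript orientation."""
        return self.end if self.strand != "-" else self.start

    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted by genomic start, 1-based inclusive

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons ({s1},{e1}) and "
                    f"({s2},{e2}) overlap or touch"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class JunctionRecord:
    """One intron observed in one sequencing library."""

    intron: Intron
    motif_code: int
    annotated_flag: int
    unique_reads: int
    multi_reads: int
    max_overhang: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.motif_code not in MOTIF_CODES:
            raise ValidationError(f"motif code {self.motif_code} not in 0..6")
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ValidationError("read counts must be non-negative")


@dataclass
class CountMatrix:
    """Junction x sample read-count matrix (absent pairs are zero).

    Rows are keyed by ``(chrom, start, end, strand)``; ``df`` holds the
    counts with those keys as a MultiIndex.
    """

    df: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def junctions(self) -> list[Intron]:
        return [Intron(c, s, e, st) for c, s, e, st in self.df.index]

    def row(self, intron: Intron) -> pd.Series:
        key = intron.key()
        if key in self.df.index:
            return self.df.loc[key]
        return pd.Series(0, index=self.df.columns)

    def total(self) -> int:
        return int(self.df.to_numpy().sum())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a Genome (uppercased, U converted to T)."""
    path = Path(path)
    sequences: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - Bio raises rarely here
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        sequences[rec.id] = seq
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features of a GTF into transcript models.

    Non-exon features are ignored.  Exons are grouped by ``transcript_id`` and
    sorted by genomic start.
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GTF: {exc}") from exc

    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if "transcript_id" not in feat.attributes:
            raise FormatError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks transcript_id attribute"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        entry = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        entry["exons"].append((feat.start, feat.end))

    transcripts = []
    for tid, entry in grouped.items():
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=entry["exons"],
            )
        )
    return transcripts


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon features (one line per exon)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for i, (start, end) in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{t.chrom}\tspliceshift\texon\t{start}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def introns_of(t: TranscriptModel) -> list[Intron]:
    """Introns between consecutive exons, in genomic order."""
    out = []
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if s2 == e1 + 1:
            raise ValidationError(
                f"transcript {t.transcript_id}: adjacent exons ({s1},{e1}) and "
                f"({s2},{e2}) leave no intron"
            )
        out.append(Intron(t.chrom, e1 + 1, s2 - 1, t.strand))
    return out


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

_JUNCTION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand_code",
    "motif_code",
    "annotated",
    "unique_reads",
    "multi_reads",
    "max_overhang",
]


def read_junction_table(path: str | Path, sample_id: str) -> list[JunctionRecord]:
    """Read one 9-column splice-junction table for one library."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 9:
        raise FormatError(
            f"{path}: expected 9 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = _JUNCTION_COLUMNS
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
            strand_code = int(row.strand_code)
            motif_code = int(row.motif_code)
            annotated = int(row.annotated)
            unique_reads = int(row.unique_reads)
            multi_reads = int(row.multi_reads)
            max_overhang = int(row.max_overhang)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer field: {exc}") from exc
        if strand_code not in STRAND_CODE_TO_SYMBOL:
            raise FormatError(
                f"{path}: line {lineno}: strand code {strand_code} not in 0/1/2"
            )
        strand = STRAND_CODE_TO_SYMBOL[strand_code]
        if strand == ".":
            logger.debug(
                "%s line %d: strand-undefined junction %s:%d-%d retained "
                "(excluded from motif/shift analyses)",
                path,
                lineno,
                row.chrom,
                start,
                end,
            )
        records.append(
            JunctionRecord(
                intron=Intron(str(row.chrom), start, end, strand),
                motif_code=motif_code,
                annotated_flag=annotated,
                unique_reads=unique_reads,
                multi_reads=multi_reads,
                max_overhang=max_overhang,
                sample_id=sample_id,
            )
        )
    return records


def write_junction_table(records: Iterable[JunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.intron.chrom,
                        r.intron.start,
                        r.intron.end,
                        STRAND_SYMBOL_TO_CODE[r.intron.strand],
                        r.motif_code,
                        r.annotated_flag,
                        r.unique_reads,
                        r.multi_reads,
                        r.max_overhang,
                    )
                )
                + "\n"
            )


def read_retention_table(path: str | Path) -> pd.DataFrame:
    """Read a per-intron retention-coverage TSV.

    Expected columns: chrom, start, end, strand, then one column per sample
    with integer intron-body read coverage.  Returns a DataFrame indexed by
    (chrom, start, end, strand).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: retention table lacks columns {missing}")
    df = df.set_index(required)
    return df.astype(int)


def build_count_matrix(
    records: Sequence[JunctionRecord],
    samples: Sequence[str],
    count_policy: str = "unique_only",
) -> CountMatrix:
    """Assemble records from several libraries into a junction x sample matrix.

    ``count_policy`` is ``unique_only`` (default) or ``unique_plus_multi``;
    whether multimapping reads count toward junction support is a dialect
    choice, so both are offered.
    """
    if count_policy not in {"unique_only", "unique_plus_multi"}:
        raise ValidationError(f"unknown count_policy {count_policy!r}")
    sample_set = set(samples)
    seen: set[tuple] = set()
    keys, cols, values = [], [], []
    for r in records:
        if r.sample_id not in sample_set:
            raise ValidationError(
                f"record sample {r.sample_id!r} not in declared manifest"
            )
        pair = (r.intron.key(), r.sample_id)
        if pair in seen:
            raise ValidationError(
                f"duplicate junction/sample entry {r.intron.key()} / {r.sample_id}"
            )
        seen.add(pair)
        count = r.unique_reads
        if count_policy == "unique_plus_multi":
            count += r.multi_reads
        keys.append(r.intron.key())
        cols.append(r.sample_id)
        values.append(count)

    long = pd.DataFrame({"key": keys, "sample": cols, "count": values})
    if long.empty:
        df = pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["chrom", "start", "end", "strand"]),
            columns=list(samples),
        ).fillna(0).astype(int)
        return CountMatrix(df)
    wide = long.pivot(index="key", columns="sample", values="count")
    wide = wide.reindex(columns=list(samples)).fillna(0).astype(int)
    wide.index = pd.MultiIndex.from_tuples(
        wide.index, names=["chrom", "start", "end", "strand"]
    )
    wide.columns.name = None
    return CountMatrix(wide.sort_index())
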