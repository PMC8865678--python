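"""Splice-site shift classification and sequence analytics for passing events.

For an alternative 5'/3' event that passed the screen, the *predominant*
form is the one used more in the control group (higher mean control PSI);
the *promoted* form is the one whose usage rises in the mutant.  The shift
offset is the signed distance (nt, transcript orientation) from the
predominant to the promoted splice site: positive offsets move downstream
(into the intron at a 5' site), negative ones upstream.

Classes:

* ``SLIP_UU`` — a +1 slip at a 5' GTT donor context: the predominant intron
  starts GTT and the promoted intron starts TT (UU on the RNA), the signature
  splice-site "slip" this pipeline screens for;
* ``GU_SHIFT`` — a 5' shift of 2–4 nt (either direction) to another GT donor;
* ``INFRAME_UPSTREAM_3P`` — a 3' acceptor shift upstream by a multiple of
  3 nt (typically −6/−9), preserving reading frame;
* ``OTHER`` — anything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Genome, Intron, ValidationError
from .junction_motifs import intron_start_seq
from .event_inference import SpliceEvent
from .delta_psi_screen import ScreenResult

logger = logging.getLogger("spliceshift")

BASES = ("A", "C", "G", "T")

SHIFT_CLASSES = ("SLIP_UU", "GU_SHIFT", "INFRAME_UPSTREAM_3P", "OTHER")


@dataclass
class ShiftCall:
    event_id: str
    offset_nt: int
    predominant_start_kmer: str  # first 4 intronic nt of the predominant form
    promoted_start_dinucleotide: str
    shift_class: str
    in_frame: bool

    def __post_init__(self) -> None:
        if self.offset_nt == 0:
            raise ValidationError("shift offset cannot be 0")
        if self.shift_class not in SHIFT_CLASSES:
            raise ValidationError(f"unknown shift class {self.shift_class!r}")


def _transcript_offset(pos_promoted: int, pos_predominant: int, strand: str) -> int:
    """Signed genomic difference converted to transcript orientation."""
    diff = pos_promoted - pos_predominant
    return diff if strand == "+" else -diff


def classify_shift(
    event: SpliceEvent,
    result: ScreenResult,
    genome: Genome,
    control_psi: Sequence[float],
) -> ShiftCall:
    """Classify one passing A5/A3 event by shift offset and donor context.

    ``control_psi`` holds the event's form-1 PSI values in the control group;
    the predominant form is the one with higher mean control PSI and the
    promoted form is the one gaining PSI in the mutant (sign of the mean
    ΔPSI).  The call depends only on that ordering, not on which form was
    labelled form 1 at inference time.
    """
    if event.event_type not in {"A5", "A3"}:
        raise ValidationError(f"shift classification needs A5/A3, got {event.event_type}")
    if event.strand == ".":
        raise ValidationError(f"event {event.event_id}: strand undefined")

    (j1,) = event.form1_junctions
    (j2,) = event.form2_junctions

    form1_control = float(np.nanmean(np.asarray(control_psi, dtype=float)))
    predominant = j1 if form1_control >= 0.5 else j2
    # mean_delta is form 1's; form 2 moves opposite
    promoted = j1 if result.mean_delta > 0 else j2

    if event.event_type == "A5":
        pos_pred, pos_prom = predominant.donor_pos, promoted.donor_pos
    else:
        pos_pred, pos_prom = predominant.acceptor_pos, promoted.acceptor_pos
    offset = _transcript_offset(pos_prom, pos_pred, event.strand)
    if offset == 0:
        raise ValidationError(
            f"event {event.event_id}: promoted and predominant sites coincide"
        )

    pred_kmer = intron_start_seq(genome, predominant, min(4, predominant.length))
    prom_dinuc = intron_start_seq(genome, promoted, 2)
    in_frame = offset % 3 == 0

    shift_class = "OTHER"
    if event.event_type == "A5":
        if offset == 1 and prom_dinuc == "TT" and pred_kmer.startswith("GTT"):
            shift_class = "SLIP_UU"
        elif abs(offset) in {2, 3, 4} and prom_dinuc == "GT":
            shift_class = "GU_SHIFT"
    else:  # A3
        if offset < 0 and in_frame:
            shift_class = "INFRAME_UPSTREAM_3P"

    return ShiftCall(
        event_id=event.event_id,
        offset_nt=offset,
        predominant_start_kmer=pred_kmer,
        promoted_start_dinucleotide=prom_dinuc,
        shift_class=shift_class,
        in_frame=in_frame,
    )


def shift_histogram(calls: Sequence[ShiftCall]) -> dict[int, int]:
    """Counts of calls by signed nucleotide offset."""
    hist: dict[int, int] = {}
    for c in calls:
        hist[c.offset_nt] = hist.get(c.offset_nt, 0) + 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# Position-frequency matrices / sequence logos
# ---------------------------------------------------------------------------


@dataclass
class Pfm:
    """Per-position base counts around a splice site, with information content.

    ``counts`` is positions x 4 (A,C,G,T); information content per column is
    R_i = 2 − H_i bits where H_i is the Shannon entropy of the column's base
    frequencies (no small-sample correction).
    """

    counts: pd.DataFrame  # index: position labels, columns: A,C,G,T
    n_exonic: int
    n_intronic: int
    n_sites: int

    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def information_content(self) -> pd.Series:
        """Bits per position, in [0, 2]."""
        freqs = self.frequencies().to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            logterm = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        entropy = -logterm.sum(axis=1)
        return pd.Series(2.0 - entropy, index=self.counts.index)

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out["information_bits"] = self.information_content().round(4)
        out.to_csv(path, sep="\t", index_label="position")

    def write_transfac(self, path, name: str = "splice_site") -> None:
        with open(path, "w") as fh:
            fh.write(f"ID {name}\nBF {name}\nP0\tA\tC\tG\tT\n")
            for i, (_, row) in enumerate(self.counts.iterrows(), start=1):
                fh.write(f"{i:02d}\t" + "\t".join(str(int(row[b])) for b in BASES) + "\n")
            fh.write("XX\n//\n")


def splice_site_window(
    genome: Genome, intron: Intron, side: str, n_exonic: int, n_intronic: int
) -> str:
    """Transcript-oriented sequence window around a donor or acceptor.

    For ``side="donor"`` the window is the last ``n_exonic`` exonic bases
    followed by the first ``n_intronic`` intronic bases; for
    ``side="acceptor"`` it is the last ``n_intronic`` intronic bases followed
    by the first ``n_exonic`` exonic bases.
    """
    if side not in {"donor", "acceptor"}:
        raise ValidationError(f"side must be donor/acceptor, got {side!r}")
    if intron.strand == ".":
        raise ValidationError("strand undefined")
    plus = intron.strand == "+"
    if side == "donor":
        if plus:
            lo, hi = intron.start - n_exonic, intron.start + n_intronic - 1
        else:
            lo, hi = intron.end - n_intronic + 1, intron.end + n_exonic
    else:
        if plus:
            lo, hi = intron.end - n_intronic + 1, intron.end + n_exonic
        else:
            lo, hi = intron.start - n_exonic, intron.start + n_intronic - 1
    seq = genome.fetch(intron.chrom, lo, hi)
    return seq if plus else seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def build_pfm(
    introns: Sequence[Intron],
    genome: Genome,
    side: str = "donor",
    window: tuple[int, int] | None = None,
) -> Pfm:
    """Position-frequency matrix over splice-site windows.

    Default windows: 3 exonic + 8 intronic positions for donors, 16 intronic
    + 3 exonic for acceptors.  Sites whose window runs off the chromosome end
    are excluded and logged.
    """
    if window is None:
        window = (3, 8) if side == "donor" else (3, 16)
    n_exonic, n_intronic = window
    width = n_exonic + n_intronic
    if side == "donor":
        labels = [f"E{-i}" for i in range(n_exonic, 0, -1)] + [
            f"I{i}" for i in range(1, n_intronic + 1)
        ]
    else:
        labels = [f"I{-i}" for i in range(n_intronic, 0, -1)] + [
            f"E{i}" for i in range(1, n_exonic + 1)
        ]
    counts = np.zeros((width, 4), dtype=int)
    base_index = {b: i for i, b in enumerate(BASES)}
    n_sites = 0
    n_excluded = 0
    for intron in introns:
        try:
            seq = splice_site_window(genome, intron, side, n_exonic, n_intronic)
        except (ValidationError, KeyError):
            n_excluded += 1
            continue
        if "N" in seq:
            n_excluded += 1
            continue
        for i, base in enumerate(seq):
            counts[i, base_index[base]] += 1
        n_sites += 1
    if n_excluded:
        logger.warning("%d sites excluded from PFM (window off end or N)", n_excluded)
    if n_sites == 0:
        raise ValidationError("no usable sites for PFM")
    df = pd.DataFrame(counts, index=labels, columns=list(BASES))
    return Pfm(counts=df, n_exonic=n_exonic, n_intronic=n_intronic, n_sites=n_sites)


# ---------------------------------------------------------------------------
# Intron-length and overlap summaries
# ---------------------------------------------------------------------------


def intron_length_summary(
    groups: Mapping[str, Sequence[Intron] | Sequence[int]]
) -> pd.DataFrame:
    """Median/quartile/N of intron lengths per labelled group.

    Even-sized groups use midpoint interpolation for the median; empty groups
    are omitted with a warning.
    """
    rows = []
    for label, members in groups.items():
        lengths = [m.length if isinstance(m, Intron) else int(m) for m in members]
        if not lengths:
            logger.warning("intron group %r empty; omitted from summary", label)
            continue
        arr = np.asarray(lengths, dtype=float)
        rows.append(
            {
                "group": label,
                "n": len(arr),
                "median": float(np.median(arr)),
                "q1": float(np.percentile(arr, 25)),
                "q3": float(np.percentile(arr, 75)),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])


def overlap_counts(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str] | None = None,
    labels: tuple[str, ...] = ("A", "B", "C"),
) -> dict[str, float]:
    """Exact region cardinalities for a 2- or 3-set Euler summary.

    Also reports the pairwise overlap fraction |A∩B| / |A|.
    """
    a, b = set(set_a), set(set_b)
    la, lb, lc = labels[0], labels[1], labels[2] if len(labels) > 2 else "C"
    if set_c is None:
        both = a & b
        out = {
            f"only_{la}": len(a - b),
            f"only_{lb}": len(b - a),
            f"{la}_and_{lb}": len(both),
        }
        out["overlap_fraction"] = len(both) / len(a) if a else 0.0
        return out
    c = set(set_c)
    out = {
        f"only_{la}": len(a - b - c),
        f"only_{lb}": len(b - a - c),
        f"only_{lc}": len(c - a - b),
        f"{la}_and_{lb}": len((a & b) - c),
        f"{la}_and_{lc}": len((a & c) - b),
        f"{lb}_and_{lc}": len((b & c) - a),
        f"{la}_and_{lb}_and_{lc}": len(a & b & c),
    }
    out["overlap_fraction"] = len(a & b) / len(a) if a else 0.0
    return out
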