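"""Percent-spliced-in (PSI) quantification per event per sample.

For an event with forms 1 and 2, the form-level count in a sample is the
*mean* of that form's junction counts (a single-junction form contributes its
count directly), and

    PSI = c1 / (c1 + c2)

PSI is the fraction of informative reads supporting form 1, so
PSI(form1) + PSI(form2) = 1 wherever defined.  A cell is missing when the
informative total ``c1 + c2`` falls below ``min_denominator``.

Averaging across a form's junctions (rather than summing or taking the
minimum) keeps a two-junction inclusion form on the same scale as a
one-junction skip form and is robust to one junction losing reads to
overhang filters; it is the dialect this package documents and tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ValidationError
from .event_inference import QuantifiedEvent

logger = logging.getLogger("spliceshift")


@dataclass
class PsiMatrix:
    """Event x sample PSI values (NaN = missing) with per-cell denominators."""

    psi: pd.DataFrame
    denominators: pd.DataFrame

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)

    def write_tsv(self, path) -> None:
        self.psi.to_csv(path, sep="\t", na_rep="NA", float_format="%.4f",
                        index_label="event_id")


def compute_psi(
    qevent: QuantifiedEvent, min_denominator: int = 1
) -> dict[str, float]:
    """Per-sample PSI for one quantified event (NaN where denominator short)."""
    out = {}
    for s in qevent.samples:
        c1_parts = qevent.form1_counts[s]
        c2_parts = qevent.form2_counts[s]
        if any(c < 0 for c in c1_parts + c2_parts):
            raise ValidationError(f"event {qevent.event.event_id}: negative count")
        c1 = float(np.mean(c1_parts)) if c1_parts else 0.0
        c2 = float(np.mean(c2_parts)) if c2_parts else 0.0
        total = c1 + c2
        out[s] = c1 / total if total >= min_denominator and total > 0 else float("nan")
    return out


def psi_matrix(
    qevents: Sequence[QuantifiedEvent],
    samples: Sequence[str] | None = None,
    min_denominator: int = 1,
) -> PsiMatrix:
    """Assemble the full event x sample PSI matrix.

    Rows missing in every sample are dropped (logged); any duplicate
    event_id is an error.
    """
    if not qevents:
        raise ValidationError("no events to quantify")
    if samples is None:
        samples = qevents[0].samples
    ids = [q.event.event_id for q in qevents]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate event ids: {dupes}")

    psi_rows, denom_rows = [], []
    for q in qevents:
        vals = compute_psi(q, min_denominator=min_denominator)
        denom = {}
        for s in q.samples:
            c1 = float(np.mean(q.form1_counts[s])) if q.form1_counts[s] else 0.0
            c2 = float(np.mean(q.form2_counts[s])) if q.form2_counts[s] else 0.0
            denom[s] = c1 + c2
        psi_rows.append([vals.get(s, float("nan")) for s in samples])
        denom_rows.append([denom.get(s, 0.0) for s in samples])

    psi = pd.DataFrame(psi_rows, index=ids, columns=list(samples))
    denominators = pd.DataFrame(denom_rows, index=ids, columns=list(samples))

    all_missing = psi.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d events with PSI missing in every sample",
                    int(all_missing.sum()))
        psi = psi.loc[~all_missing]
        denominators = denominators.loc[~all_missing]
    return PsiMatrix(psi=psi, denominators=denominators)
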