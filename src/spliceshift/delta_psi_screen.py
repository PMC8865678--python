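"""High-stringency replicate-pairwise ΔPSI screen.

With three control and three treatment replicates, every event yields nine
ordered pairwise differences ΔPSI = treatment − control.  The screen's
concordance statistic, *pairSum*, counts how many of those comparisons exceed
a per-pair threshold (default 15%) in the direction of the mean change; an
event passes only when every comparison agrees (pairSum = 9 for 3 vs 3) *and*
the mean ΔPSI across all comparisons exceeds a second threshold (default
20%).  Requiring all nine replicate pairs to agree is the screen's multiple-
testing guard: no p-value-based FDR correction is applied, deliberately.

Both thresholds are strict inequalities on fractions (a delta of exactly
0.15 does not count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ValidationError
from .psi_quant import PsiMatrix

logger = logging.getLogger("spliceshift")


class MissingPsiError(ValueError):
    """An event has a missing PSI cell and cannot enter pairwise comparison."""


@dataclass
class ScreenConfig:
    min_pair_delta: float = 0.15
    min_mean_delta: float = 0.20
    required_pair_sum: int | None = None  # None -> all pairs (n_A * n_B)
    direction_policy: str = "signed_consistent"  # or "absolute"

    def __post_init__(self) -> None:
        if not 0 < self.min_pair_delta <= self.min_mean_delta <= 1:
            raise ValidationError(
                "need 0 < min_pair_delta <= min_mean_delta <= 1, got "
                f"{self.min_pair_delta}, {self.min_mean_delta}"
            )
        if self.direction_policy not in {"signed_consistent", "absolute"}:
            raise ValidationError(f"unknown direction_policy {self.direction_policy!r}")


@dataclass
class ScreenResult:
    event_id: str
    deltas: list[float]
    pair_sum: int
    mean_delta: float
    direction: str  # "up", "down" or "undefined"
    passes: bool


def pairwise_deltas(
    control_psi: Sequence[float], mutant_psi: Sequence[float]
) -> list[float]:
    """All ordered pairwise differences mutant_j − control_i.

    Length is n_control × n_mutant (nine for triplicates).  Any missing (NaN)
    value raises :class:`MissingPsiError`; events with missing cells are
    excluded upstream, not imputed.
    """
    control = np.asarray(control_psi, dtype=float)
    mutant = np.asarray(mutant_psi, dtype=float)
    if np.isnan(control).any() or np.isnan(mutant).any():
        raise MissingPsiError("missing PSI value in pairwise comparison")
    return [float(m - c) for c in control for m in mutant]


def pair_sum(
    deltas: Sequence[float],
    min_pair_delta: float = 0.15,
    direction_policy: str = "signed_consistent",
) -> tuple[int, str]:
    """Count pairwise comparisons exceeding the threshold.

    Under ``signed_consistent`` (default) only deltas sharing the sign of the
    mean delta count; under ``absolute`` any |Δ| above threshold counts.  A
    mean delta of exactly zero leaves the direction undefined and falls back
    to the absolute count (flagged in the log).
    """
    if not len(deltas):
        raise ValidationError("empty delta list")
    arr = np.asarray(deltas, dtype=float)
    mean = float(arr.mean())
    if mean > 0:
        direction = "up"
    elif mean < 0:
        direction = "down"
    else:
        direction = "undefined"
        logger.warning("mean delta exactly 0; pair_sum computed under absolute policy")
    if direction_policy == "absolute" or direction == "undefined":
        count = int(np.sum(np.abs(arr) > min_pair_delta))
    else:
        sign = 1.0 if direction == "up" else -1.0
        count = int(np.sum((arr * sign) > min_pair_delta))
    return count, direction


def screen(
    psi: PsiMatrix,
    control_samples: Sequence[str],
    mutant_samples: Sequence[str],
    cfg: ScreenConfig | None = None,
) -> list[ScreenResult]:
    """Run the pairSum ΔPSI screen over every event with complete PSI.

    Events with any missing cell in either group are excluded and logged.
    Results are sorted by |mean ΔPSI| descending.
    """
    cfg = cfg or ScreenConfig()
    if len(control_samples) < 2 or len(mutant_samples) < 2:
        raise ValidationError("each group needs at least 2 replicates")
    missing_cols = (set(control_samples) | set(mutant_samples)) - set(psi.samples)
    if missing_cols:
        raise ValidationError(f"samples not in PSI matrix: {sorted(missing_cols)}")
    required = cfg.required_pair_sum
    if required is None:
        required = len(control_samples) * len(mutant_samples)

    results = []
    n_excluded = 0
    for event_id, row in psi.psi.iterrows():
        control = [row[s] for s in control_samples]
        mutant = [row[s] for s in mutant_samples]
        try:
            deltas = pairwise_deltas(control, mutant)
        except MissingPsiError:
            n_excluded += 1
            logger.debug("event %s excluded: missing PSI cell", event_id)
            continue
        count, direction = pair_sum(deltas, cfg.min_pair_delta, cfg.direction_policy)
        mean_delta = float(np.mean(deltas))
        passes = count == required and abs(mean_delta) > cfg.min_mean_delta
        results.append(
            ScreenResult(
                event_id=event_id,
                deltas=deltas,
                pair_sum=count,
                mean_delta=mean_delta,
                direction=direction,
                passes=passes,
            )
        )
    if n_excluded:
        logger.info("screen excluded %d events with missing PSI cells", n_excluded)
    results.sort(key=lambda r: (-abs(r.mean_delta), r.event_id))
    return results


def psi_t_test(
    group1_psi: Sequence[float], group2_psi: Sequence[float]
) -> tuple[float, float]:
    """Welch's unequal-variance two-tailed t-test on PSI values.

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1 (no evidence of difference) instead of scipy's NaN.
    """
    g1 = np.asarray(group1_psi, dtype=float)
    g2 = np.asarray(group2_psi, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs at least 2 values")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return 0.0, 1.0
        return float("inf") if g1.mean() > g2.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(g1, g2, equal_var=False)
    return float(t), float(p)
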