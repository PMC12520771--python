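"""PSE deviations, adaptation slopes and the two ordering contrasts.

The deviation of a fitted PSE from the physical probe level measures the
perceptual bias at that level.  Regressing deviation on probe level
yields the adaptation index: an OLS slope whose magnitude quantifies the
pull toward the central anchor (for the generative observer with a fixed
anchor the slope is exactly ``-(1 - w)``).

Two ordering contrasts are provided: a half-split of the extreme probe
blocks (first vs second half of a block-wise session) and the
majority/minority deviation table of the biased-context sessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from loudadapt.psychometrics import PsychometricFit

logger = logging.getLogger(__name__)


class InsufficientLevelsError(ValueError):
    """Fewer than two probe levels with usable deviations."""


class UnclassifiableError(ValueError):
    """A half-split target block cannot be assigned to either half."""


class MissingPhaseError(ValueError):
    """A context-session phase has no fitted PSE."""


@dataclass(frozen=True)
class SubjectSummary:
    subject: str
    condition: str
    deviations: Mapping[float, float]  # probe_db -> pse_db - probe_db
    adaptation_slope: Optional[float] = None
    adaptation_intercept: Optional[float] = None
    block_order: Optional[Tuple[float, ...]] = None


def pse_deviations(
    fits: Iterable[PsychometricFit],
    subject: str,
    condition: str,
    block_order: Optional[Sequence[float]] = None,
) -> SubjectSummary:
    """Collect ``PSE - probe`` per probe level for one subject.

    Non-converged fits are skipped with a logged warning.
    """
    deviations: Dict[float, float] = {}
    n_skipped = 0
    for fit in fits:
        if not fit.converged:
            n_skipped += 1
            continue
        deviations[fit.probe_db] = fit.pse_db - fit.probe_db
    if n_skipped:
        logger.warning(
            "subject %s: skipped %d non-converged fit(s)", subject, n_skipped
        )
    if not deviations:
        raise InsufficientLevelsError(f"subject {subject!r}: no converged fits")
    return SubjectSummary(
        subject=subject,
        condition=condition,
        deviations=dict(deviations),
        block_order=tuple(block_order) if block_order is not None else None,
    )


def adaptation_index(summary: SubjectSummary) -> float:
    """OLS slope of deviation vs probe level (with intercept)."""
    slope, _ = _fit_line(summary)
    return slope


def with_adaptation_index(summary: SubjectSummary) -> SubjectSummary:
    """Return a copy with ``adaptation_slope``/``intercept`` filled in."""
    slope, intercept = _fit_line(summary)
    return replace(summary, adaptation_slope=slope, adaptation_intercept=intercept)


def _fit_line(summary: SubjectSummary) -> Tuple[float, float]:
    if len(summary.deviations) < 2:
        raise InsufficientLevelsError(
            f"subject {summary.subject!r}: need >= 2 probe levels, "
            f"got {len(summary.deviations)}"
        )
    levels = np.array(sorted(summary.deviations))
    devs = np.array([summary.deviations[v] for v in levels])
    slope, intercept = np.polyfit(levels, devs, 1)
    return float(slope), float(intercept)


def half_split_contrast(
    summaries: Iterable[SubjectSummary],
    levels: Tuple[float, float] = (40.0, 80.0),
    strict: bool = True,
) -> pd.DataFrame:
    """Classify each subject's extreme probe blocks into session halves.

    With five blocks, positions 1-2 count as the first half, 4-5 as the
    second; a target block in the middle position is dropped for that
    level.  Returns a long table (subject, condition, probe_db, half,
    deviation); a subject with neither target level classifiable raises
    :class:`UnclassifiableError` when ``strict`` and is silently omitted
    (participant selection) otherwise.
    """
    rows = []
    for s in summaries:
        if s.block_order is None:
            raise ValueError(f"subject {s.subject!r}: block_order unknown")
        n_blocks = len(s.block_order)
        classified = 0
        for level in levels:
            if level not in s.block_order or level not in s.deviations:
                continue
            pos = s.block_order.index(level)  # 0-based
            if pos <= (n_blocks // 2) - 1:
                half = "first_half"
            elif pos >= (n_blocks + 1) // 2:
                half = "second_half"
            else:
                continue  # middle block: unclassifiable for this level
            classified += 1
            rows.append(
                {
                    "subject": s.subject,
                    "condition": s.condition,
                    "probe_db": level,
                    "half": half,
                    "deviation_db": s.deviations[level],
                }
            )
        if classified == 0 and strict:
            raise UnclassifiableError(
                f"subject {s.subject!r}: both target blocks fall in the middle position"
            )
    return pd.DataFrame(rows, columns=["subject", "condition", "probe_db", "half", "deviation_db"])


#: Cells of the context-effect table.
CONTEXT_CELLS = ("baseline_majority", "baseline_minority", "test_majority", "test_minority")


def context_effects(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject deviation table for the biased-context sessions.

    ``fits`` needs columns ``subject, context, phase, probe_db, pse_db,
    converged`` with phases ``baseline1`` (minority-level baseline),
    ``baseline2`` (majority-level baseline) and ``test`` (both levels).
    Majority level is 40 dB in the quiet context, 80 dB in the loud one.
    Returns a long table (subject, context, cell, probe_db,
    deviation_db); raises :class:`MissingPhaseError` for incomplete
    subjects.
    """
    majority_by_context = {"quiet": 40.0, "loud": 80.0}
    required = {"subject", "context", "phase", "probe_db", "pse_db", "converged"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns {sorted(missing)}")

    rows = []
    for (subject, context), sub in fits.groupby(["subject", "context"], sort=True):
        majority = majority_by_context[context]
        minority = 120.0 - majority
        cells = {
            "baseline_majority": ("baseline2", majority),
            "baseline_minority": ("baseline1", minority),
            "test_majority": ("test", majority),
            "test_minority": ("test", minority),
        }
        for cell, (phase, level) in cells.items():
            match = sub[(sub["phase"] == phase) & (sub["probe_db"] == level) & sub["converged"]]
            if len(match) == 0:
                raise MissingPhaseError(
                    f"subject {subject!r}: no converged fit for phase {phase!r} at {level} dB"
                )
            pse = float(match["pse_db"].iloc[0])
            rows.append(
                {
                    "subject": subject,
                    "context": context,
                    "cell": cell,
                    "probe_db": level,
                    "deviation_db": pse - level,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "context", "cell", "probe_db", "deviation_db"])
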