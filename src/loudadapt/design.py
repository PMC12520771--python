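"""Seeded trial-schedule construction for the three session layouts.

Sessions 1 and 2 are block-wise method-of-constant-stimuli designs: five
probe levels (40-80 dB in 10 dB steps) presented in blocks of 70 trials,
each block crossing the probe with seven comparison levels (probe +/- 3
steps of 2 dB) repeated 10 times, for 350 trials in total.  Session 3
builds a biased sound context: two 70-trial baselines, a 70-trial
adaptation block and a 350-trial test phase mixing a majority level
(80 % of trials) with a minority level (20 %), all with a 3 dB step.

All ordering is driven by a single ``numpy`` Generator seeded per
session, so schedules are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

Condition = Literal["baseline", "active", "continuous_cue", "flashed_cue"]
Phase = Literal["main", "baseline1", "baseline2", "adaptation", "test"]
Context = Literal["none", "quiet", "loud"]

#: Probe levels (dB) for the block-wise sessions.
PROBE_LEVELS: Tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0)
#: Comparison offsets in units of the design step size.
COMPARISON_OFFSETS: Tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
#: Repetitions of each (probe, comparison) pair within a block.
REPS_PER_COMPARISON: int = 10

TONE_DURATION_MS: float = 300.0
TONE_FREQ_HZ: float = 1000.0

#: Continuous cue: two bars meet after 70 frames on a 60 Hz display.
CONTINUOUS_CUE_DURATION_MS: float = 70 / 60 * 1000.0
#: Flashed cue: fixation cross flashes at 700 ms for 300 ms.
FLASH_ONSET_MS: float = 700.0
FLASH_DURATION_MS: float = 300.0

#: Inter-trial jitter bounds (ms) for random-onset (passive) trials.
ITI_JITTER_MS: Tuple[float, float] = (500.0, 3000.0)

#: Context-session levels: majority/minority per context.
CONTEXT_LEVELS = {"quiet": (40.0, 80.0), "loud": (80.0, 40.0)}
EXP3_STEP_DB: float = 3.0
EXP3_TEST_MAJORITY_TRIALS: int = 280
EXP3_TEST_MINORITY_TRIALS: int = 70


@dataclass(frozen=True)
class TrialSpec:
    """A single scheduled 2AFC trial (no response yet)."""

    experiment: int
    condition: Condition
    phase: Phase
    block_index: int
    trial_index: int
    probe_db: float
    comparison_db: float
    tone_duration_ms: float = TONE_DURATION_MS
    tone_freq_hz: float = TONE_FREQ_HZ
    cue_onset_ms: Optional[float] = None
    cue_duration_ms: Optional[float] = None
    tone_onset_ms: Optional[float] = None
    iti_jitter_ms: Optional[float] = None


@dataclass(frozen=True)
class SessionDesign:
    """An ordered trial schedule plus its design parameters."""

    trials: Tuple[TrialSpec, ...]
    probe_levels: Tuple[float, ...]
    step_db: float
    reps_per_comparison: int
    context: Context
    seed: int
    condition: Condition

    def __len__(self) -> int:
        return len(self.trials)

    def comparison_levels(self, probe_db: float) -> Tuple[float, ...]:
        """Sorted distinct comparison levels scheduled for ``probe_db``."""
        levels = sorted({t.comparison_db for t in self.trials if t.probe_db == probe_db})
        return tuple(levels)


def _block_pairs(probe_db: float, step_db: float, reps: int) -> list[float]:
    """Comparison levels of one block, ``reps`` copies of each offset."""
    return [probe_db + k * step_db for k in COMPARISON_OFFSETS for _ in range(reps)]


def _shuffled_block(
    rng: np.random.Generator, probe_db: float, step_db: float, reps: int
) -> list[float]:
    comps = np.asarray(_block_pairs(probe_db, step_db, reps))
    rng.shuffle(comps)
    return comps.tolist()


def _constant_stimuli_session(
    experiment: int,
    condition: Condition,
    seed: int,
    *,
    cue_onset_ms: Optional[float] = None,
    cue_duration_ms: Optional[float] = None,
    tone_onset_ms: Optional[float] = None,
) -> SessionDesign:
    rng = np.random.default_rng(seed)
    block_order = rng.permutation(np.asarray(PROBE_LEVELS))
    passive_onset = condition in ("baseline",)  # random probe onset
    trials: list[TrialSpec] = []
    idx = 0
    for block_index, probe in enumerate(block_order):
        for comp in _shuffled_block(rng, float(probe), 2.0, REPS_PER_COMPARISON):
            jitter = float(rng.uniform(*ITI_JITTER_MS)) if passive_onset else None
            trials.append(
                TrialSpec(
                    experiment=experiment,
                    condition=condition,
                    phase="main",
                    block_index=block_index,
                    trial_index=idx,
                    probe_db=float(probe),
                    comparison_db=float(comp),
                    cue_onset_ms=cue_onset_ms,
                    cue_duration_ms=cue_duration_ms,
                    tone_onset_ms=tone_onset_ms,
                    iti_jitter_ms=jitter,
                )
            )
            idx += 1
    return SessionDesign(
        trials=tuple(trials),
        probe_levels=PROBE_LEVELS,
        step_db=2.0,
        reps_per_comparison=REPS_PER_COMPARISON,
        context="none",
        seed=seed,
        condition=condition,
    )


def make_exp1_design(group: Condition, seed: int) -> SessionDesign:
    """Build one experiment-1 session (350 trials, 5 blocks of 70).

    Parameters
    ----------
    group
        ``"baseline"`` (random probe onset) or ``"active"``
        (self-triggered probe).
    seed
        Non-negative session seed driving block order and within-block
        shuffles.
    """
    if group not in ("baseline", "active"):
        raise ValueError(f"experiment 1 group must be baseline|active, got {group!r}")
    _check_seed(seed)
    return _constant_stimuli_session(1, group, seed)


def make_exp2_design(
    cue: Condition, seed: int, *, flashed_tone_delay_ms: float = 700.0
) -> SessionDesign:
    """Build one experiment-2 session (cued passive probe onset).

    ``continuous_cue`` trials carry two bars closing over 70 frames at
    60 Hz with the tone at bar contact; ``flashed_cue`` trials carry a
    700 ms flash onset, 300 ms flash duration, and a tone onset of
    flash onset + ``flashed_tone_delay_ms`` (default 700 ms; set 300 to
    use the text's alternative timing).  Timing is metadata only.
    """
    if cue not in ("continuous_cue", "flashed_cue"):
        raise ValueError(f"experiment 2 cue must be continuous_cue|flashed_cue, got {cue!r}")
    _check_seed(seed)
    if cue == "continuous_cue":
        return _constant_stimuli_session(
            2,
            cue,
            seed,
            cue_onset_ms=0.0,
            cue_duration_ms=CONTINUOUS_CUE_DURATION_MS,
            tone_onset_ms=CONTINUOUS_CUE_DURATION_MS,
        )
    return _constant_stimuli_session(
        2,
        cue,
        seed,
        cue_onset_ms=FLASH_ONSET_MS,
        cue_duration_ms=FLASH_DURATION_MS,
        tone_onset_ms=FLASH_ONSET_MS + flashed_tone_delay_ms,
    )


def make_exp3_design(context: Context, seed: int) -> SessionDesign:
    """Build one experiment-3 context session (560 trials, 4 phases).

    Phase order: ``baseline1`` (70 trials at the non-context level),
    ``baseline2`` (70 at the context level), ``adaptation`` (70 at the
    context level), ``test`` (280 context-level + 70 other-level trials
    uniformly interleaved).  Baseline and adaptation phases use the
    passive random-onset structure; test trials are self-generated.
    """
    if context not in CONTEXT_LEVELS:
        raise ValueError(f"context must be quiet|loud, got {context!r}")
    _check_seed(seed)
    majority, minority = CONTEXT_LEVELS[context]
    rng = np.random.default_rng(seed)
    step = EXP3_STEP_DB
    trials: list[TrialSpec] = []
    idx = 0

    def extend(phase: Phase, block_index: int, probes_comps: Sequence[tuple[float, float]],
               condition: Condition) -> None:
        nonlocal idx
        passive = condition == "baseline"
        for probe, comp in probes_comps:
            jitter = float(rng.uniform(*ITI_JITTER_MS)) if passive else None
            trials.append(
                TrialSpec(
                    experiment=3,
                    condition=condition,
                    phase=phase,
                    block_index=block_index,
                    trial_index=idx,
                    probe_db=probe,
                    comparison_db=comp,
                    iti_jitter_ms=jitter,
                )
            )
            idx += 1

    # Lead-in blocks: minority-level baseline, context-level baseline,
    # context-level adaptation; all passive.
    for phase, probe, block_index in (
        ("baseline1", minority, 0),
        ("baseline2", majority, 1),
        ("adaptation", majority, 2),
    ):
        comps = _shuffled_block(rng, probe, step, REPS_PER_COMPARISON)
        extend(phase, block_index, [(probe, c) for c in comps], "baseline")

    # Test phase: 280 majority + 70 minority trials, jointly shuffled.
    majority_reps = EXP3_TEST_MAJORITY_TRIALS // len(COMPARISON_OFFSETS)
    minority_reps = EXP3_TEST_MINORITY_TRIALS // len(COMPARISON_OFFSETS)
    pairs = [(majority, majority + k * step) for k in COMPARISON_OFFSETS for _ in range(majority_reps)]
    pairs += [(minority, minority + k * step) for k in COMPARISON_OFFSETS for _ in range(minority_reps)]
    order = rng.permutation(len(pairs))
    extend("test", 3, [pairs[i] for i in order], "active")

    return SessionDesign(
        trials=tuple(trials),
        probe_levels=(majority, minority),
        step_db=step,
        reps_per_comparison=REPS_PER_COMPARISON,
        context=context,
        seed=seed,
        condition="active",
    )


def _check_seed(seed: int) -> None:
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
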