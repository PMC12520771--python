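"""Generative central-tendency observer for 2AFC loudness sessions.

The observer's percept of the probe tone is a weighted average of the
physical level and a running anchor: ``w * probe + (1 - w) * mu``.  The
comparison tone is perceived veridically up to sensory noise.  The
anchor tracks the experienced sound statistics with an exponential
moving average, and a lapse parameter mixes in stimulus-independent
coin-flip responses.

The probability that the comparison is judged louder is available in
closed form (:func:`p_comparison_louder`); :func:`simulate_session`
draws Bernoulli responses from it trial by trial while the anchor
evolves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.special import ndtr

from loudadapt.design import Condition, SessionDesign, TrialSpec

#: Default prior weights per condition, chosen so that replication runs
#: reproduce a roughly two-fold slope ratio between the self-generated /
#: cued conditions and baseline.  Configurable, not ground truth.
DEFAULT_W_BY_CONDITION: Dict[str, float] = {
    "baseline": 0.94,
    "active": 0.88,
    "continuous_cue": 0.88,
    "flashed_cue": 0.88,
}
DEFAULT_ANCHOR_INIT_DB: float = 60.0  # everyday average sound level
DEFAULT_ANCHOR_LR: float = 0.005
DEFAULT_NOISE_DB: float = 3.0
DEFAULT_LAPSE: float = 0.02


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one simulated observer.

    Attributes
    ----------
    w_by_condition
        Prior weight ``w`` in [0, 1] per condition; ``1 - w`` is the
        pull toward the anchor.
    anchor_init_db
        Initial anchor level (dB).
    anchor_lr
        Exponential-moving-average learning rate ``alpha`` in [0, 1].
    noise_probe_db, noise_comp_db
        Sensory/memory noise SDs (dB, > 0) for probe and comparison.
    lapse
        Stimulus-independent response probability ``lambda`` in [0, 0.2].
    """

    w_by_condition: Mapping[str, float]
    anchor_init_db: float = DEFAULT_ANCHOR_INIT_DB
    anchor_lr: float = DEFAULT_ANCHOR_LR
    noise_probe_db: float = DEFAULT_NOISE_DB
    noise_comp_db: float = DEFAULT_NOISE_DB
    lapse: float = DEFAULT_LAPSE

    def __post_init__(self):
        for cond, w in self.w_by_condition.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"w for {cond!r} must be in [0, 1], got {w}")
        if not 0.0 <= self.anchor_lr <= 1.0:
            raise ValueError(f"anchor_lr must be in [0, 1], got {self.anchor_lr}")
        if self.noise_probe_db <= 0 or self.noise_comp_db <= 0:
            raise ValueError("noise SDs must be strictly positive")
        if not 0.0 <= self.lapse <= 0.2:
            raise ValueError(f"lapse must be in [0, 0.2], got {self.lapse}")

    def w(self, condition: str) -> float:
        try:
            return self.w_by_condition[condition]
        except KeyError as exc:
            raise KeyError(f"no prior weight configured for condition {condition!r}") from exc


def default_observer_params(**overrides) -> ObserverParams:
    """The default replication parameter set (see module docstring)."""
    kwargs = dict(
        w_by_condition=dict(DEFAULT_W_BY_CONDITION),
        anchor_init_db=DEFAULT_ANCHOR_INIT_DB,
        anchor_lr=DEFAULT_ANCHOR_LR,
        noise_probe_db=DEFAULT_NOISE_DB,
        noise_comp_db=DEFAULT_NOISE_DB,
        lapse=DEFAULT_LAPSE,
    )
    kwargs.update(overrides)
    return ObserverParams(**kwargs)


@dataclass(frozen=True)
class PriorState:
    """Running state of the anchor."""

    anchor_db: float
    n_updates: int = 0


@dataclass(frozen=True)
class TrialRecord:
    """One completed 2AFC trial: the scheduled spec plus the outcome."""

    spec: TrialSpec
    subject: str
    response: int  # 1 = comparison judged louder, 0 = probe judged louder
    anchor_db: float  # anchor in effect when the probe was perceived
    p_comparison_louder: float


def p_comparison_louder(
    probe_db: float,
    comparison_db: float,
    state: PriorState,
    params: ObserverParams,
    condition: str,
) -> float:
    """Closed-form probability of judging the comparison louder.

    ``lambda/2 + (1 - lambda) * Phi((c - [w*L + (1-w)*mu]) / sqrt(sp^2 + sc^2))``.
    """
    var = params.noise_probe_db**2 + params.noise_comp_db**2
    if var == 0.0:
        raise ValueError("total noise variance must be positive")
    w = params.w(condition)
    percept_mean = w * probe_db + (1.0 - w) * state.anchor_db
    z = (comparison_db - percept_mean) / math.sqrt(var)
    return params.lapse / 2.0 + (1.0 - params.lapse) * float(ndtr(z))


def update_prior(state: PriorState, experienced_db: float, alpha: float) -> PriorState:
    """Exponential-moving-average anchor update: ``mu' = (1-a)*mu + a*x``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return PriorState(
        anchor_db=(1.0 - alpha) * state.anchor_db + alpha * experienced_db,
        n_updates=state.n_updates + 1,
    )


def simulate_session(
    design: SessionDesign,
    params: ObserverParams,
    seed: Union[int, Sequence[int]],
    subject: str = "s0",
) -> Tuple[TrialRecord, ...]:
    """Simulate one observer running through ``design``.

    Responses are Bernoulli draws from :func:`p_comparison_louder`; after
    every trial the anchor is updated with the trial's probe and then its
    comparison level.  The prior weight follows each trial's condition
    flag, so mixed-phase sessions switch weights automatically.
    """
    rng = np.random.default_rng(seed)
    n = len(design.trials)
    u = rng.random(n)  # one uniform per trial, drawn up front

    alpha = params.anchor_lr
    lapse = params.lapse
    inv_sd = 1.0 / math.sqrt(params.noise_probe_db**2 + params.noise_comp_db**2)
    mu = params.anchor_init_db

    records: list[TrialRecord] = []
    n_updates = 0
    sqrt2 = math.sqrt(2.0)
    for i, trial in enumerate(design.trials):
        w = params.w(trial.condition)
        percept_mean = w * trial.probe_db + (1.0 - w) * mu
        z = (trial.comparison_db - percept_mean) * inv_sd
        p = lapse / 2.0 + (1.0 - lapse) * 0.5 * math.erfc(-z / sqrt2)
        records.append(
            TrialRecord(
                spec=trial,
                subject=subject,
                response=int(u[i] < p),
                anchor_db=mu,
                p_comparison_louder=p,
            )
        )
        if alpha > 0.0:
            mu = (1.0 - alpha) * mu + alpha * trial.probe_db
            mu = (1.0 - alpha) * mu + alpha * trial.comparison_db
            n_updates += 2
    return tuple(records)


# --------------------------------------------------------------------------
# Cohort sampling


@dataclass(frozen=True)
class ParamSpec:
    """Truncated-normal specification for one scalar parameter.

    ``sd = 0`` degenerates to a point mass at ``mean`` (which must lie
    inside ``[low, high]``).
    """

    mean: float
    sd: float = 0.0
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.low > self.high:
            raise ValueError(f"empty truncation interval [{self.low}, {self.high}]")
        if self.sd == 0 and not self.low <= self.mean <= self.high:
            raise ValueError(
                f"point mass {self.mean} outside truncation [{self.low}, {self.high}]"
            )

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return self.mean
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng))


#: Field names drawable by :func:`make_cohort`.
_COHORT_FIELDS = ("w", "anchor_init_db", "anchor_lr", "noise_probe_db", "noise_comp_db", "lapse")


def default_cohort_distribution(w_mean: Optional[float] = None) -> Dict[str, ParamSpec]:
    """Mild between-subject variability around the default parameters."""
    dist = {
        "anchor_init_db": ParamSpec(DEFAULT_ANCHOR_INIT_DB, 3.0, 30.0, 90.0),
        "anchor_lr": ParamSpec(DEFAULT_ANCHOR_LR, 0.0, 0.0, 1.0),
        "noise_probe_db": ParamSpec(DEFAULT_NOISE_DB, 0.5, 0.5, 10.0),
        "noise_comp_db": ParamSpec(DEFAULT_NOISE_DB, 0.5, 0.5, 10.0),
        "lapse": ParamSpec(DEFAULT_LAPSE, 0.01, 0.0, 0.2),
    }
    if w_mean is not None:
        dist["w"] = ParamSpec(w_mean, 0.03, 0.0, 1.0)
    return dist


def make_cohort(
    n_subjects: int,
    condition: str,
    param_distribution: Mapping[str, Union[ParamSpec, float]],
    seed: Union[int, Sequence[int]],
) -> Tuple[ObserverParams, ...]:
    """Draw per-subject :class:`ObserverParams` for one condition.

    ``param_distribution`` maps a subset of
    ``{"w", "anchor_init_db", "anchor_lr", "noise_probe_db",
    "noise_comp_db", "lapse"}`` to :class:`ParamSpec` (or a float for a
    point mass); unspecified fields take the package defaults.  The
    ``"w"`` draw sets the weight for ``condition``; other conditions keep
    their default weights.  Each subject gets an independent RNG stream
    derived from ``(seed, subject index)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    specs: Dict[str, ParamSpec] = {}
    for name, value in param_distribution.items():
        if name not in _COHORT_FIELDS:
            raise KeyError(f"unknown parameter {name!r}; expected one of {_COHORT_FIELDS}")
        specs[name] = value if isinstance(value, ParamSpec) else ParamSpec(float(value))

    base_seed = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    cohort: list[ObserverParams] = []
    for sid in range(n_subjects):
        rng = np.random.default_rng(base_seed + [sid])
        kwargs = dict(
            anchor_init_db=DEFAULT_ANCHOR_INIT_DB,
            anchor_lr=DEFAULT_ANCHOR_LR,
            noise_probe_db=DEFAULT_NOISE_DB,
            noise_comp_db=DEFAULT_NOISE_DB,
            lapse=DEFAULT_LAPSE,
        )
        w_by_condition = dict(DEFAULT_W_BY_CONDITION)
        for name in _COHORT_FIELDS:
            if name not in specs:
                continue
            value = specs[name].sample(rng)
            if name == "w":
                w_by_condition[condition] = value
            else:
                kwargs[name] = value
        cohort.append(ObserverParams(w_by_condition=w_by_condition, **kwargs))
    return tuple(cohort)
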