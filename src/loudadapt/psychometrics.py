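"""Per-subject aggregation, cumulative-Gaussian fitting and exclusion.

For every probe level the "comparison louder" responses are averaged per
comparison level and a cumulative Gaussian ``Phi((c - pse) / sigma)`` is
fitted; its mean is the point of subjective equality (PSE).  The default
fit is nonlinear least squares on the averaged proportions; a Bernoulli
maximum-likelihood fit on the raw counts is available via
``method="mle"``.

Subjects answering incorrectly on more than 25 % of the catch trials
(the extreme comparison levels, where the physical ordering defines a
correct answer) are flagged for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import ndtr

from loudadapt.observer import TrialRecord

PSE_HALF_RANGE_DB = 15.0
SIGMA_BOUNDS_DB = (0.1, 30.0)


class InsufficientDataError(ValueError):
    """Fewer than two comparison levels carry responses."""


class DegenerateDataError(ValueError):
    """All proportions identical: no slope information to fit."""


class MissingExtremesError(ValueError):
    """No trials at the extreme comparison offsets."""


@dataclass(frozen=True)
class ProportionTable:
    """Averaged 2AFC responses for one subject x probe level."""

    probe_db: float
    comparison_db: np.ndarray  # sorted, distinct
    n_trials: np.ndarray
    prop_comparison_louder: np.ndarray

    def __post_init__(self):
        if np.any(self.n_trials <= 0):
            raise ValueError("every row needs at least one trial")
        if np.any((self.prop_comparison_louder < 0) | (self.prop_comparison_louder > 1)):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class PsychometricFit:
    pse_db: float
    sigma_db: float
    sse_or_loglik: float
    converged: bool
    n_points: int
    probe_db: float
    method: str = "lsq"


def aggregate_proportions(
    trials: Iterable[TrialRecord], subject: str, probe_db: float
) -> ProportionTable:
    """Average "comparison louder" responses per comparison level."""
    comps: dict[float, list[int]] = {}
    for rec in trials:
        if rec.subject == subject and rec.spec.probe_db == probe_db:
            comps.setdefault(rec.spec.comparison_db, []).append(rec.response)
    if len(comps) < 2:
        raise InsufficientDataError(
            f"subject {subject!r} probe {probe_db} has {len(comps)} comparison level(s); need >= 2"
        )
    levels = np.array(sorted(comps))
    n = np.array([len(comps[c]) for c in levels])
    prop = np.array([np.mean(comps[c]) for c in levels])
    return ProportionTable(
        probe_db=probe_db, comparison_db=levels, n_trials=n, prop_comparison_louder=prop
    )


def _grid_init(
    c: np.ndarray, p: np.ndarray, n: np.ndarray, lo: float, hi: float, method: str
) -> Tuple[float, float]:
    """Coarse grid over (pse, sigma) to seed the local optimizer."""
    pse_grid = np.linspace(lo, hi, 61)
    sig_grid = np.geomspace(SIGMA_BOUNDS_DB[0], SIGMA_BOUNDS_DB[1], 25)
    z = (c[None, None, :] - pse_grid[:, None, None]) / sig_grid[None, :, None]
    pred = ndtr(z)
    if method == "lsq":
        loss = np.sum((pred - p[None, None, :]) ** 2, axis=-1)
    else:
        pred = np.clip(pred, 1e-12, 1 - 1e-12)
        loss = -np.sum(
            n[None, None, :] * (p[None, None, :] * np.log(pred)
                                + (1 - p[None, None, :]) * np.log1p(-pred)),
            axis=-1,
        )
    i, j = np.unravel_index(np.argmin(loss), loss.shape)
    return float(pse_grid[i]), float(sig_grid[j])


def fit_cumulative_gaussian(
    table: ProportionTable, method: Literal["lsq", "mle"] = "lsq"
) -> PsychometricFit:
    """Fit ``Phi((c - pse) / sigma)`` to one proportion table.

    PSE is bounded to probe +/- 15 dB and sigma to [0.1, 30] dB.  The
    returned ``converged`` flag is False (without raising) when the
    optimizer fails or the solution sits on a bound.
    """
    c = np.asarray(table.comparison_db, dtype=float)
    p = np.asarray(table.prop_comparison_louder, dtype=float)
    n = np.asarray(table.n_trials, dtype=float)
    if len(c) < 3:
        raise InsufficientDataError(f"need >= 3 comparison levels, got {len(c)}")
    if np.allclose(p, p[0]):
        raise DegenerateDataError("all proportions identical; psychometric slope undefined")

    lo, hi = table.probe_db - PSE_HALF_RANGE_DB, table.probe_db + PSE_HALF_RANGE_DB
    x0 = _grid_init(c, p, n, lo, hi, method)
    bounds_lo = (lo, SIGMA_BOUNDS_DB[0])
    bounds_hi = (hi, SIGMA_BOUNDS_DB[1])

    if method == "lsq":
        def residuals(x):
            return ndtr((c - x[0]) / x[1]) - p

        res = least_squares(residuals, x0=x0, bounds=(bounds_lo, bounds_hi), xtol=1e-12,
                            ftol=1e-12, gtol=1e-12)
        pse, sigma = res.x
        goodness = float(np.sum(res.fun**2))
        ok = bool(res.success)
    elif method == "mle":
        def nll(x):
            pred = np.clip(ndtr((c - x[0]) / x[1]), 1e-12, 1 - 1e-12)
            return -float(np.sum(n * (p * np.log(pred) + (1 - p) * np.log1p(-pred))))

        res = minimize(nll, x0=x0, bounds=list(zip(bounds_lo, bounds_hi)),
                       method="L-BFGS-B", options={"ftol": 1e-14, "gtol": 1e-10})
        pse, sigma = res.x
        goodness = -float(res.fun)  # log-likelihood
        ok = bool(res.success)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    eps = 1e-6
    on_bound = (
        pse <= lo + eps or pse >= hi - eps
        or sigma <= SIGMA_BOUNDS_DB[0] + eps or sigma >= SIGMA_BOUNDS_DB[1] - eps
    )
    return PsychometricFit(
        pse_db=float(pse),
        sigma_db=float(sigma),
        sse_or_loglik=goodness,
        converged=ok and not on_bound,
        n_points=len(c),
        probe_db=table.probe_db,
        method=method,
    )


def exclusion_check(trials: Sequence[TrialRecord]) -> Tuple[bool, float]:
    """Catch-trial exclusion rule for one subject's session.

    At the two extreme comparison levels of each probe block the physical
    ordering defines a correct answer; responses contradicting it count
    as errors, pooled over the session.  Excluded iff error rate > 0.25
    (strict).
    """
    by_probe: dict[float, list[TrialRecord]] = {}
    for rec in trials:
        by_probe.setdefault(rec.spec.probe_db, []).append(rec)

    n_catch = 0
    n_err = 0
    for probe, recs in by_probe.items():
        comps = sorted({r.spec.comparison_db for r in recs})
        extremes = {comps[0], comps[-1]} - {probe}
        for rec in recs:
            cmp_db = rec.spec.comparison_db
            if cmp_db not in extremes:
                continue
            n_catch += 1
            correct = 1 if cmp_db > probe else 0
            n_err += int(rec.response != correct)
    if n_catch == 0:
        raise MissingExtremesError("session contains no extreme-offset catch trials")
    error_rate = n_err / n_catch
    return error_rate > 0.25, error_rate
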