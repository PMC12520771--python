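"""Inferential statistics on subject-level summaries.

Implements the mixed within-between ANOVA (balanced within factor,
uncorrected df by default, Greenhouse-Geisser behind a flag), the
one-way ANOVA, the pooled-variance independent-samples t-test with
Cohen's d, and the two-sample JZS Bayes factor (Cauchy effect-size
prior, default scale r = 0.707) by adaptive quadrature.

Effect sizes: classical eta-squared is ``SS_effect / SS_total``; partial
eta-squared is ``SS_effect / (SS_effect + SS_error_effect)``.  Both are
reported on every ANOVA row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats


class UnbalancedDesignError(ValueError):
    """The within factor is not fully crossed with subjects."""


class ZeroVarianceError(ValueError):
    """No variance to test against."""


class IntegrationError(RuntimeError):
    """Bayes-factor quadrature did not reach the requested tolerance."""


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_sq_classical: float
    eta_sq_partial: float


@dataclass(frozen=True)
class AnovaTable:
    rows: Tuple[AnovaRow, ...]

    def __getitem__(self, effect: str) -> AnovaRow:
        for row in self.rows:
            if row.effect == effect:
                return row
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    se: float
    mean_diff: float


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    r_scale: float
    t_input: float
    n1: int
    n2: int
    rel_err: float = 0.0


def _f_p(F: float, df1: int, df2: int) -> float:
    return float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "subject",
    between: str = "group",
    correction: Optional[str] = None,
) -> AnovaTable:
    """Mixed within-between ANOVA on a long subject-level table.

    Every subject must contribute exactly one value per within level
    (balanced within factor) and every group needs >= 2 subjects.  With a
    single group the table reduces to the one-way repeated-measures
    ANOVA (no between/interaction rows).  ``correction="gg"`` applies
    Greenhouse-Geisser-corrected df to the within and interaction rows.
    """
    df = data[[subject, between, within, dv]].copy()
    levels = np.sort(df[within].unique())
    k = len(levels)
    groups = np.sort(df[between].unique())
    g = len(groups)

    wide = df.pivot_table(index=[subject, between], columns=within, values=dv, aggfunc="first")
    if wide.isna().any().any() or len(df) != wide.size:
        raise UnbalancedDesignError("every subject needs exactly one value per within level")
    n_per_group = wide.groupby(level=between).size()
    if (n_per_group < 2).any():
        raise UnbalancedDesignError("every group needs >= 2 subjects")
    N = len(wide)

    x = wide.to_numpy()  # N x k
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())

    subj_means = x.mean(axis=1)
    ss_between_subj = k * float(((subj_means - grand) ** 2).sum())

    group_labels = wide.index.get_level_values(between).to_numpy()
    ss_group = 0.0
    ss_inter = 0.0
    level_means = x.mean(axis=0)
    ss_level = N * float(((level_means - grand) ** 2).sum())
    for gl in groups:
        mask = group_labels == gl
        n_g = int(mask.sum())
        gmean = x[mask].mean()
        ss_group += k * n_g * (gmean - grand) ** 2
        cell_means = x[mask].mean(axis=0)
        ss_inter += n_g * float(((cell_means - gmean - level_means + grand) ** 2).sum())
    ss_subj_err = ss_between_subj - ss_group
    ss_within_err = ss_total - ss_between_subj - ss_level - ss_inter

    df_level, df_inter = k - 1, (k - 1) * (g - 1)
    df_group, df_subj_err = g - 1, N - g
    df_within_err = (k - 1) * (N - g)

    ms_err_w = _safe_ratio(ss_within_err, df_within_err)
    ms_err_b = _safe_ratio(ss_subj_err, df_subj_err)

    eps = 1.0
    if correction == "gg":
        eps = _gg_epsilon(x)

    def row(effect, ss_eff, df1, df2, ms_err, ss_err, corrected=False) -> AnovaRow:
        ms_eff = _safe_ratio(ss_eff, df1)
        F = _safe_ratio(ms_eff, ms_err)
        d1, d2 = (df1 * eps, df2 * eps) if corrected else (df1, df2)
        return AnovaRow(
            effect=effect,
            F=F,
            df1=df1,
            df2=df2,
            p=float(stats.f.sf(F, d1, d2)) if F > 0 else 1.0,
            eta_sq_classical=_safe_ratio(ss_eff, ss_total),
            eta_sq_partial=_safe_ratio(ss_eff, ss_eff + ss_err),
        )

    rows = [row(within, ss_level, df_level, df_within_err, ms_err_w, ss_within_err,
                corrected=correction == "gg")]
    if g > 1:
        rows.append(
            row(f"{within} * {between}", ss_inter, df_inter, df_within_err, ms_err_w,
                ss_within_err, corrected=correction == "gg")
        )
        rows.append(row(between, ss_group, df_group, df_subj_err, ms_err_b, ss_subj_err))
    return AnovaTable(rows=tuple(rows))


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance."""
    k = x.shape[1]
    S = np.cov(x, rowvar=False)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc**2)
    if den == 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def oneway_anova(values: Sequence[float], groups: Sequence) -> AnovaTable:
    """One-way between-subjects ANOVA (classical eta-squared)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if any((groups == gl).sum() < 2 for gl in labels):
        raise ValueError("every group needs >= 2 values")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0:
        raise ZeroVarianceError("total variance is zero")
    ss_between = sum(
        (groups == gl).sum() * (values[groups == gl].mean() - grand) ** 2 for gl in labels
    )
    ss_within = ss_total - ss_between
    df1, df2 = len(labels) - 1, len(values) - len(labels)
    F = _safe_ratio(ss_between / df1, ss_within / df2)
    eta = ss_between / ss_total
    return AnovaTable(
        rows=(
            AnovaRow(
                effect="group", F=F, df1=df1, df2=df2, p=_f_p(F, df1, df2),
                eta_sq_classical=eta, eta_sq_partial=eta,
            ),
        )
    )


def student_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance independent-samples t with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per sample")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ZeroVarianceError("pooled variance is zero")
    sp = math.sqrt(sp2)
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    diff = float(x.mean() - y.mean())
    t = diff / se
    return TTestResult(
        t=t, df=df, p=float(2 * stats.t.sf(abs(t), df)), d=diff / sp, se=se, mean_diff=diff
    )


def jzs_bf10(t: float, n1: int, n2: int, r: float = 0.707) -> BayesFactorResult:
    """Two-sample JZS Bayes factor by adaptive quadrature.

    The alternative marginalises the t likelihood over a Cauchy(0, r)
    prior on the standardised effect size; the null is the point delta =
    0.  The Cauchy prior is integrated in its normal scale-mixture form
    (inverse-gamma(1/2, 1/2) mixing density on the variance scale g),
    which keeps the integrand stable for arbitrarily large df; the ratio
    to the null marginal is folded into the integrand so everything
    stays O(1) in logs.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if r <= 0:
        raise ValueError("Cauchy scale r must be positive")
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    t2 = t * t
    log_null = -(nu + 1) / 2.0 * math.log1p(t2 / nu)

    def integrand(g: float) -> float:
        if g <= 0.0:
            return 0.0
        a = 1.0 + n_eff * g * r * r
        log_lik = -0.5 * math.log(a) - (nu + 1) / 2.0 * math.log1p(t2 / (a * nu))
        log_prior = -1.5 * math.log(g) - 0.5 / g - 0.5 * math.log(2.0 * math.pi)
        return math.exp(log_lik + log_prior - log_null)

    bf10, err = integrate.quad(integrand, 0.0, math.inf, epsrel=1e-8, limit=200)
    if bf10 <= 0 or (err / bf10) > 1e-6:
        raise IntegrationError(
            f"marginal-likelihood quadrature unreliable (value={bf10}, err={err})"
        )
    return BayesFactorResult(
        bf10=bf10, r_scale=r, t_input=t, n1=n1, n2=n2, rel_err=err / bf10
    )
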