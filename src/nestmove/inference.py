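"""Statistical layer: logistic intersection model, windowed odds ratios,
and the Welch two-sample comparison.

The unit of analysis is the hourly path segment, pooled across females
within a subspecies (no random effect; per-bird clustering is an
acknowledged, unmodeled source of optimism in the standard errors —
cluster-robust SEs are available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .tracks_io import ValidationError


class SeparationError(ValueError):
    """Logistic fit is not identified (complete separation or constant outcome)."""


@dataclass
class LogisticFit:
    region: str
    intercept: float
    slope: float  # per day-before-laying
    se_intercept: float
    se_slope: float
    p_intercept: float
    p_slope: float
    n: int
    converged: bool
    score_norm: float  # sup-norm of the log-likelihood gradient at the MLE
    n_clusters: int | None = None  # set when SEs are cluster-robust

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald CI for the day slope.

        Normal critical value for independent-segment SEs; with
        cluster-robust SEs the t(G-1) critical value is used — with few
        birds the robust variance is itself noisy and the normal interval
        under-covers.
        """
        alpha = 1.0 - level
        if self.n_clusters is not None:
            crit = float(scipy.stats.t.ppf(1 - alpha / 2, self.n_clusters - 1))
        else:
            crit = float(scipy.stats.norm.ppf(1 - alpha / 2))
        return (self.slope - crit * self.se_slope, self.slope + crit * self.se_slope)


@dataclass
class OddsRatioResult:
    a: float  # in-buffer, window A
    b: float  # not in-buffer, window A
    c: float  # in-buffer, window B
    d: float  # not in-buffer, window B
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to all cells


def fit_intersection_model(
    records: pd.DataFrame,
    region: str,
    cluster_robust: bool = False,
) -> LogisticFit:
    """ML logistic fit of P(intersect) on days-before-laying.

    logit P(flag = 1) = b0 + b1 * day_before_laying, Wald SEs and p-values.
    ``cluster_robust=True`` clusters SEs on bird_id.
    """
    if region not in records.columns:
        raise ValidationError(f"region {region!r} not in records")
    y = records[region].to_numpy(dtype=float)
    day = records["day_before_laying"].to_numpy(dtype=float)
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise SeparationError(f"region {region}: outcome is constant ({uniq})")
    X = sm.add_constant(day)
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            if cluster_robust:
                res = model.fit(
                    disp=0,
                    cov_type="cluster",
                    cov_kwds={"groups": records["bird_id"].to_numpy()},
                )
            else:
                res = model.fit(disp=0)
        except (RuntimeWarning, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"region {region}: {exc}") from exc
    score = model.score(res.params)
    score_norm = float(np.max(np.abs(score)))
    if not res.mle_retvals.get("converged", False) or score_norm > 1e-4:
        raise SeparationError(
            f"region {region}: fit did not converge (|score|={score_norm:.2e}),"
            " likely separation"
        )
    return LogisticFit(
        region=region,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        p_intercept=float(res.pvalues[0]),
        p_slope=float(res.pvalues[1]),
        n=len(y),
        converged=True,
        score_norm=score_norm,
        n_clusters=(
            int(records["bird_id"].nunique()) if cluster_robust else None
        ),
    )


def predict_probability(fit: LogisticFit, day: int | np.ndarray) -> float | np.ndarray:
    """Inverse-logit of the linear predictor at the given day(s)."""
    eta = fit.intercept + fit.slope * np.asarray(day, dtype=float)
    out = 1.0 / (1.0 + np.exp(-eta))
    return float(out) if np.isscalar(day) or np.ndim(day) == 0 else out


def window_odds_ratio(
    records: pd.DataFrame,
    region: str,
    window_a: tuple[int, int],
    window_b: tuple[int, int],
    z: float = 1.96,
) -> OddsRatioResult:
    """Contingency odds ratio between two days-before-laying windows.

    OR = (a/b) / (c/d) with a = in-buffer segments in window A, etc.; 95% CI
    by the Woolf log method, exp(ln OR +- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe,
    flagged).
    """
    day = records["day_before_laying"]
    in_a = records[(day >= window_a[0]) & (day <= window_a[1])][region]
    in_b = records[(day >= window_b[0]) & (day <= window_b[1])][region]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValidationError(
            f"empty window: A has {len(in_a)}, B has {len(in_b)} segments"
        )
    a = float(in_a.sum())
    b = float(len(in_a) - a)
    c = float(in_b.sum())
    d = float(len(in_b) - c)
    corrected = any(v == 0 for v in (a, b, c, d))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(odds_ratio)
    return OddsRatioResult(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(odds_ratio),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        corrected=corrected,
    )


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Satterthwaite df, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValidationError("zero variance in both groups with unequal means")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
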