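"""Covariate-adjusted association models, Hochberg multiple-testing
correction, intraclass correlation reliability, and paired-condition
contrasts.

The association between a network diagnostic and the skill-learning score is
an ordinary least-squares model with age, sex, and mean framewise
displacement as covariates of non-interest; the effect size reported for the
variable of interest is the partial correlation r = t / sqrt(t^2 + df).
Raw p-values across the family of diagnostics are adjusted with Hochberg's
step-up procedure. Test-retest reliability uses the two-way ANOVA
decomposition behind ICC(2,1) (absolute agreement) and ICC(3,1)
(consistency), with Fleiss interpretation bands. The two-level
repeated-measures drug contrast is implemented as a difference-score
regression, algebraically equivalent to the repeated-measures ANCOVA F test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "ICCResult",
    "PairedContrast",
    "fit_linear_model",
    "partial_r_from_t",
    "hochberg_adjust",
    "icc",
    "icc_label",
    "paired_condition_contrast",
    "partial_correlation",
]


def partial_r_from_t(t: float, df: float) -> float:
    """Partial correlation implied by a t statistic at its residual df."""
    return float(t / np.sqrt(t * t + df))


@dataclass(frozen=True)
class ModelFit:
    interest: str
    coefficients: pd.Series
    t: float
    p: float
    df: int
    partial_r: float
    perfect_fit: bool = False


def fit_linear_model(
    y: np.ndarray | pd.Series,
    records: pd.DataFrame,
    interest: str,
    covariates: tuple[str, ...] | list[str] = (),
) -> ModelFit:
    """OLS of ``y`` on intercept + interest + covariates.

    Returns the t statistic, two-sided p, residual df, and the partial
    correlation of the interest variable. A numerically perfect fit
    (residual variance ~ 0) is flagged rather than reported as r = 1.
    """
    y = np.asarray(y, dtype=float)
    cols = [interest, *covariates]
    if records[cols].isna().any().any():
        raise ValueError("missing values in model variables")
    X = sm.add_constant(records[cols].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > {X.shape[1] + 1} observations, got {len(y)}")
    res = sm.OLS(y, X).fit()
    df = int(res.df_resid)
    perfect = bool(res.ssr <= 1e-12 * max(1.0, float(np.sum(y * y))))
    t = float(res.tvalues[interest])
    return ModelFit(
        interest=interest,
        coefficients=res.params,
        t=t,
        p=float(res.pvalues[interest]),
        df=df,
        partial_r=1.0 if perfect else partial_r_from_t(t, df),
        perfect_fit=perfect,
    )


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values, returned in the input order.

    With raw p sorted ascending p_(1) <= ... <= p_(m), the adjusted value at
    rank i is min over j >= i of (m - j + 1) * p_(j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass(frozen=True)
class ICCResult:
    icc_2_1: float
    icc_3_1: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    label: str


def icc_label(value: float) -> str:
    """Fleiss interpretation bands."""
    if value < 0.4:
        return "poor"
    if value <= 0.75:
        return "fair to good"
    return "excellent"


def icc(data: np.ndarray) -> ICCResult:
    """Intraclass correlations from a complete subjects x sessions matrix.

    Two-way ANOVA mean squares (rows = subjects, columns = sessions) give

        ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
        ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)

    The interpretation label is attached to ICC(2,1).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 sessions")
    if np.any(np.isnan(x)):
        raise ValueError("ICC requires a complete matrix")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc21 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    icc31 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return ICCResult(
        icc_2_1=float(icc21),
        icc_3_1=float(icc31),
        ms_rows=float(ms_r),
        ms_cols=float(ms_c),
        ms_error=float(ms_e),
        label=icc_label(float(icc21)),
    )


@dataclass(frozen=True)
class PairedContrast:
    f: float
    p: float
    df: int
    mean_difference: float
    degenerate: bool = False


def paired_condition_contrast(
    values_a: np.ndarray,
    values_b: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> PairedContrast:
    """Two-level within-subject condition effect with optional covariates.

    The within-subject difference (B - A) is regressed on an intercept plus
    mean-centered covariates; F(1, df) is the squared t of the intercept,
    df = n - 1 - (number of covariates). A zero-variance difference vector
    (constant shift) is flagged as degenerate rather than reported as an
    infinite F.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("condition vectors must be 1-D and the same length")
    diff = b - a
    n = diff.size
    q = 0 if covariates is None else covariates.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > {q + 2} complete pairs, got {n}")
    if covariates is not None and covariates.isna().any().any():
        raise ValueError("missing covariate values")
    X = np.ones((n, 1))
    if covariates is not None:
        c = covariates.to_numpy(dtype=float)
        X = np.column_stack([X, c - c.mean(axis=0)])
    res = sm.OLS(diff, X).fit()
    df = int(res.df_resid)
    if np.allclose(diff, 0.0):
        return PairedContrast(f=0.0, p=1.0, df=df, mean_difference=0.0)
    if np.allclose(diff, diff.mean()) or res.ssr <= 1e-12 * max(1.0, float(np.sum(diff * diff))):
        # zero-variance nonzero shift: F -> infinity, flagged rather than trusted
        return PairedContrast(f=np.inf, p=0.0, df=df, mean_difference=float(diff.mean()), degenerate=True)
    t0 = float(res.tvalues[0])
    return PairedContrast(
        f=t0 * t0,
        p=float(sps.f.sf(t0 * t0, 1, df)),
        df=df,
        mean_difference=float(diff.mean()),
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float, int]:
    """Partial correlation of x and y given covariates.

    Both variables are residualized on [intercept + covariates] and the
    residuals correlated; t = r * sqrt(df / (1 - r^2)), df = n - q - 2 with
    q covariates. Returns (r, t, p, df). A perfect correlation yields
    t = +/-inf and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    q = 0 if covariates is None else covariates.shape[1]
    if n <= q + 3:
        raise ValueError(f"need n > {q + 3} observations, got {n}")
    Z = np.ones((n, 1))
    if covariates is not None:
        Z = np.column_stack([Z, covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ beta_x
    ry = y - Z @ beta_y
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - q - 2
    if abs(r) >= 1.0 - 1e-12:
        return (1.0 if r > 0 else -1.0), float(np.sign(r) * np.inf), 0.0, df
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return r, float(t), p, df
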