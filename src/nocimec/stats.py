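"""Outlier-treated regression, prediction and agreement statistics.

The cohort analysis relates each subject's minimum evoked current
(MEC, mA) or K_R80 (%) to the rate of change of systolic blood pressure
at skin incision (ROC_BP, %):

* ordinary least-squares regression with iterative Smirnov–Grubbs
  outlier removal on the residuals (one extreme point per iteration,
  refit between removals);
* Pearson correlation with Bonferroni correction across the four
  monitored parameters;
* substitution of a provisional MEC for out-of-range subjects by
  inverting the regression line at their mean ROC_BP;
* Bland–Altman agreement between measured and predicted ROC_BP
  (fixed bias, 1.96·SD limits of agreement, proportional-bias test);
* Fisher-z power analysis for a target correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .response import OUT_OF_RANGE

ALPHA = 0.05
BONFERRONI_M = 4
LOA_MULTIPLIER = 1.96


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    n_used: int
    removed_ids: list
    iterations: int


@dataclass
class GrubbsOutcome:
    statistic: float          # G = max |v - mean| / sd
    critical_value: float
    flagged_index: int | None

    @property
    def significant(self) -> bool:
        return self.flagged_index is not None


@dataclass
class AgreementReport:
    fixed_bias: float         # mean(measured - predicted), %
    loa_low: float
    loa_high: float
    proportional_r: float | None
    proportional_p: float | None


@dataclass
class PowerSpec:
    r_target: float
    alpha: float = ALPHA
    power: float = 0.8


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-distribution p-value (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, m: int = BONFERRONI_M) -> float:
    """Bonferroni-corrected p-value: min(1, m·p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def grubbs_test(values, alpha: float = ALPHA) -> GrubbsOutcome:
    """Two-sided Smirnov–Grubbs test for a single outlier.

    G = max|v − mean|/sd (sample sd).  The critical value is
    ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) quantile of the
    t-distribution at n−2 df.  A constant list has G = 0, no outlier.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return GrubbsOutcome(0.0, grubbs_critical(n, alpha), None)
    dev = np.abs(v - v.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / sd)
    crit = grubbs_critical(n, alpha)
    return GrubbsOutcome(G, crit, i if G > crit else None)


def grubbs_critical(n: int, alpha: float = ALPHA) -> float:
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def iterative_outlier_regression(x, y, ids=None, alpha: float = ALPHA) -> RegressionFit:
    """OLS of y on x with iterative Grubbs removal on the residuals.

    Each iteration fits the line, Grubbs-tests the residuals and, if the
    extreme residual is significant, removes that single pair and refits.
    The loop stops when no outlier is flagged or removal would leave
    fewer than 3 pairs.  The fit at that point is the final line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if ids is None:
        ids = list(range(len(x)))
    ids = list(ids)
    removed: list = []
    iterations = 0
    while True:
        fit = sps.linregress(x, y)
        resid = y - (fit.slope * x + fit.intercept)
        if resid.std(ddof=1) == 0:
            break
        outcome = grubbs_test(resid, alpha=alpha)
        if not outcome.significant or len(x) - 1 < 3:
            break
        i = outcome.flagged_index
        removed.append(ids.pop(i))
        x = np.delete(x, i)
        y = np.delete(y, i)
        iterations += 1
    fit = sps.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n_used=len(x),
        removed_ids=removed,
        iterations=iterations,
    )


def substitute_out_of_range(fit: RegressionFit, oor_roc_bp_values) -> float:
    """Provisional MEC for out-of-range subjects.

    Inverts the regression line at the mean ROC_BP of the out-of-range
    cases: provisional MEC = (mean − intercept) / slope.
    """
    vals = np.asarray(oor_roc_bp_values, dtype=float)
    if len(vals) == 0:
        raise ValueError("need at least one out-of-range ROC_BP value")
    if fit.slope == 0:
        raise ValueError("zero slope: the regression line cannot be inverted")
    return float((vals.mean() - fit.intercept) / fit.slope)


def predict_rocbp(fit: RegressionFit, x) -> float | np.ndarray:
    """Predicted ROC_BP (%) from MEC or K_R80 via the fitted line."""
    out = fit.slope * np.asarray(x, dtype=float) + fit.intercept
    return float(out) if np.ndim(x) == 0 else out


def bland_altman(measured, predicted,
                 loa_multiplier: float = LOA_MULTIPLIER) -> AgreementReport:
    """Bland–Altman agreement between measured and predicted values.

    Differences d = measured − predicted; fixed bias = mean(d); limits
    of agreement = bias ± 1.96·sd(d); proportional bias = Pearson test
    of d against the pairwise means (not applicable when either side is
    constant).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(m) != len(p):
        raise ValueError("measured and predicted must have equal length")
    if len(m) < 3:
        raise ValueError("need at least 3 pairs")
    d = m - p
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (m + p) / 2.0
    if np.std(d) == 0 or np.std(means) == 0:
        prop_r, prop_p = None, None
    else:
        prop_r, prop_p = pearson_test(d, means)
    return AgreementReport(
        fixed_bias=bias,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        proportional_r=prop_r,
        proportional_p=prop_p,
    )


def power_sample_size(spec: PowerSpec) -> int:
    """Sample size to detect a correlation via the Fisher-z approximation.

    n = ((z_{1−α/2} + z_{1−β}) / arctanh(r))², rounded to the nearest
    integer.  At r = 0.5, α = 0.05, power = 0.8 this gives 26.
    """
    if not 0 < spec.r_target < 1:
        raise ValueError("r_target must be in (0, 1)")
    if not 0 < spec.alpha < 1 or not 0 < spec.power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    za = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = sps.norm.ppf(spec.power)
    n = ((za + zb) / np.arctanh(spec.r_target)) ** 2
    return int(round(n))


# ---------------------------------------------------------------------------
# cohort-level analysis
# ---------------------------------------------------------------------------

MEC_COLUMNS = ("mec_k", "mec_hr", "mec_bp", "mec_ppg")


def _numeric_mask(col: pd.Series) -> pd.Series:
    return col.apply(lambda v: not (isinstance(v, str) or v is None or
                                    (isinstance(v, float) and np.isnan(v))))


def analyze_cohort(
    cohort: pd.DataFrame,
    predictor: str = "mec_k",
    alpha: float = ALPHA,
    bonferroni_m: int = BONFERRONI_M,
    loa_multiplier: float = LOA_MULTIPLIER,
) -> dict:
    """Full prediction chain for one predictor column.

    Regresses ROC_BP on the predictor over the subjects where both are
    measurable, with iterative Grubbs outlier treatment; computes the
    provisional MEC for out-of-range subjects from their mean ROC_BP;
    predicts ROC_BP for the whole cohort (outlier-removed subjects
    included, out-of-range subjects at the provisional value); and runs
    the Bland–Altman agreement between measured and predicted ROC_BP.
    """
    col = cohort[predictor]
    measurable = _numeric_mask(col) if predictor in MEC_COLUMNS else col.notna()
    x = col[measurable].astype(float).to_numpy()
    y = cohort.loc[measurable, "roc_bp"].astype(float).to_numpy()
    ids = cohort.loc[measurable, "subject_id"].tolist()
    fit = iterative_outlier_regression(x, y, ids=ids, alpha=alpha)

    oor_mask = ~measurable
    provisional = None
    x_all = col.copy()
    if predictor in MEC_COLUMNS and oor_mask.any():
        oor_vals = cohort.loc[oor_mask, "roc_bp"].astype(float).to_numpy()
        provisional = substitute_out_of_range(fit, oor_vals)
        x_all = x_all.where(measurable, provisional)
    x_all = x_all.astype(float).to_numpy()
    predicted = predict_rocbp(fit, x_all)
    measured = cohort["roc_bp"].astype(float).to_numpy()
    agreement = bland_altman(measured, predicted, loa_multiplier=loa_multiplier)
    return {
        "predictor": predictor,
        "fit": fit,
        "pearson_r": fit.r,
        "p_corrected": bonferroni(fit.p, bonferroni_m),
        "provisional_mec": provisional,
        "predicted_roc_bp": predicted,
        "measured_roc_bp": measured,
        "agreement": agreement,
        "n_out_of_range": int(oor_mask.sum()),
    }
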