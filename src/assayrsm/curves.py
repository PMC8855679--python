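"""Standard-curve fitting and quality control for colorimetric assays.

A standard curve relates analyte mass per well (µg of glucose or
glycogen) to blank-corrected absorbance through Beer's law: a straight
line whose slope is the assay's proportionality constant (A.U./µg).
Readings above a saturation cap (default 1.6 A.U.) deviate from
linearity and are excluded from the fit.  Outlier screening follows the
robust-fit-then-FDR recipe (a ROUT-style procedure with tuning
parameter Q): an iteratively reweighted robust line, a robust residual
scale, then a Benjamini-Hochberg test of absolute studentized
residuals.  Flags are advisory — removing a point is a separate,
logged user decision, since a statistical flag alone is not an
experimental explanation.

Precision is summarized as the intra-assay coefficient of variation,
100·sd/mean of blank-corrected replicates at each level; %CV is only
meaningful after blank correction, when zero absorbance means zero
material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "InsufficientRangeError",
    "StandardCurve",
    "CVSummary",
    "fit_standard_curve",
    "detect_outliers_rout",
    "blank_correct",
    "intra_assay_cv",
]

DEFAULT_CAP = 1.6  # A.U.; linear-range ceiling


class InsufficientRangeError(ValueError):
    """Fewer than 3 usable distinct standard levels below the cap."""


@dataclass
class StandardCurve:
    analyte: str
    slope: float  # A.U. per µg — the proportionality constant
    intercept: float  # A.U.
    slope_se: float
    intercept_se: float
    cap: float
    included: np.ndarray  # mask of observations that entered the fit
    outlier_flags: np.ndarray
    per_level_cv: dict[float, float] = field(default_factory=dict)
    weighted_cv: float = float("nan")
    r2: float = float("nan")

    @property
    def n_used(self) -> int:
        return int(self.included.sum())

    def mass_from_absorbance(self, absorbance) -> np.ndarray:
        """Invert the curve: blank-corrected mass estimate in µg."""
        return (np.asarray(absorbance, float) - self.intercept) / self.slope


def detect_outliers_rout(levels, absorbances, q: float = 0.01) -> np.ndarray:
    """Flag outliers from a linear standard curve, ROUT-style.

    Fits a robust line by iteratively reweighted least squares, forms a
    robust residual scale from the median absolute residual (with a
    small-sample degrees-of-freedom correction), and tests absolute
    studentized residuals with a Benjamini-Hochberg step-up at false
    discovery rate ``q``.  Returns a boolean flag per observation; the
    underlying data and any subsequent fit are not mutated.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError(f"need at least 6 observations for outlier screening, got {n}")
    X = sm.add_constant(x)
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    resid = y - rlm.fittedvalues
    dof = n - 2
    scale = 1.4826 * np.median(np.abs(resid)) * np.sqrt(n / dof)
    # floor the scale so exactly-collinear data cannot divide by zero
    floor = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    scale = max(scale, floor)
    t = np.abs(resid) / scale
    pvals = 2.0 * stats.t.sf(t, dof)
    # Benjamini-Hochberg step-up at rate q
    order = np.argsort(pvals)
    flags = np.zeros(n, dtype=bool)
    thresh = q * (np.arange(1, n + 1)) / n
    passing = np.nonzero(pvals[order] <= thresh)[0]
    if passing.size:
        flags[order[: passing.max() + 1]] = True
    return flags


def fit_standard_curve(
    levels,
    absorbances,
    cap: float = DEFAULT_CAP,
    exclude=None,
    analyte: str = "glycogen",
) -> StandardCurve:
    """Fit the Beer's-law line through sub-cap, non-excluded observations.

    Parameters
    ----------
    levels, absorbances : array-like
        Long-form standards: analyte mass per well (µg) and raw
        absorbance per observation (replicates repeat the level).
    cap : float
        Linear-range ceiling; readings at the cap are kept (the cap is
        the boundary of the usable region, inclusive by default).
    exclude : array-like of bool, optional
        Observations to drop before fitting, e.g. outliers confirmed
        against the experimental log.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    exclude = np.zeros(len(y), bool) if exclude is None else np.asarray(exclude, bool)
    included = (y <= cap) & ~exclude
    if len(np.unique(x[included])) < 3:
        raise InsufficientRangeError(
            "need >= 3 distinct standard levels below the cap"
        )
    X = sm.add_constant(x[included])
    res = sm.OLS(y[included], X).fit()
    intercept, slope = res.params
    # %CV is summarized over the nonzero standards only: the blank's
    # corrected mean hovers around zero, where a CV is meaningless
    cv_mask = included & (x > 0)
    cv = intra_assay_cv(x[cv_mask], y[cv_mask] - intercept)
    flags = np.zeros(len(y), dtype=bool)
    if included.sum() >= 6:
        flags[included] = detect_outliers_rout(x[included], y[included])
    return StandardCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        cap=cap,
        included=included,
        outlier_flags=flags,
        per_level_cv=cv.per_level,
        weighted_cv=cv.weighted,
        r2=float(res.rsquared),
    )


def blank_correct(absorbances, curve: StandardCurve) -> np.ndarray:
    """Subtract the curve intercept so zero absorbance means zero analyte."""
    return np.asarray(absorbances, dtype=float) - curve.intercept


@dataclass
class CVSummary:
    per_level: dict[float, float]  # level -> %CV (NaN where undefined)
    weighted: float  # replicate-count-weighted average %CV
    undefined_levels: list[float]


def intra_assay_cv(levels, blanked_absorbances) -> CVSummary:
    """Per-level and weighted-average intra-assay %CV.

    %CV = 100·sd/mean per level of blank-corrected replicates; the
    weighted average weights each level by its replicate count.  Levels
    whose mean is <= 0 (e.g. the zero standard) have undefined CV and
    are flagged rather than averaged.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(blanked_absorbances, dtype=float)
    per_level: dict[float, float] = {}
    undefined: list[float] = []
    weights: list[tuple[float, int]] = []
    for lv in np.unique(x):
        vals = y[x == lv]
        if len(vals) < 2:
            continue
        m = vals.mean()
        if m <= 0:
            per_level[float(lv)] = float("nan")
            undefined.append(float(lv))
            continue
        cv = 100.0 * vals.std(ddof=1) / m
        per_level[float(lv)] = float(cv)
        weights.append((float(cv), len(vals)))
    if weights:
        wsum = sum(n for _, n in weights)
        weighted = sum(cv * n for cv, n in weights) / wsum
    else:
        weighted = float("nan")
    return CVSummary(per_level=per_level, weighted=float(weighted), undefined_levels=undefined)
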