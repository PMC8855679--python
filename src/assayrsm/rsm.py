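"""Quadratic response-surface fitting, reduction, and diagnostics.

The absorbance surface is modeled as a polynomial in the coded reagent
volumes: a full quadratic with all interaction terms (for three factors,
11 terms: intercept, 3 linear, 3 squares, 3 two-way products, and the
three-way product).  Fitting is ordinary least squares; each coefficient
carries a two-sided t-test of H0: coefficient = 0.  Model reduction
drops terms consistent with zero while preserving hierarchy (a linear
term stays whenever a retained square or interaction involves it), and
competing models are compared by the small-sample corrected Akaike
information criterion

    AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n - K - 1),

where K counts the fitted coefficients plus one variance parameter —
the least-squares convention used by common curve-fitting software.
Center-point replicates dispersed through the run order provide a
process-stability diagnostic (mean absolute deviation over mean < 5%).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .doe import DesignTable

__all__ = [
    "SingularDesignError",
    "ModelTerms",
    "RSMFit",
    "MeasurementSet",
    "full_quadratic_terms",
    "build_design_matrix",
    "fit_ols",
    "reduce_model",
    "aicc",
    "compare_aicc",
    "predict",
    "center_point_drift",
]


class SingularDesignError(ValueError):
    """The design matrix is rank deficient."""


class UndefinedAICcError(ValueError):
    """AICc denominator n - K - 1 is not positive."""


Term = tuple[int, ...]  # exponent vector over factors; all zeros = intercept


@dataclass(frozen=True)
class ModelTerms:
    """Ordered polynomial terms as exponent vectors over the factors.

    ``(0, 0, 0)`` is the intercept, ``(1, 0, 0)`` the first linear term,
    ``(0, 2, 0)`` the second factor's square, ``(1, 1, 1)`` the
    three-way interaction.
    """

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate model terms")
        k = len(self.terms[0])
        if any(len(t) != k for t in self.terms):
            raise ValueError("inconsistent term lengths")
        if tuple([0] * k) not in self.terms:
            raise ValueError("intercept term is required")

    @property
    def k(self) -> int:
        return len(self.terms[0])

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def labels(self, names: list[str] | None = None) -> list[str]:
        names = names or [f"x{i + 1}" for i in range(self.k)]
        out = []
        for t in self.terms:
            parts = [
                names[i] if e == 1 else f"{names[i]}^{e}"
                for i, e in enumerate(t)
                if e > 0
            ]
            out.append(":".join(parts) if parts else "intercept")
        return out


def full_quadratic_terms(k: int) -> ModelTerms:
    """Full quadratic model with all interaction terms for ``k`` factors.

    Intercept, linear terms, pure squares, and every product of distinct
    factors up to the k-way interaction.  For k=3 this is 11 terms.
    """
    terms: list[Term] = [tuple([0] * k)]
    for i in range(k):
        t = [0] * k
        t[i] = 1
        terms.append(tuple(t))
    for i in range(k):
        t = [0] * k
        t[i] = 2
        terms.append(tuple(t))
    # interaction products of 2..k distinct factors
    import itertools

    for order in range(2, k + 1):
        for combo in itertools.combinations(range(k), order):
            t = [0] * k
            for i in combo:
                t[i] = 1
            terms.append(tuple(t))
    return ModelTerms(tuple(terms))


@dataclass
class MeasurementSet:
    """A design together with its measured absorbances (A.U.)."""

    design: DesignTable
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != len(self.design.runs):
            raise ValueError("one absorbance per run is required")
        if np.any(self.y < 0):
            raise ValueError("absorbances must be non-negative")


@dataclass
class RSMFit:
    """A fitted response surface with uncertainty and fit statistics."""

    terms: ModelTerms
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    pvalues: np.ndarray
    rss: float
    df_resid: int
    r2: float
    r2_adj: float
    aicc: float
    n: int
    factor_names: list[str] | None = field(default=None)

    def ci95(self) -> np.ndarray:
        """(p, 2) array of t-based 95% confidence bounds per coefficient."""
        tcrit = stats.t.ppf(0.975, self.df_resid)
        return np.column_stack(
            [self.beta - tcrit * self.se, self.beta + tcrit * self.se]
        )

    def coef(self, term: Term) -> float:
        return float(self.beta[self.terms.terms.index(tuple(term))])

    def to_json(self, path=None) -> str:
        ci = self.ci95()
        report = {
            "terms": self.terms.labels(self.factor_names),
            "exponents": [list(t) for t in self.terms],
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci95": ci.tolist(),
            "p": self.pvalues.tolist(),
            "rss": self.rss,
            "df_resid": self.df_resid,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "aicc": self.aicc,
            "n": self.n,
        }
        text = json.dumps(report, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RSMFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            terms=ModelTerms(tuple(tuple(t) for t in d["exponents"])),
            beta=np.array(d["beta"]),
            se=np.array(d["se"]),
            cov=np.full((len(d["beta"]), len(d["beta"])), np.nan),
            pvalues=np.array(d["p"]),
            rss=d["rss"],
            df_resid=d["df_resid"],
            r2=d["r2"],
            r2_adj=d["r2_adj"],
            aicc=d["aicc"],
            n=d["n"],
        )


def build_design_matrix(
    design: DesignTable | np.ndarray, terms: ModelTerms
) -> np.ndarray:
    """One column per term: products of coded levels raised to exponents."""
    coded = design.coded if isinstance(design, DesignTable) else np.asarray(design, float)
    if coded.ndim == 1:
        coded = coded[None, :]
    exps = np.array(terms.terms)  # (p, k)
    # (n, 1, k) ** (1, p, k) -> product over k
    return np.prod(coded[:, None, :] ** exps[None, :, :], axis=2)


def _aicc_from_rss(rss: float, n: int, n_coef: int, count_variance: bool = True) -> float:
    K = n_coef + (1 if count_variance else 0)
    if n - K - 1 <= 0:
        raise UndefinedAICcError(
            f"AICc undefined: n={n}, K={K} leaves n-K-1={n - K - 1}"
        )
    return n * math.log(rss / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def fit_ols(
    design_matrix: np.ndarray,
    y: np.ndarray,
    terms: ModelTerms,
    factor_names: list[str] | None = None,
) -> RSMFit:
    """Ordinary least squares fit of the response surface.

    Coefficient standard errors come from the residual variance; each
    coefficient carries a two-sided t-test of the hypothesis that its
    true value is zero.
    """
    X = np.asarray(design_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows to fit {p} terms, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    try:
        aicc_value = _aicc_from_rss(rss, n, p)
    except UndefinedAICcError:
        aicc_value = float("nan")  # saturated fit; aicc() will raise
    return RSMFit(
        terms=terms,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        cov=np.asarray(res.cov_params()),
        pvalues=np.asarray(res.pvalues),
        rss=rss,
        df_resid=int(res.df_resid),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        aicc=aicc_value,
        n=n,
    )


def fit_measurements(
    measurements: MeasurementSet, terms: ModelTerms
) -> RSMFit:
    """Convenience: build the design matrix and fit in one call."""
    X = build_design_matrix(measurements.design, terms)
    names = (
        [f.name for f in measurements.design.factors]
        if measurements.design.factors
        else None
    )
    fit = fit_ols(X, measurements.y, terms, factor_names=names)
    fit.factor_names = names
    return fit


def reduce_model(fit: RSMFit, alpha: float = 0.05) -> ModelTerms:
    """Drop terms not distinguishable from zero, preserving hierarchy.

    A term is removed when its coefficient's two-sided p-value is >=
    ``alpha`` (its estimate is consistent with zero).  The intercept is
    never removed, and a linear term is retained whenever any retained
    square or interaction involves that factor — interactions require
    their main effects.  Two-way interactions are not themselves
    protected by a retained higher-order interaction; only their own
    test keeps them.
    """
    keep: list[Term] = []
    dropped: list[Term] = []
    for t, p in zip(fit.terms, fit.pvalues):
        if sum(t) == 0:
            keep.append(t)  # intercept
        elif p < alpha:
            keep.append(t)
        else:
            dropped.append(t)
    # hierarchy: resurrect linear terms required by retained higher terms
    needed = set()
    for t in keep:
        if sum(t) >= 2:
            for i, e in enumerate(t):
                if e > 0:
                    lin = tuple(1 if j == i else 0 for j in range(len(t)))
                    needed.add(lin)
    for t in list(dropped):
        if t in needed:
            dropped.remove(t)
            keep.append(t)
    # preserve the original term ordering
    order = {t: i for i, t in enumerate(fit.terms)}
    keep.sort(key=order.__getitem__)
    return ModelTerms(tuple(keep))


def aicc(fit: RSMFit, count_variance: bool = True) -> float:
    """Corrected AIC of a fit; K = coefficients + 1 by default."""
    return _aicc_from_rss(fit.rss, fit.n, len(fit.terms), count_variance)


def compare_aicc(fit_a: RSMFit, fit_b: RSMFit) -> tuple[float, float]:
    """AICc difference a - b, and the probability that model a is correct.

    ``prob_correct = 1 / (1 + exp(delta/2))``: above 0.5 when model a
    has the lower AICc.  The two orderings give probabilities summing
    to 1 and deltas of opposite sign.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("models must be fitted to the same data")
    delta = aicc(fit_a) - aicc(fit_b)
    prob = 1.0 / (1.0 + math.exp(delta / 2.0))
    return delta, prob


def predict(
    fit: RSMFit, coded_point, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Surface estimate at a coded point with a t-based confidence interval.

    Points beyond the axial distance in any coordinate are extrapolation
    and produce a warning rather than an error.
    """
    x = build_design_matrix(np.asarray(coded_point, float), fit.terms)[0]
    from .doe import axial_distance

    alpha_dist = axial_distance(fit.terms.k) if fit.terms.k >= 2 else 1.0
    pt = np.asarray(coded_point, float)
    # tolerance absorbs axial levels quoted at 3 d.p. (1.682 vs 2^(3/4))
    if np.any(np.abs(pt) > alpha_dist + 1e-3):
        warnings.warn(
            f"coded point {pt.tolist()} lies outside the design region "
            f"(|coded| > {alpha_dist:.3f}); prediction is extrapolation",
            UserWarning,
            stacklevel=2,
        )
    est = float(x @ fit.beta)
    var = float(x @ fit.cov @ x)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
    half = tcrit * math.sqrt(max(var, 0.0))
    return est, (est - half, est + half)


@dataclass
class CenterPointDrift:
    """Process-stability summary from replicated center points."""

    order: np.ndarray  # run order positions of the center points
    residuals: np.ndarray  # center absorbance minus center mean, in run order
    mean: float
    mad: float
    mad_over_mean: float
    passed: bool


def center_point_drift(
    measurements: MeasurementSet, threshold: float = 0.05
) -> CenterPointDrift:
    """Residuals of center replicates against run order, and MAD/mean test.

    The replicated center points bracket and intersperse the sequence;
    their mean absolute deviation around their mean, relative to that
    mean, flags process instability (color decay, drift) when it exceeds
    ``threshold`` (default 5%).
    """
    mask = measurements.design.center_mask()
    if mask.sum() < 2:
        raise ValueError("need at least 2 center points for drift diagnostics")
    yc = measurements.y[mask]
    order = np.nonzero(mask)[0] + 1
    mean = float(yc.mean())
    resid = yc - mean
    mad = float(np.abs(resid).mean())
    ratio = mad / mean
    return CenterPointDrift(
        order=order,
        residuals=resid,
        mean=mean,
        mad=mad,
        mad_over_mean=ratio,
        passed=bool(ratio < threshold),
    )
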