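"""Logistic risk model for balance alteration, with Hosmer–Lemeshow
calibration, probability prediction and Cochran sample-size planning.

The model is

    P(balance alteration) = 1 / (1 + exp(-(b0 + b1*DIC + b2*SEX + b3*AGE + b4*BMI)))

where DIC flags a mean AP CoP velocity at or above the screening
cut-off, SEX is coded woman = 1, AGE is in years and BMI in kg/m².
Inference is Wald-based on the maximum-likelihood fit; odds ratios are
exp(beta) with exponentiated Wald confidence limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import roc_analysis

__all__ = [
    "LogisticFit",
    "SampleSizeSpec",
    "MODEL_COVARIATES",
    "fit_logistic",
    "predict_probability",
    "hosmer_lemeshow",
    "cochran_sample_size",
    "model_auc",
]

#: Default design-matrix columns (after the constant), in Table-style order.
MODEL_COVARIATES = ("mvelap_dic", "sex_woman", "age", "bmi")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


@dataclass(frozen=True)
class LogisticFit:
    names: tuple[str, ...]  # const first
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    n_used: int
    n_dropped: int
    log_likelihood: float
    fitted: np.ndarray = field(repr=False)
    endpoint: np.ndarray = field(repr=False)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "OR": self.odds_ratios, "beta": self.beta, "SE": self.se,
            "p_value": self.p_values, "ci_low": self.or_ci_low,
            "ci_high": self.or_ci_high,
        }, index=list(self.names))

    def display_frame(self) -> pd.DataFrame:
        """Rounded for display: beta/OR to 2 dp, p to 3 dp."""
        df = self.summary_frame()
        return pd.DataFrame({
            "OR": df["OR"].round(2), "beta": df["beta"].round(2),
            "p_value": df["p_value"].round(3),
            "ci_low": df["ci_low"].round(2), "ci_high": df["ci_high"].round(2),
        }, index=df.index)


@dataclass(frozen=True)
class SampleSizeSpec:
    z: float
    p: float
    q: float
    d: float
    n_exact: float
    n_required: int


def fit_logistic(design: pd.DataFrame, endpoint, level: float = 0.95,
                 tol: float = 1e-8, maxiter: int = 50) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``design`` holds the covariate columns (no constant; one is added).
    Rows with any missing covariate or endpoint are dropped
    (complete-case analysis) and counted in ``n_dropped``.
    """
    y = pd.Series(np.asarray(endpoint).astype(float), index=design.index)
    keep = design.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    X = design.loc[keep].astype(float)
    y = y.loc[keep]
    if y.nunique() < 2:
        raise ValueError("endpoint must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, tol=tol, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True):
        se = np.asarray(res.bse)
        worst = Xc.columns[int(np.argmax(se))]
        raise SeparationError(
            f"logistic fit did not converge (suspect separation on {worst!r})")
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return LogisticFit(
        names=tuple(Xc.columns), beta=beta, se=se,
        p_values=np.asarray(res.pvalues), odds_ratios=np.exp(beta),
        or_ci_low=np.exp(beta - z * se), or_ci_high=np.exp(beta + z * se),
        n_used=int(keep.sum()), n_dropped=n_dropped,
        log_likelihood=float(res.llf),
        fitted=np.asarray(res.predict(Xc)), endpoint=y.to_numpy(),
    )


def predict_probability(beta, x) -> float:
    """Inverse-logit prediction 1 / (1 + exp(-(b0 + sum b_i x_i))).

    ``beta`` is a coefficient vector with the constant first (a
    LogisticFit is also accepted); ``x`` the covariates without the
    constant, in matching order.
    """
    if isinstance(beta, LogisticFit):
        beta = beta.beta
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != len(beta) - 1:
        raise ValueError(f"expected {len(beta) - 1} covariates, got {len(x)}")
    lp = beta[0] + float(beta[1:] @ x)
    return 1.0 / (1.0 + math.exp(-lp))


def hosmer_lemeshow(probabilities, endpoint, g: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit test.

    Subjects are ranked by fitted probability and split into ``g``
    equal-count groups (tied probabilities stay together); the statistic
    sums (observed - expected)^2 / expected over both outcomes in each
    group and is referred to chi-square with g - 2 degrees of freedom.
    Returns (chi2, df, p).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(endpoint).astype(float)
    if p.shape != y.shape:
        raise ValueError("probabilities and endpoint must align")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    n = len(p)
    edges = np.round(np.linspace(0, n, g + 1)).astype(int)
    # keep ties together: push each interior edge past any run of equal p
    for k in range(1, g):
        e = edges[k]
        while 0 < e < n and p[e] == p[e - 1]:
            e += 1
        edges[k] = e
    chi2 = 0.0
    for k in range(g):
        lo, hi = edges[k], edges[k + 1]
        if hi <= lo:
            continue
        n_g = hi - lo
        obs1 = float(y[lo:hi].sum())
        exp1 = float(p[lo:hi].sum())
        exp0 = n_g - exp1
        if exp1 <= 0.0 or exp0 <= 0.0:
            raise ValueError(f"group {k} has zero expected count; use smaller g")
        chi2 += (obs1 - exp1) ** 2 / exp1 + ((n_g - obs1) - exp0) ** 2 / exp0
    df = g - 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


def cochran_sample_size(p: float, d: float, confidence: float = 0.95) -> SampleSizeSpec:
    """Cochran's large-population sample size n = z^2 p q / d^2, rounded up."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not 0.0 < d < 1.0:
        raise ValueError("d must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    # the conventional two-decimal quantile (1.96 at 95%), as used in planning
    z = round(z, 2)
    q = 1.0 - p
    n_exact = z ** 2 * p * q / d ** 2
    return SampleSizeSpec(z=z, p=p, q=q, d=d, n_exact=n_exact,
                          n_required=math.ceil(n_exact - 1e-9))


def likelihood_ratio_test(design: pd.DataFrame, endpoint,
                          covariate: str) -> tuple[float, float]:
    """Likelihood-ratio test for one covariate (alternative to the Wald
    p-value reported by ``fit_logistic``).  Returns (LR chi2, p)."""
    full = fit_logistic(design, endpoint)
    reduced = fit_logistic(design.drop(columns=[covariate]), endpoint)
    lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    return lr, float(stats.chi2.sf(lr, 1))


def model_auc(fit: LogisticFit) -> roc_analysis.ROCResult:
    """ROC of the fitted probabilities against the observed endpoint."""
    return roc_analysis.roc_curve(fit.fitted, fit.endpoint.astype(int))
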