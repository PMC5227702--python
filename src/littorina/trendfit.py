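"""Best-fit latitudinal regression and Pearson correlation.

Population trait means (metabolic rate, growth, shell metrics) are regressed
on latitude with ordinary least squares, comparing a linear and a quadratic
form; the reported model minimizes AIC, with ties broken toward fewer
parameters.  For least squares with Gaussian errors,

    AIC = n * ln(RSS / n) + 2 * (k + 1)

where k is the number of fitted coefficients (the +1 counts the error
variance).  AICc (the small-sample correction) is available via a flag since
latitudinal designs often have only a handful of populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TrendFit:
    form: str  # 'linear' | 'quadratic'
    coefficients: np.ndarray  # ascending powers: [b0, b1, (b2)]
    r_squared: float
    aic: float
    r: float  # sign-adjusted sqrt(R^2) (linear) or multiple R (quadratic)
    df: int  # residual df, n - k
    p_value: float  # F test of the regression
    aic_by_form: dict[str, float] | None = None
    r2_by_form: dict[str, float] | None = None


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int):
    X = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef, rss, r2


def _aic_ls(n: int, rss: float, k: int, corrected: bool) -> float:
    rss = max(rss, 1e-300)  # exact fits: AIC -> -inf, keep finite ordering
    aic = n * np.log(rss / n) + 2 * (k + 1)
    if corrected:
        denom = n - (k + 1) - 1
        if denom > 0:
            aic += 2 * (k + 1) * (k + 2) / denom
        else:
            aic = np.inf
    return float(aic)


def fit_trend(
    x: np.ndarray,
    y: np.ndarray,
    forms: tuple[str, ...] = ("linear", "quadratic"),
    corrected: bool = False,
) -> TrendFit:
    """Fit each candidate polynomial form and keep the AIC-minimizing one.

    Requires n >= 4 so the quadratic retains a residual degree of freedom.
    ``r`` is the sign-adjusted sqrt(R^2) for the linear form and the multiple
    correlation for the quadratic; ``p_value`` is from the regression F test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y length mismatch")
    if x.size < 4:
        raise ValueError("need n >= 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    degrees = {"linear": 1, "quadratic": 2}
    unknown = set(forms) - set(degrees)
    if unknown:
        raise ValueError(f"unknown forms {unknown}")

    n = x.size
    fits = {}
    for form in forms:
        deg = degrees[form]
        coef, rss, r2 = _ols_poly(x, y, deg)
        k = deg + 1
        fits[form] = (coef, rss, r2, _aic_ls(n, rss, k, corrected), k)

    # minimum AIC; ties toward fewer parameters (iterate simple -> complex)
    best_form = min(
        sorted(fits, key=lambda f: degrees[f]), key=lambda f: fits[f][3]
    )
    coef, rss, r2, aic, k = fits[best_form]

    df_model = k - 1
    df_resid = n - k
    if rss <= 1e-300 or r2 >= 1.0:
        f_p = 0.0
    else:
        f_stat = (r2 / df_model) / ((1 - r2) / df_resid)
        f_p = float(stats.f.sf(f_stat, df_model, df_resid))
    r = np.sqrt(max(r2, 0.0))
    if best_form == "linear":
        r *= np.sign(coef[1]) if coef[1] != 0 else 1.0

    return TrendFit(
        form=best_form,
        coefficients=coef,
        r_squared=r2,
        aic=aic,
        r=float(r),
        df=df_resid,
        p_value=f_p,
        aic_by_form={f: fits[f][3] for f in fits},
        r2_by_form={f: fits[f][2] for f in fits},
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Product-moment correlation with two-sided p from the t transform.

    Returns (r, df, p) with df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), x.size - 2, float(res.pvalue)
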