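"""Two-interruption segmented regression for interrupted time series.

The outcome series :math:`Y_t` (here a monthly percentage) is modelled as

.. math::

    Y_t = \\beta_0 + \\beta_1\\,t + \\beta_2\\,I_1(t) + \\beta_3\\,c_1(t)
          + \\beta_4\\,I_2(t) + \\beta_5\\,c_2(t) + \\varepsilon_t

where :math:`I_1` switches from 0 to 1 at the first interruption month
:math:`m_1` (and :math:`I_2` at :math:`m_2`), and the post-interruption clocks
:math:`c_1(t) = \\max(0, t - (m_1-1))`, :math:`c_2(t) = \\max(0, t - (m_2-1))`
count months since each interruption (1 in the interruption month itself).
:math:`\\beta_2,\\beta_4` are level changes, :math:`\\beta_3,\\beta_5` trend
changes; the post-interruption slope is :math:`\\beta_1+\\beta_3` (and
:math:`\\beta_1+\\beta_3+\\beta_5` after the second interruption).

Estimation follows the usual two-step practice: fit ordinary least squares,
test the residuals for first-order serial correlation with the Durbin-Watson
statistic, and — when serial correlation is significant — refit by exact
maximum likelihood under stationary AR(1) errors
:math:`\\varepsilon_t = \\rho\\,\\varepsilon_{t-1} + u_t`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

FULL_TERMS = ("intercept", "time", "nims", "time_after_nims", "covid", "time_after_covid")
SINGLE_TERMS = FULL_TERMS[:4]

# Human-readable coefficient labels in reporting order.
TERM_LABELS = {
    "intercept": "Intercept (b0)",
    "time": "Baseline trend (b1)",
    "nims": "Level change after NIMS (b2)",
    "time_after_nims": "Trend change after NIMS (b3)",
    "covid": "Level change after COVID-19 (b4)",
    "time_after_covid": "Trend change after COVID-19 (b5)",
}


class FitError(RuntimeError):
    """Raised when an estimator fails (rank deficiency or non-convergence)."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class DesignMatrix:
    """Segmented-regression design for months t = 1..n.

    ``X`` has columns intercept, time, nims, time_after_nims and — when a
    second interruption is supplied — covid, time_after_covid.  ``m1``/``m2``
    are 1-based interruption month indices.
    """

    X: pd.DataFrame
    m1: int
    m2: int | None

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


@dataclass
class ITSFit:
    """A fitted segmented regression with inference.

    ``dw``/``dw_p`` always describe the OLS residuals (the published
    convention); for an AR(1)-ML refit the final-model Durbin-Watson is kept
    in ``dw_final`` alongside.
    """

    estimator: str                      # "OLS" or "AR1-ML"
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rho_hat: float
    sigma_hat: float
    dw: float
    dw_p: float
    residuals: pd.Series
    fitted: pd.Series
    loglik: float
    design: DesignMatrix
    dw_final: float = float("nan")
    cov_params: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def build_design(n_months: int, m1: int, m2: int | None = None) -> DesignMatrix:
    """Build the segmented design for ``n_months`` with interruptions at m1 (, m2).

    The level indicators are 1 from the interruption month on; the
    post-interruption clocks equal ``t - (m - 1)`` from month m on (so 1 in the
    interruption month itself) and 0 before.  With ``m2=None`` the two second-
    interruption columns are omitted (single-interruption variant).  Segments
    shorter than 12 months trigger a warning, not an error.
    """
    if n_months < 3:
        raise ValueError("n_months must be >= 3")
    if not (1 < m1 <= n_months):
        raise ValueError(f"m1 must satisfy 1 < m1 <= n_months, got {m1}")
    if m2 is not None and not (m1 < m2 <= n_months):
        raise ValueError(f"m2 must satisfy m1 < m2 <= n_months, got {m2}")

    t = np.arange(1, n_months + 1)
    cols = {
        "intercept": np.ones(n_months),
        "time": t.astype(float),
        "nims": (t >= m1).astype(float),
        "time_after_nims": np.where(t >= m1, t - (m1 - 1), 0).astype(float),
    }
    if m2 is not None:
        cols["covid"] = (t >= m2).astype(float)
        cols["time_after_covid"] = np.where(t >= m2, t - (m2 - 1), 0).astype(float)

    bounds = [m1 - 1, (m2 - m1 if m2 else n_months - m1 + 1)]
    if m2 is not None:
        bounds.append(n_months - m2 + 1)
    if min(bounds) < 12:
        warnings.warn(
            f"segment lengths {bounds} include fewer than the recommended "
            "12 monthly observations", UserWarning, stacklevel=2)

    X = pd.DataFrame(cols, index=pd.Index(t, name="t"))
    return DesignMatrix(X=X, m1=m1, m2=m2)


def _prepare_y(design: DesignMatrix, y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(pd.Series(y, dtype=float))
    if len(y) != design.n:
        raise ValueError(f"y has length {len(y)}, design has {design.n} rows")
    mask = np.isfinite(y)
    if not mask.all():
        warnings.warn(
            f"dropping {int((~mask).sum())} missing month(s) listwise; design "
            "rows keep their calendar t", UserWarning, stacklevel=3)
    return y, mask


def _check_rank(Xv: np.ndarray, terms: Sequence[str]) -> None:
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        _, R = np.linalg.qr(Xv)
        bad = [terms[j] for j in range(Xv.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise FitError(f"rank-deficient design; collinear column(s): {bad or terms}")


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def fit_ols(design: DesignMatrix, y) -> ITSFit:
    """Ordinary least squares with classical (n - p) inference."""
    y_full, mask = _prepare_y(design, y)
    Xv = design.X.to_numpy()[mask]
    yv = y_full[mask]
    n, p = Xv.shape
    if n <= p:
        raise FitError(f"too few observations ({n}) for {p} coefficients")
    _check_rank(Xv, design.terms)

    beta, _, _, _ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = yv - Xv @ beta
    ssr = float(resid @ resid)
    dof = n - p
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(Xv.T @ Xv)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    loglik = -0.5 * n * (np.log(2 * np.pi * ssr / n) + 1)

    idx = pd.Index(design.terms)
    t_index = design.X.index[mask]
    dw_stat, dw_p = durbin_watson(resid, design=design, mask=mask)
    return ITSFit(
        estimator="OLS",
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        rho_hat=0.0,
        sigma_hat=float(np.sqrt(sigma2)),
        dw=dw_stat,
        dw_p=dw_p,
        residuals=pd.Series(resid, index=t_index),
        fitted=pd.Series(Xv @ beta, index=t_index),
        loglik=float(loglik),
        design=design,
        dw_final=dw_stat,
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# Durbin-Watson
# ---------------------------------------------------------------------------

def _dw_matrix(n: int) -> np.ndarray:
    A = np.zeros((n, n))
    i = np.arange(n)
    A[i, i] = 2.0
    A[0, 0] = A[-1, -1] = 1.0
    A[i[:-1], i[:-1] + 1] = -1.0
    A[i[:-1] + 1, i[:-1]] = -1.0
    return A


def durbin_watson(
    residuals,
    design: DesignMatrix | None = None,
    mask: np.ndarray | None = None,
    method: str = "normal",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Durbin-Watson statistic and a two-sided significance approximation.

    statistic = sum((e_t - e_{t-1})^2) / sum(e_t^2).  With the design supplied,
    the p-value uses a normal approximation with the exact null mean and
    variance of the statistic given that design (Durbin-Watson moment
    formulas); ``method="bootstrap"`` replaces it with a Monte-Carlo null.
    Without a design a cruder N(2, 4/n) reference is used.  All-zero residuals
    leave the statistic undefined (NaN, NaN with a warning).
    """
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(e @ e)
    if denom == 0.0:
        warnings.warn("all-zero residuals: Durbin-Watson undefined",
                      UserWarning, stacklevel=2)
        return float("nan"), float("nan")
    d = float(np.sum(np.diff(e) ** 2) / denom)

    n = len(e)
    if design is None:
        mean, var = 2.0, 4.0 / n
    else:
        Xv = design.X.to_numpy()
        if mask is not None:
            Xv = Xv[mask]
        k = Xv.shape[1]
        M = np.eye(n) - Xv @ np.linalg.pinv(Xv)
        MA = M @ _dw_matrix(n)
        nu = n - k
        s1 = np.trace(MA)
        s2 = np.trace(MA @ MA)
        mean = s1 / nu
        var = 2.0 * (s2 - s1**2 / nu) / (nu * (nu + 2))
        if method == "bootstrap":
            rng = rng or np.random.default_rng(0)
            eps = rng.standard_normal((n_boot, n))
            eb = eps @ M.T
            db = np.sum(np.diff(eb, axis=1) ** 2, axis=1) / np.sum(eb**2, axis=1)
            p = float(np.mean(np.abs(db - mean) >= abs(d - mean)))
            return d, p
    z = (d - mean) / np.sqrt(var)
    return d, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# AR(1) maximum likelihood
# ---------------------------------------------------------------------------

def _ar1_transform(Xv: np.ndarray, yv: np.ndarray, rho: float):
    """Prais-Winsten whitening for stationary AR(1) errors."""
    c = np.sqrt(1.0 - rho * rho)
    Xs = Xv.copy()
    ys = yv.copy()
    Xs[0] *= c
    ys[0] *= c
    Xs[1:] = Xv[1:] - rho * Xv[:-1]
    ys[1:] = yv[1:] - rho * yv[:-1]
    return Xs, ys


def _profile_loglik(rho: float, Xv: np.ndarray, yv: np.ndarray) -> float:
    """Exact stationary-AR(1) Gaussian log-likelihood, profiled over beta, sigma."""
    n = len(yv)
    Xs, ys = _ar1_transform(Xv, yv, rho)
    beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    ssr = float(resid @ resid)
    if ssr <= 0:
        ssr = 1e-300
    sigma2 = ssr / n
    return (-0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
            + 0.5 * np.log(1.0 - rho * rho))


def fit_ar1_ml(
    design: DesignMatrix,
    y,
    rho_bounds: tuple[float, float] = (-0.99, 0.99),
    maxiter: int = 200,
) -> ITSFit:
    """Exact Gaussian ML for the regression with stationary AR(1) errors.

    Maximizes the profile likelihood over rho (bounded search starting from
    rho = 0), with beta and sigma concentrated out via generalized least
    squares on the Prais-Winsten transform.  Coefficient covariance is the GLS
    covariance at rho_hat; p-values use the large-sample normal reference.
    """
    y_full, mask = _prepare_y(design, y)
    Xv = design.X.to_numpy()[mask]
    yv = y_full[mask]
    n, p = Xv.shape
    if n <= p + 1:
        raise FitError(f"too few observations ({n}) for AR(1)-ML with {p} coefficients")
    _check_rank(Xv, design.terms)

    res = optimize.minimize(
        lambda r: -_profile_loglik(float(r[0]), Xv, yv),
        x0=[0.0], bounds=[rho_bounds], method="L-BFGS-B",
        options={"maxiter": maxiter})
    if not res.success:
        raise FitError(f"AR(1)-ML did not converge: {res.message}", trace=res)
    rho = float(res.x[0])

    Xs, ys = _ar1_transform(Xv, yv, rho)
    beta, _, _, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    white_resid = ys - Xs @ beta
    ssr = float(white_resid @ white_resid)
    sigma2 = ssr / n                     # ML innovation variance
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    resid = yv - Xv @ beta               # AR(1)-correlated residuals on the original scale
    loglik = _profile_loglik(rho, Xv, yv)

    idx = pd.Index(design.terms)
    t_index = design.X.index[mask]
    dw_final, _ = durbin_watson(resid, design=design, mask=mask)
    return ITSFit(
        estimator="AR1-ML",
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        rho_hat=rho,
        sigma_hat=float(np.sqrt(sigma2)),
        dw=float("nan"),                 # filled by fit_its with the OLS value
        dw_p=float("nan"),
        residuals=pd.Series(resid, index=t_index),
        fitted=pd.Series(Xv @ beta, index=t_index),
        loglik=float(loglik),
        design=design,
        dw_final=dw_final,
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
    )


def fit_its(design: DesignMatrix, y, alpha: float = 0.05,
            estimator: str = "auto") -> ITSFit:
    """Fit OLS, test the residuals with Durbin-Watson, refit AR(1)-ML if needed.

    With ``estimator="auto"`` the AR(1)-ML refit replaces OLS when the DW test
    is significant at ``alpha``; the OLS Durbin-Watson statistic and p-value
    are carried on the returned fit either way (the reporting convention).
    ``estimator`` may force ``"ols"`` or ``"ar1"``.
    """
    ols = fit_ols(design, y)
    if estimator == "ols":
        return ols
    use_ar1 = estimator == "ar1" or (
        estimator == "auto" and np.isfinite(ols.dw_p) and ols.dw_p < alpha)
    if not use_ar1:
        return ols
    fit = fit_ar1_ml(design, y)
    fit.dw = ols.dw
    fit.dw_p = ols.dw_p
    return fit


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def post_slope(fit, which: str = "after_first") -> float:
    """Post-interruption slope: b1+b3 after the first, b1+b3+b5 after the second.

    ``fit`` may be an :class:`ITSFit` or any mapping of term name -> coefficient.
    """
    coefs = fit.params if isinstance(fit, ITSFit) else pd.Series(dict(fit))
    if which == "after_first":
        return float(coefs["time"] + coefs["time_after_nims"])
    if which == "after_second":
        if "time_after_covid" not in coefs:
            raise ValueError("fit has no second interruption; cannot compute "
                             "the slope after it")
        return float(coefs["time"] + coefs["time_after_nims"]
                     + coefs["time_after_covid"])
    raise ValueError(f"which must be 'after_first' or 'after_second', got {which!r}")


def predict_lines(fit: ITSFit, design: DesignMatrix | None = None) -> pd.DataFrame:
    """Fitted segment means plus counterfactual extensions for plotting.

    ``counterfactual_pre`` extends the pre-first-interruption line forward
    (all interruption terms zeroed); ``counterfactual_mid`` (two-interruption
    fits only) extends the between-interruptions model past the second
    interruption (second-interruption terms zeroed).
    """
    design = design or fit.design
    X = design.X
    beta = fit.params.reindex(X.columns).to_numpy()
    out = pd.DataFrame(index=X.index)
    out["fitted"] = X.to_numpy() @ beta

    X_pre = X.copy()
    for col in ("nims", "time_after_nims", "covid", "time_after_covid"):
        if col in X_pre:
            X_pre[col] = 0.0
    out["counterfactual_pre"] = X_pre.to_numpy() @ beta

    if design.m2 is not None:
        X_mid = X.copy()
        for col in ("covid", "time_after_covid"):
            X_mid[col] = 0.0
        out["counterfactual_mid"] = X_mid.to_numpy() @ beta
    return out


def residual_diagnostics(fit: ITSFit, max_lag: int = 20) -> pd.DataFrame:
    """Sample ACF/PACF of the fit residuals with +-1.96/sqrt(n) bounds."""
    from statsmodels.tsa.stattools import acf, pacf

    e = fit.residuals.to_numpy()
    n = len(e)
    if n < max_lag + 2:
        raise ValueError(f"need at least max_lag+2={max_lag + 2} residuals, have {n}")
    acf_vals = acf(e, nlags=max_lag, fft=False)
    pacf_vals = pacf(e, nlags=max_lag, method="ywm")
    bound = 1.96 / np.sqrt(n)
    return pd.DataFrame({
        "lag": np.arange(max_lag + 1),
        "acf": acf_vals,
        "pacf": pacf_vals,
        "lower": -bound,
        "upper": bound,
    }).set_index("lag")
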