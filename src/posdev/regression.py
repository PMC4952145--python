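"""Linear-model machinery for positive-deviance screening.

Ordinary least squares via singular-value decomposition (minimum-norm under
rank deficiency), hat-matrix leverages, externally studentized residuals by
the closed-form leave-one-out downdate, the Gaussian maximum log-likelihood,
likelihood-ratio comparison of nested fits, and Cook's-distance influence
diagnostics.

Conventions
-----------
* The design matrix always carries an explicit intercept column.
* ``p`` is the *effective rank* of the design, so degrees of freedom stay
  correct when sensitivity analyses drop or duplicate collinear covariates.
* "Studentized" means **externally** studentized: the residual scale for unit
  i is estimated with unit i excluded, so a gross outlier cannot mask itself
  by inflating the pooled error variance.  Under a correct Gaussian model
  t_i ~ Student-t with n - p - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDFError, NestingError, UnderdeterminedFitError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelFit:
    """A fitted ordinary-least-squares model and everything screening needs.

    ``coefficients`` aligns with ``column_names`` (intercept first);
    ``sigma2_mle`` is RSS/n (the ML error variance used by the LRT),
    ``sigma2_unbiased`` is RSS/(n - p).
    """

    outcome_name: str
    stratum: tuple
    step: str  # "context_only" or "full"
    column_names: list[str]
    coefficients: np.ndarray
    residuals: np.ndarray
    fitted_values: np.ndarray
    hat_diag: np.ndarray
    sigma2_mle: float
    sigma2_unbiased: float
    log_likelihood: float
    r_squared: float
    n: int
    p: int  # effective rank
    unit_ids: list[Hashable]
    degenerate: bool = False
    # SVD pieces retained for covariance / influence computations
    _svd: tuple = field(default=None, repr=False)

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    def cov_unscaled(self) -> np.ndarray:
        """Pseudo-inverse of X'X restricted to the estimable subspace."""
        s, Vt = self._svd[1], self._svd[2]
        return (Vt.T / s**2) @ Vt

    def coef_standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_unscaled()) * self.sigma2_unbiased)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Per-coefficient t intervals, shape (len(coefficients), 2)."""
        se = self.coef_standard_errors()
        q = stats.t.ppf(0.5 + level / 2.0, self.n - self.p)
        return np.column_stack([self.coefficients - q * se, self.coefficients + q * se])


def fit_ols(
    y: np.ndarray,
    design: np.ndarray,
    unit_ids: Sequence[Hashable],
    column_names: Sequence[str] | None = None,
    outcome_name: str = "",
    stratum: tuple = (),
    step: str = "",
) -> ModelFit:
    """Least-squares fit via SVD; minimum-norm solution under rank deficiency.

    Raises :class:`UnderdeterminedFitError` when n <= number of columns.  A
    zero-variance outcome is fit (intercept absorbs it) with ``r_squared`` 0
    and ``degenerate`` set.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-dimensional")
    n, n_cols = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match design rows")
    if n <= n_cols:
        raise UnderdeterminedFitError(
            f"n = {n} <= {n_cols} design columns: fit is underdetermined"
        )
    if column_names is None:
        column_names = [f"x{j}" for j in range(n_cols)]
    column_names = list(column_names)
    if len(column_names) != n_cols:
        raise ValueError("column_names length does not match design columns")
    unit_ids = list(unit_ids)
    if len(unit_ids) != n:
        raise ValueError("unit_ids length does not match design rows")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(n, n_cols) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    Ur, sr, Vr = U[:, :rank], s[:rank], Vt[:rank]
    coef = Vr.T @ ((Ur.T @ y) / sr)
    fitted = Ur @ (Ur.T @ y)
    resid = y - fitted
    hat = np.einsum("ij,ij->i", Ur, Ur)
    rss = float(resid @ resid)
    sigma2_mle = rss / n
    sigma2_unb = rss / (n - rank) if n > rank else np.nan

    const_cols = np.ptp(X, axis=0) == 0.0
    has_intercept = bool(np.any(const_cols & (X[0] != 0.0)))
    tss = float(np.sum((y - y.mean()) ** 2)) if has_intercept else float(y @ y)
    degenerate = False
    if tss <= 0.0:
        r2 = 0.0
        degenerate = True
    else:
        r2 = 1.0 - rss / tss
        r2 = float(min(1.0, max(0.0, r2)))

    # an RSS that is zero up to rounding (relative to the outcome's scale)
    # is a perfect fit: infinite-likelihood sentinel
    rss_eff = 0.0 if rss <= 1e-12 * max(tss, 1e-300) else rss
    ll = log_likelihood_from_rss(rss_eff, n)
    return ModelFit(
        outcome_name=outcome_name,
        stratum=tuple(stratum),
        step=step,
        column_names=column_names,
        coefficients=coef,
        residuals=resid,
        fitted_values=fitted,
        hat_diag=hat,
        sigma2_mle=sigma2_mle,
        sigma2_unbiased=sigma2_unb,
        log_likelihood=ll,
        r_squared=r2,
        n=n,
        p=rank,
        unit_ids=unit_ids,
        degenerate=degenerate,
        _svd=(Ur, sr, Vr),
    )


def log_likelihood_from_rss(rss: float, n: int) -> float:
    """Gaussian maximum log-likelihood -(n/2)(ln 2pi + ln(RSS/n) + 1).

    RSS = 0 yields the infinite-likelihood sentinel ``+inf``.
    """
    if rss <= 0.0:
        return np.inf
    return float(-(n / 2.0) * (_LOG_2PI + np.log(rss / n) + 1.0))


def log_likelihood_gaussian(fit: ModelFit) -> float:
    return log_likelihood_from_rss(fit.rss, fit.n)


def studentized_residuals(fit: ModelFit) -> np.ndarray:
    """Externally studentized residuals t_i = e_i / (s_(i) sqrt(1 - h_ii)).

    s_(i)^2, the unbiased error variance with unit i deleted, comes from the
    closed-form downdate s_(i)^2 = (RSS - e_i^2/(1-h_ii)) / (n - p - 1); no
    refitting.  Exact zero residuals map to t_i = 0; units with h_ii = 1 get
    NaN (undefined; such a unit determines its own fit and belongs in the
    influence report).
    """
    n, p = fit.n, fit.p
    if n <= p + 1:
        raise InsufficientDFError(
            f"external studentization needs n > p + 1 (n = {n}, p = {p})"
        )
    e = fit.residuals
    h = fit.hat_diag
    t = np.full(n, np.nan)
    ok = h < 1.0 - 1e-10
    rss = fit.rss
    # residuals that are zero up to rounding count as exact zeros
    e_zero = np.abs(e) <= 1e-12 * max(1.0, float(np.max(np.abs(fit.fitted_values))))
    with np.errstate(invalid="ignore", divide="ignore"):
        s_i2 = (rss - e[ok] ** 2 / (1.0 - h[ok])) / (n - p - 1)
        s_i2 = np.maximum(s_i2, 0.0)
        denom = np.sqrt(s_i2 * (1.0 - h[ok]))
        ratio = np.divide(e[ok], denom, out=np.full(ok.sum(), np.inf) * np.sign(e[ok]),
                          where=denom > 0.0)
        t[ok] = np.where(e_zero[ok], 0.0, ratio)
    return t


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of nested least-squares fits."""

    statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def likelihood_ratio_test(reduced: ModelFit, full: ModelFit) -> LRTResult:
    """2(ll_full - ll_reduced) against chi-square with df = rank difference.

    Both fits must cover the same units and outcome values, and the reduced
    column set must nest in the full one.  df = 0 forces statistic 0 and
    p-value 1; a perfect (RSS = 0) full fit reports p-value 0 with the
    degeneracy flag.
    """
    if list(reduced.unit_ids) != list(full.unit_ids):
        raise NestingError("reduced and full fits cover different unit sets")
    y_r = reduced.fitted_values + reduced.residuals
    y_f = full.fitted_values + full.residuals
    if not np.allclose(y_r, y_f, rtol=1e-10, atol=1e-10):
        raise NestingError("reduced and full fits use different outcome vectors")
    if not set(reduced.column_names) <= set(full.column_names):
        raise NestingError("reduced model columns are not a subset of the full model's")
    df = full.p - reduced.p
    if df < 0:
        raise NestingError("full model has lower effective rank than reduced model")
    if df == 0:
        return LRTResult(statistic=0.0, df=0, p_value=1.0)
    ll_f, ll_r = full.log_likelihood, reduced.log_likelihood
    if np.isinf(ll_f):
        if np.isinf(ll_r):
            return LRTResult(statistic=0.0, df=df, p_value=1.0, degenerate=True)
        return LRTResult(statistic=np.inf, df=df, p_value=0.0, degenerate=True)
    stat = max(0.0, 2.0 * (ll_f - ll_r))
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


@dataclass
class InfluenceReport:
    """Leverage, externally studentized residual and Cook's distance per unit."""

    unit_ids: list[Hashable]
    hat_diag: np.ndarray
    studentized: np.ndarray
    cooks_distance: np.ndarray
    flagged: list[Hashable]
    hat_cutoff: float
    cooks_cutoff: float


def cooks_distance(fit: ModelFit) -> np.ndarray:
    """D_i = (e_i^2 / (p sigma2_unbiased)) * h_ii / (1 - h_ii)^2."""
    e, h = fit.residuals, fit.hat_diag
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (e**2 / (fit.p * fit.sigma2_unbiased)) * h / (1.0 - h) ** 2
    d = np.where(h >= 1.0 - 1e-10, np.inf, d)
    return d


def influence_diagnostics(
    fit: ModelFit,
    hat_multiplier: float = 2.0,
    cooks_threshold: float | None = None,
) -> InfluenceReport:
    """Flag "influential leverage points": high leverage *and* high influence.

    A unit is flagged iff h_ii > hat_multiplier * p / n and Cook's distance
    exceeds ``cooks_threshold`` (default 4/n).  Both cutoffs are the standard
    rules of thumb and are exposed for sensitivity analysis.
    """
    if cooks_threshold is None:
        cooks_threshold = 4.0 / fit.n
    hat_cut = hat_multiplier * fit.p / fit.n
    d = cooks_distance(fit)
    t = studentized_residuals(fit)
    mask = (fit.hat_diag > hat_cut) & (d > cooks_threshold)
    flagged = [uid for uid, m in zip(fit.unit_ids, mask) if m]
    return InfluenceReport(
        unit_ids=list(fit.unit_ids),
        hat_diag=fit.hat_diag,
        studentized=t,
        cooks_distance=d,
        flagged=flagged,
        hat_cutoff=hat_cut,
        cooks_cutoff=cooks_threshold,
    )
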